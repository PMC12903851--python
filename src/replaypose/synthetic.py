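"""Synthetic fixtures with known ground truth.

Three generators make the full protocol testable without downloads or an MD
engine:

* :func:`make_blob_ensemble` - labeled Gaussian point clouds standing in for
  the RMSD-space structure of a refined pose ensemble; the generating labels
  are the clustering oracle.
* :func:`make_two_basin_system` - a 1-D analytic double-well landscape with
  reference basin weights computed by dense quadrature of the stationary
  density exp(-E/kT). Because uniform replay-buffer selection does not
  target the Boltzmann measure, the weights are used only for ORDER
  assertions (the deeper basin should collect more occupancy), never for
  numeric equality.
* :func:`make_toy_complex` - miniature receptor PDB + 3-pose ligand SDF that
  exercise the whole I/O path, including a FAD residue with a C4A atom for
  geometry reports.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import NumericError, ValidationError
from .propagation import AnalyticLandscape, GaussianWell, SystemState
from .structures import PoseSet, Structure, write_pose_set

__all__ = [
    "BlobEnsembleSpec",
    "TwoBasinSpec",
    "make_blob_ensemble",
    "make_two_basin_system",
    "make_toy_complex",
]


@dataclass(frozen=True)
class BlobEnsembleSpec:
    """Spec for a labeled Gaussian-blob point ensemble.

    If ``centers`` is omitted they are placed on a line with pairwise
    spacing ``separation_ratio * within_sd``, giving cleanly separable
    clusters at the default ratio of 10.
    """

    k: int = 3
    points_per_cluster: int = 20
    dimension: int = 2
    within_sd: float = 1.0
    separation_ratio: float = 10.0
    centers: Optional[tuple[tuple[float, ...], ...]] = None
    seed: int = 0

    def resolved_centers(self) -> np.ndarray:
        if self.centers is not None:
            c = np.asarray(self.centers, dtype=float)
            if c.shape != (self.k, self.dimension):
                raise ValidationError("centers must be (k, dimension)")
            return c
        spacing = self.separation_ratio * self.within_sd
        c = np.zeros((self.k, self.dimension))
        c[:, 0] = np.arange(self.k) * spacing
        return c


def make_blob_ensemble(spec: BlobEnsembleSpec) -> tuple[np.ndarray, np.ndarray]:
    """Seeded Gaussian blobs: returns (points (n, D), true labels (n,))."""
    if spec.k < 1 or spec.points_per_cluster < 1 or spec.dimension < 1:
        raise ValidationError("k, points_per_cluster and dimension must be >= 1")
    if spec.within_sd <= 0:
        raise ValidationError("within_sd must be > 0")
    rng = np.random.default_rng(spec.seed)
    centers = spec.resolved_centers()
    points, labels = [], []
    for c_idx in range(spec.k):
        pts = centers[c_idx] + spec.within_sd * rng.standard_normal(
            (spec.points_per_cluster, spec.dimension)
        )
        points.append(pts)
        labels.append(np.full(spec.points_per_cluster, c_idx))
    return np.vstack(points), np.concatenate(labels)


@dataclass(frozen=True)
class TwoBasinSpec:
    """Spec for a 1-D double-well landscape with known basin weights.

    Defaults give a deep basin (depth 4 kT) and a shallow one (depth 1 kT)
    far enough apart to be distinct clusters, with the shallow well leaky
    enough that free segments can hop into the deep one.
    """

    centers: tuple[float, float] = (-1.5, 1.5)
    depths: tuple[float, float] = (4.0, 1.0)
    widths: tuple[float, float] = (0.6, 0.6)
    kT: float = 1.0
    confinement_k: float = 0.5  # harmonic container emulating the bounded pocket
    barrier_height: float = 0.0  # optional explicit Gaussian bump at the midpoint
    barrier_width: float = 0.4
    n_poses_per_basin: int = 1
    quad_points: int = 20001
    domain_pad: float = 6.0

    def __post_init__(self):
        if self.kT <= 0:
            raise ValidationError("kT must be > 0")
        if min(self.widths) <= 0:
            raise ValidationError("widths must be > 0")


def make_two_basin_system(
    spec: TwoBasinSpec,
) -> tuple[AnalyticLandscape, list[SystemState], np.ndarray]:
    """Build the landscape, straddling initial states, and reference weights.

    Reference weights are the Boltzmann mass of each basin (split at the
    midpoint between the centers), computed by trapezoid quadrature of
    exp(-E/kT) on a dense grid; the tail truncation and grid error are
    checked to be below 1e-6 of the total mass.
    """
    wells = [
        GaussianWell(center=(spec.centers[0],), depth=spec.depths[0], width=spec.widths[0]),
        GaussianWell(center=(spec.centers[1],), depth=spec.depths[1], width=spec.widths[1]),
    ]
    if spec.barrier_height > 0:
        mid = 0.5 * (spec.centers[0] + spec.centers[1])
        wells.append(GaussianWell(center=(mid,), depth=-spec.barrier_height, width=spec.barrier_width))
    landscape = AnalyticLandscape(wells, kT=spec.kT, confinement_k=spec.confinement_k)

    lo = min(spec.centers) - spec.domain_pad
    hi = max(spec.centers) + spec.domain_pad
    x = np.linspace(lo, hi, spec.quad_points)
    energies = np.array([landscape.energy(np.array([xi])) for xi in x])
    rho = np.exp(-energies / spec.kT)
    total = np.trapezoid(rho, x)
    if not np.isfinite(total) or total <= 0:
        raise NumericError("stationary-density quadrature failed")
    # convergence check: halving the grid must not move the split masses
    mid = 0.5 * (spec.centers[0] + spec.centers[1])
    left_mask = x <= mid
    left = np.trapezoid(rho[left_mask], x[left_mask])
    coarse_x, coarse_rho = x[::2], rho[::2]
    coarse_mask = coarse_x <= mid
    coarse_total = np.trapezoid(coarse_rho, coarse_x)
    coarse_left = np.trapezoid(coarse_rho[coarse_mask], coarse_x[coarse_mask])
    if abs(left / total - coarse_left / coarse_total) > 1e-6:
        raise NumericError("basin-weight quadrature did not converge to 1e-6")
    weights = np.array([left / total, 1.0 - left / total])

    states = []
    for b, center in enumerate(spec.centers):
        for r in range(spec.n_poses_per_basin):
            states.append(
                SystemState(coords=np.array([float(center)]), tag=f"basin{b}_pose{r + 1}")
            )
    return landscape, states, weights


# -- miniature receptor/ligand files ---------------------------------------

_AA_NAMES = ["ALA", "GLY", "SER", "THR", "VAL", "LEU", "PHE", "TRP", "HIS", "MET"]


def make_toy_complex(
    n_receptor_atoms: int,
    n_ligand_atoms: int,
    seed: int,
    out_dir,
) -> tuple[Path, Path]:
    """Write a miniature receptor PDB and a 3-pose ligand SDF.

    The receptor's last residue is a FAD cofactor whose final two atoms are
    named C4A and N5, so geometry reports can be exercised end to end. The
    three ligand poses are rigid translations of one random conformation.
    Regeneration with the same arguments is byte-identical.
    """
    if n_receptor_atoms < 1 or n_ligand_atoms < 1:
        raise ValidationError("atom counts must be >= 1")
    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # receptor: CA trace plus a trailing FAD residue (>= C4A, N5 when room)
    coords = np.round(10.0 * rng.random((n_receptor_atoms, 3)), 3)
    n_fad = min(2, n_receptor_atoms)
    n_protein = n_receptor_atoms - n_fad
    names, elements, residue_ids = [], [], []
    for i in range(n_protein):
        names.append("CA")
        elements.append("C")
        residue_ids.append(("A", str(i + 1), _AA_NAMES[i % len(_AA_NAMES)]))
    fad_atoms = [("C4A", "C"), ("N5", "N")][-n_fad:] if n_fad else []
    for nm, el in fad_atoms:
        names.append(nm)
        elements.append(el)
        residue_ids.append(("A", str(n_protein + 1), "FAD"))
    receptor = Structure(
        atom_names=names,
        elements=elements,
        coords=coords,
        residue_ids=residue_ids,
        source="synthetic",
    )
    receptor_path = out / "receptor.pdb"
    _write_minimal_pdb(receptor, receptor_path)

    # ligand: one random conformation, 3 translated poses
    base = np.round(2.0 * rng.random((n_ligand_atoms, 3)), 3)
    shifts = np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0], [0.0, 1.5, 0.0]])
    template = Structure(
        atom_names=[f"C{i + 1}" for i in range(n_ligand_atoms)],
        elements=["C"] * n_ligand_atoms,
        coords=base,
        residue_ids=[("L", "1", "LIG")] * n_ligand_atoms,
        source="synthetic",
    )
    poses = PoseSet(
        ligand_template=template,
        pose_coords=[base + s for s in shifts],
        pose_ids=[f"pose_{i + 1}" for i in range(3)],
        scores=[-7.0, -6.5, -6.0],
    )
    poses_path = out / "ligand_poses.sdf"
    write_pose_set(poses, poses_path, format="sdf")
    return receptor_path, poses_path


def _write_minimal_pdb(structure: Structure, path: Path) -> None:
    # deterministic fixed-width output (no library banner lines), so seeded
    # regeneration is byte-identical
    lines = []
    for i in range(structure.n_atoms):
        chain, resnum, resname = structure.residue_ids[i]
        x, y, z = structure.coords[i]
        record = "HETATM" if resname in ("FAD", "LIG") else "ATOM  "
        name = structure.atom_names[i]
        name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
        lines.append(
            f"{record}{i + 1:>5d} {name_field} {resname:<3s} {chain:1s}{int(resnum):>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {structure.elements[i]:>2s}"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
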