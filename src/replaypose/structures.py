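"""Structure and pose-set I/O plus atom-selection resolution.

Receptors are read from PDB; docked ligand pose sets from SDF (V2000) or
multi-model PDB. Coordinates are Angstrom everywhere and atom indexing is
0-based internally; files keep their native 1-based serials. Selection
expressions use the MDAnalysis selection language (``resname FAD and name
C4A``, ``chain A``, ``resid 95`` ...); ``chain`` is accepted as an alias for
``chainID``.

PDBQT output from docking engines is not parsed directly - convert with
``obabel poses.pdbqt -O poses.sdf`` first.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import ConsistencyError, FormatError, InputError, SelectionError, ValidationError

__all__ = [
    "Structure",
    "PoseSet",
    "AtomSelection",
    "read_structure",
    "read_pose_set",
    "write_pose_set",
    "resolve_selection",
]

# tags commonly used by docking engines for per-record scores
_SCORE_TAGS = ("minimizedAffinity", "docking_score", "score", "Score", "SCORE")

_POSE_REMARK = "REMARK 300 POSE"


@dataclass
class Structure:
    """A molecular structure: atoms, elements, coordinates, residue labels.

    ``residue_ids`` holds one ``(chain, residue number, residue name)`` tuple
    per atom; the residue number is a string so insertion codes survive
    round-trips (``"52"``, ``"52A"``).
    """

    atom_names: list[str]
    elements: list[str]
    coords: np.ndarray  # (N, 3) Angstrom
    residue_ids: list[tuple[str, str, str]]
    source: str = ""
    _universe: object = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValidationError("coords must be an (N, 3) array")
        n = self.coords.shape[0]
        if n < 1:
            raise ValidationError("a Structure needs at least one atom")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("coords must be finite")
        if not (len(self.atom_names) == len(self.elements) == len(self.residue_ids) == n):
            raise ConsistencyError("atom_names, elements, residue_ids and coords disagree in length")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def to_universe(self):
        """Build (and cache) an MDAnalysis Universe view of this structure."""
        if self._universe is not None:
            return self._universe
        import MDAnalysis as mda

        n = self.n_atoms
        # residues in order of first appearance
        res_keys: list[tuple[str, str, str]] = []
        res_index = np.empty(n, dtype=int)
        seen: dict[tuple[str, str, str], int] = {}
        for i, key in enumerate(self.residue_ids):
            if key not in seen:
                seen[key] = len(res_keys)
                res_keys.append(key)
            res_index[i] = seen[key]

        resids, icodes, resnames, chains = [], [], [], []
        for chain, resnum, resname in res_keys:
            m = re.fullmatch(r"(-?\d+)([A-Za-z]?)", str(resnum))
            if m:
                resids.append(int(m.group(1)))
                icodes.append(m.group(2))
            else:
                resids.append(0)
                icodes.append("")
            resnames.append(resname)
            chains.append(chain or "A")

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe.empty(
                n,
                n_residues=len(res_keys),
                n_segments=len(set(chains)) or 1,
                atom_resindex=res_index,
                residue_segindex=[sorted(set(chains)).index(c) for c in chains],
                trajectory=True,
            )
            u.add_TopologyAttr("name", list(self.atom_names))
            u.add_TopologyAttr("type", list(self.elements))
            u.add_TopologyAttr("element", list(self.elements))
            u.add_TopologyAttr("resname", resnames)
            u.add_TopologyAttr("resid", resids)
            u.add_TopologyAttr("icode", icodes)
            u.add_TopologyAttr("chainID", [chains[res_index[i]] for i in range(n)])
            u.add_TopologyAttr("segid", sorted(set(chains)))
            u.add_TopologyAttr("occupancy", np.ones(n))
            u.add_TopologyAttr("tempfactor", np.zeros(n))
            u.atoms.positions = self.coords.astype(np.float32)
        self._universe = u
        return u

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return Structure(
            atom_names=self.atom_names,
            elements=self.elements,
            coords=np.asarray(coords, dtype=float),
            residue_ids=self.residue_ids,
            source=self.source,
        )


@dataclass
class PoseSet:
    """A set of ligand poses sharing one topology.

    ``ligand_template`` carries names/elements/residues; each entry of
    ``pose_coords`` is an (M, 3) array congruent with the template. For toy
    systems (analytic landscapes) the template may be ``None`` and pose
    coordinates are bare D-vectors.
    """

    ligand_template: Optional[Structure]
    pose_coords: list[np.ndarray]
    pose_ids: list[str]
    scores: Optional[list[float]] = None
    _rdkit_mol: object = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.pose_coords = [np.asarray(c, dtype=float) for c in self.pose_coords]
        if len(self.pose_ids) != len(self.pose_coords):
            raise ConsistencyError("pose_ids and pose_coords disagree in length")
        if len(set(self.pose_ids)) != len(self.pose_ids):
            raise ValidationError("pose_ids must be unique")
        if self.ligand_template is not None:
            m = self.ligand_template.n_atoms
            for pid, c in zip(self.pose_ids, self.pose_coords):
                if c.shape != (m, 3):
                    raise ConsistencyError(
                        f"pose {pid!r} has shape {c.shape}, template expects ({m}, 3)"
                    )
        if self.scores is not None and len(self.scores) != len(self.pose_ids):
            raise ConsistencyError("scores and pose_ids disagree in length")

    def __len__(self) -> int:
        return len(self.pose_coords)

    def subset(self, n: int) -> "PoseSet":
        """First ``n`` poses (docking rank order)."""
        return PoseSet(
            ligand_template=self.ligand_template,
            pose_coords=self.pose_coords[:n],
            pose_ids=self.pose_ids[:n],
            scores=None if self.scores is None else self.scores[:n],
            _rdkit_mol=self._rdkit_mol,
        )


@dataclass(frozen=True)
class AtomSelection:
    """A resolved atom selection: the expression plus sorted 0-based indices."""

    expression: str
    resolved_indices: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.resolved_indices)

    @property
    def indices(self) -> np.ndarray:
        return np.asarray(self.resolved_indices, dtype=int)


def _alias_selection(expression: str) -> str:
    # `chain A` is a widespread shorthand; MDAnalysis calls the keyword chainID
    return re.sub(r"\bchain\b", "chainID", expression)


def resolve_selection(structure: Structure, expression: str) -> AtomSelection:
    """Resolve a selection expression to a sorted, deterministic index list.

    Raises :class:`SelectionError` if the expression matches zero atoms.
    """
    u = structure.to_universe()
    try:
        group = u.select_atoms(_alias_selection(expression))
    except Exception as exc:  # MDAnalysis SelectionError and parser errors
        raise SelectionError(f"invalid selection {expression!r}: {exc}") from exc
    if len(group) == 0:
        raise SelectionError(f"selection {expression!r} matched no atoms")
    idx = tuple(int(i) for i in np.sort(group.indices))
    return AtomSelection(expression=expression, resolved_indices=idx)


def _structure_from_universe(u, source: str) -> Structure:
    atoms = u.atoms
    n = len(atoms)
    if n == 0:
        raise FormatError(f"{source}: no atoms found")
    names = [str(x) for x in atoms.names] if hasattr(atoms, "names") else [f"X{i+1}" for i in range(n)]
    if hasattr(atoms, "elements") and all(atoms.elements):
        elements = [str(e).capitalize() for e in atoms.elements]
    else:
        elements = [re.sub(r"[^A-Za-z].*", "", nm)[:1].upper() or "X" for nm in names]
    chains = atoms.chainIDs if hasattr(atoms, "chainIDs") else ["A"] * n
    icodes = atoms.icodes if hasattr(atoms, "icodes") else [""] * n
    residue_ids = [
        (str(c), f"{int(r)}{str(ic).strip()}", str(rn))
        for c, r, ic, rn in zip(chains, atoms.resids, icodes, atoms.resnames)
    ]
    return Structure(
        atom_names=names,
        elements=elements,
        coords=atoms.positions.astype(float),
        residue_ids=residue_ids,
        source=source,
    )


def read_structure(path, format: str = "pdb") -> Structure:
    """Read a receptor (or any) structure from a PDB file."""
    if format != "pdb":
        raise ValidationError(f"unsupported structure format {format!r}")
    path = Path(path)
    if not path.is_file():
        raise InputError(f"no such file: {path}")
    import MDAnalysis as mda

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except Exception as exc:
        raise FormatError(f"could not parse {path} as PDB: {exc}") from exc
    return _structure_from_universe(u, source=str(path))


def _infer_pose_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".sdf":
        return "sdf"
    if suffix in (".pdb", ".ent"):
        return "pdb"
    raise ValidationError(f"cannot infer pose format from {path.name!r}; pass format=")


def _read_pose_set_sdf(path: Path) -> PoseSet:
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    mols = [m for m in supplier if m is not None]
    if not mols:
        raise FormatError(f"{path}: no molecules in SDF")
    n0 = mols[0].GetNumAtoms()
    coords, ids, scores = [], [], []
    any_score = False
    for i, mol in enumerate(mols):
        if mol.GetNumAtoms() != n0:
            raise ConsistencyError(
                f"{path}: record {i} has {mol.GetNumAtoms()} atoms, expected {n0}"
            )
        conf = mol.GetConformer()
        coords.append(np.array(conf.GetPositions(), dtype=float))
        name = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"pose_{i+1}"
        ids.append(name)
        score = None
        for tag in _SCORE_TAGS:
            if mol.HasProp(tag):
                try:
                    score = float(mol.GetProp(tag))
                    any_score = True
                except ValueError:
                    pass
                break
        scores.append(score)
    # de-duplicate ids if the SDF reused titles
    if len(set(ids)) != len(ids):
        ids = [f"{name}_{i+1}" for i, name in enumerate(ids)]
    template_mol = mols[0]
    elements = [a.GetSymbol() for a in template_mol.GetAtoms()]
    names = [f"{sym.upper()}{i+1}" for i, sym in enumerate(elements)]
    template = Structure(
        atom_names=names,
        elements=elements,
        coords=coords[0],
        residue_ids=[("L", "1", "LIG")] * n0,
        source=str(path),
    )
    return PoseSet(
        ligand_template=template,
        pose_coords=coords,
        pose_ids=ids,
        scores=scores if any_score else None,
        _rdkit_mol=template_mol,
    )


def _read_pose_set_pdb(path: Path) -> PoseSet:
    import MDAnalysis as mda

    # pose ids / scores from our REMARK 300 header lines, if present
    remark_ids: list[str] = []
    remark_scores: list[float] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(_POSE_REMARK):
                parts = line.split()
                # REMARK 300 POSE <index> <id> [<score>]
                if len(parts) >= 5:
                    remark_ids.append(parts[4])
                    if len(parts) >= 6:
                        try:
                            remark_scores.append(float(parts[5]))
                        except ValueError:
                            pass
            elif line.startswith(("MODEL", "ATOM", "HETATM")):
                break
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except Exception as exc:
        raise ConsistencyError(f"could not parse {path} as multi-model PDB: {exc}") from exc
    template = _structure_from_universe(u, source=str(path))
    coords = []
    for ts in u.trajectory:
        coords.append(ts.positions.astype(float).copy())
    if remark_ids and len(remark_ids) == len(coords):
        ids = remark_ids
    else:
        ids = [f"model_{i+1}" for i in range(len(coords))]
    scores = remark_scores if len(remark_scores) == len(coords) else None
    return PoseSet(
        ligand_template=template.with_coords(coords[0]),
        pose_coords=coords,
        pose_ids=ids,
        scores=scores,
    )


def read_pose_set(path, format: Optional[str] = None) -> PoseSet:
    """Read a docked pose set from SDF or multi-model PDB.

    All records/models must share atom count and order; per-record docking
    score tags (e.g. Smina's ``minimizedAffinity``) populate ``scores``.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"no such file: {path}")
    fmt = format or _infer_pose_format(path)
    if fmt == "sdf":
        return _read_pose_set_sdf(path)
    if fmt == "pdb":
        return _read_pose_set_pdb(path)
    raise ValidationError(f"unsupported pose format {fmt!r}")


def _write_pose_set_sdf(poses: PoseSet, path: Path) -> None:
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    if poses._rdkit_mol is not None:
        base = Chem.Mol(poses._rdkit_mol)
    else:
        rw = Chem.RWMol()
        for el in poses.ligand_template.elements:
            rw.AddAtom(Chem.Atom(el))
        base = rw.GetMol()
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for i, (pid, xyz) in enumerate(zip(poses.pose_ids, poses.pose_coords)):
            mol = Chem.Mol(base)
            conf = Chem.Conformer(mol.GetNumAtoms())
            for a in range(mol.GetNumAtoms()):
                conf.SetAtomPosition(a, Point3D(*xyz[a]))
            mol.RemoveAllConformers()
            mol.AddConformer(conf, assignId=True)
            mol.SetProp("_Name", pid)
            if poses.scores is not None and poses.scores[i] is not None:
                mol.SetProp("score", repr(float(poses.scores[i])))
            writer.write(mol)
    finally:
        writer.close()


def _write_pose_set_pdb(poses: PoseSet, path: Path) -> None:
    import MDAnalysis as mda

    template = poses.ligand_template
    u = template.to_universe()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), multiframe=True, n_atoms=template.n_atoms) as writer:
            for xyz in poses.pose_coords:
                u.atoms.positions = np.asarray(xyz, dtype=np.float32)
                writer.write(u.atoms)
    # inject pose-id remarks into the header (before the first MODEL record)
    text = path.read_text().splitlines(keepends=True)
    remarks = []
    for i, pid in enumerate(poses.pose_ids):
        line = f"{_POSE_REMARK} {i + 1} {pid}"
        if poses.scores is not None and poses.scores[i] is not None:
            line += f" {float(poses.scores[i]):.6g}"
        remarks.append(line + "\n")
    first_model = next(
        (j for j, ln in enumerate(text) if ln.startswith(("MODEL", "ATOM", "HETATM"))), 0
    )
    path.write_text("".join(text[:first_model] + remarks + text[first_model:]))


def write_pose_set(poses: PoseSet, path, format: Optional[str] = None) -> None:
    """Write a pose set to SDF or multi-model PDB.

    Round-trips coordinates to format precision (0.001 A for PDB) and pose ids
    as record titles (SDF) / REMARK 300 header lines (PDB).
    """
    if len(poses) == 0:
        raise ValidationError("cannot write an empty pose set")
    if poses.ligand_template is None:
        raise ValidationError("toy pose sets have no molecular topology to write")
    path = Path(path)
    fmt = format or _infer_pose_format(path)
    try:
        if fmt == "sdf":
            _write_pose_set_sdf(poses, path)
        elif fmt == "pdb":
            _write_pose_set_pdb(poses, path)
        else:
            raise ValidationError(f"unsupported pose format {fmt!r}")
    except OSError as exc:
        raise InputError(f"cannot write {path}: {exc}") from exc
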