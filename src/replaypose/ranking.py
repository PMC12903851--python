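"""Pose probabilities, representatives and active-site geometry reports.

The probability of each pose (cluster) is its relative occupancy: the
fraction of all replay-buffer states assigned to that cluster. The cluster
representative is the medoid - the member minimizing summed RMSD to all
other members - with ties broken by lower averaged energy, then lower buffer
index. Geometry reports measure user-specified atom-pair distances (e.g.
ligand oxygenation site to flavin C4a) and three-atom angles on any
structure or pose.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .clustering import ClusteringResult
from .errors import ConsistencyError, SelectionError, ValidationError
from .replay import ReplayBuffer
from .structures import Structure, resolve_selection

__all__ = [
    "PoseCluster",
    "cluster_probabilities",
    "representative_pose",
    "geometry_report",
]


@dataclass
class PoseCluster:
    """One cluster of buffer states with its occupancy probability."""

    cluster_id: int
    member_indices: tuple[int, ...]
    occupancy: int
    probability: float
    representative_index: int
    mean_energy: float
    origin_pose_histogram: dict[str, int]


def representative_pose(buffer: ReplayBuffer, member_indices, d: np.ndarray) -> int:
    """Medoid of a cluster: argmin of summed distance to the other members.

    Exact ties go to the lower averaged energy, then the lower buffer index.
    ``member_indices`` may be a PoseCluster or an index sequence.
    """
    if isinstance(member_indices, PoseCluster):
        member_indices = member_indices.member_indices
    members = np.asarray(list(member_indices), dtype=int)
    if members.size == 0:
        raise ValidationError("cluster is empty")
    if members.size == 1:
        return int(members[0])
    sub = np.asarray(d, dtype=float)[np.ix_(members, members)]
    sums = sub.sum(axis=1)
    best = sums.min()
    tied = members[sums == best]
    energies = np.array([buffer[i].averaged_energy for i in tied])
    tied = tied[energies == energies.min()]
    return int(tied.min())


def cluster_probabilities(
    buffer: ReplayBuffer,
    clustering: ClusteringResult,
    d: Optional[np.ndarray] = None,
    include_init: bool = True,
) -> list[PoseCluster]:
    """Occupancy probability of each cluster, sorted by descending probability.

    Probabilities are occupancy counts over the total number of counted
    entries and sum to 1. ``include_init=False`` counts only MC-generated
    entries (initialization entries keep their labels but are excluded from
    occupancy). The representative is the medoid when a distance matrix is
    supplied, otherwise the lowest-energy member.
    """
    labels = np.asarray(clustering.labels)
    n = len(buffer)
    if labels.shape != (n,):
        raise ConsistencyError(f"{labels.size} labels for a buffer of {n} entries")
    counted = np.ones(n, dtype=bool)
    if not include_init:
        counted = np.array([e.mc_step > 0 for e in buffer])
        if not counted.any():
            raise ValidationError("no MC-generated entries to count")
    total = int(counted.sum())
    clusters: list[PoseCluster] = []
    for cid in np.unique(labels):
        members = np.flatnonzero(labels == cid)
        occupancy = int(counted[members].sum())
        hist: dict[str, int] = {}
        for i in members:
            hist[buffer[i].origin_pose] = hist.get(buffer[i].origin_pose, 0) + 1
        if d is not None:
            rep = representative_pose(buffer, members, d)
        else:
            energies = np.array([buffer[i].averaged_energy for i in members])
            rep = int(members[np.argmin(energies)])
        clusters.append(
            PoseCluster(
                cluster_id=int(cid),
                member_indices=tuple(int(i) for i in members),
                occupancy=occupancy,
                probability=occupancy / total,
                representative_index=rep,
                mean_energy=float(np.mean([buffer[i].averaged_energy for i in members])),
                origin_pose_histogram=hist,
            )
        )
    clusters.sort(key=lambda c: (-c.probability, c.cluster_id))
    return clusters


def _resolve_single_atom(structure: Structure, expression: str) -> int:
    sel = resolve_selection(structure, expression)
    if len(sel) != 1:
        raise SelectionError(
            f"geometry reference {expression!r} resolves to {len(sel)} atoms, need exactly 1"
        )
    return sel.resolved_indices[0]


def geometry_report(structure: Structure, specs: Sequence[dict]) -> pd.DataFrame:
    """Measure named atom-pair distances and atom-triple angles.

    Each spec is ``{"name": ..., "atoms": [expr, expr]}`` (distance, Angstrom)
    or three expressions (angle at the middle atom, degrees). Every
    expression must resolve to exactly one atom.
    """
    rows = []
    for spec in specs:
        name = spec.get("name", "+".join(spec["atoms"]))
        exprs = list(spec["atoms"])
        if len(exprs) not in (2, 3):
            raise ValidationError(f"geometry spec {name!r} needs 2 or 3 atom references")
        idx = [_resolve_single_atom(structure, e) for e in exprs]
        pts = structure.coords[idx]
        if len(idx) == 2:
            value = float(np.linalg.norm(pts[0] - pts[1]))
            kind = "distance"
        else:
            v1 = pts[0] - pts[1]
            v2 = pts[2] - pts[1]
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            value = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            kind = "angle"
        rows.append({"name": name, "kind": kind, "atoms": " | ".join(exprs), "value": value})
    return pd.DataFrame(rows, columns=["name", "kind", "atoms", "value"])
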