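"""Self-tuning spectral clustering of buffer states by RMSD.

Pipeline: pairwise RMSD matrix over all buffer states -> affinity with local
scaling, A_ij = exp(-d_ij^2 / (sigma_i sigma_j)) where sigma_i is the
distance to point i's k-th nearest neighbor (default k = 10) -> eigengap of
the symmetric normalized Laplacian proposes candidate cluster counts (up to
25) -> spectral clustering is repeated (default 25 trials) over the
candidates with varied k-means restarts -> the partition with the maximum
silhouette score wins.

Local scaling adapts the Gaussian bandwidth to each point's neighborhood
density, so tight and diffuse pose clusters can coexist in one affinity
matrix. The eigengap heuristic exploits the fact that an affinity graph with
k well-separated components has k near-zero Laplacian eigenvalues followed
by a gap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.spatial.transform import Rotation

from .errors import ConsistencyError, NumericError, ValidationError
from .replay import ReplayBuffer, derive_seed
from .structures import AtomSelection

__all__ = [
    "Affinity",
    "ClusteringResult",
    "pairwise_rmsd",
    "compute_rmsd_matrix",
    "local_scaling_sigmas",
    "build_affinity",
    "laplacian_eigenvalues",
    "rank_eigengaps",
    "select_candidate_ks",
    "spectral_cluster",
    "silhouette",
    "select_best_clustering",
]

SIGMA_FLOOR = 1e-8


@dataclass(frozen=True)
class Affinity:
    """Locally scaled affinity matrix plus the per-point scales used."""

    values: np.ndarray  # (n, n), symmetric, diagonal 1, entries in (0, 1]
    sigmas: np.ndarray  # (n,) local scales, > 0


@dataclass
class ClusteringResult:
    """The selected partition with its model-selection audit trail."""

    labels: np.ndarray  # (n,) ints in [0, k)
    k: int
    silhouette: float
    eigenvalues: np.ndarray  # ascending Laplacian spectrum used for selection
    candidate_ks: list[int]
    trials: list[dict] = field(default_factory=list)  # per-trial (k, seed, silhouette)


def _check_distance_matrix(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.all(np.isfinite(d)):
        raise NumericError("distance matrix contains non-finite values")
    if np.any(d < 0) or not np.allclose(d, d.T):
        raise ValidationError("distance matrix must be symmetric and non-negative")
    return d


def pairwise_rmsd(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    rmsd_indices: Optional[np.ndarray] = None,
    align_indices: Optional[np.ndarray] = None,
) -> float:
    """RMSD between two (N, 3) conformations.

    If ``align_indices`` is given, B is optimally superposed onto A (Kabsch,
    least-squares rotation after centroid removal) using those atoms, and the
    RMSD is then evaluated over ``rmsd_indices`` (default: all atoms). With
    no alignment the raw coordinates are compared.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise ConsistencyError(f"conformation shapes differ: {a.shape} vs {b.shape}")
    if rmsd_indices is None:
        rmsd_indices = np.arange(a.shape[0])
    rmsd_indices = np.asarray(rmsd_indices, dtype=int)
    if align_indices is not None:
        align_indices = np.asarray(align_indices, dtype=int)
        ca = a[align_indices].mean(axis=0)
        cb = b[align_indices].mean(axis=0)
        rot, _ = Rotation.align_vectors(a[align_indices] - ca, b[align_indices] - cb)
        b = rot.apply(b - cb) + ca
    diff = a[rmsd_indices] - b[rmsd_indices]
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def compute_rmsd_matrix(
    buffer: ReplayBuffer,
    rmsd_selection: Optional[AtomSelection] = None,
    align_selection: Optional[AtomSelection] = None,
) -> np.ndarray:
    """Pairwise RMSD matrix between all buffer states.

    Molecular states ((N, 3) coordinates): RMSD over ``rmsd_selection`` atoms
    (default all) after optional rigid superposition on ``align_selection``
    atoms. Toy states (bare D-vectors): Euclidean distance in landscape
    units; selections are ignored.
    """
    if len(buffer) == 0:
        raise ValidationError("empty buffer")
    coords = buffer.coords_array()
    n = coords.shape[0]
    if coords.ndim == 2:  # toy D-vectors
        return squareform(pdist(coords))
    if coords.ndim != 3 or coords.shape[2] != 3:
        raise ConsistencyError(f"unexpected state coordinate shape {coords.shape[1:]}")
    n_atoms = coords.shape[1]
    ridx = None if rmsd_selection is None else rmsd_selection.indices
    aidx = None if align_selection is None else align_selection.indices
    for sel, what in ((ridx, "rmsd"), (aidx, "align")):
        if sel is not None and (sel.min() < 0 or sel.max() >= n_atoms):
            raise ConsistencyError(f"{what} selection indices out of range for stored states")
    if aidx is None:
        # no superposition: fully vectorized
        sub = coords if ridx is None else coords[:, ridx, :]
        flat = sub.reshape(n, -1)
        sq = squareform(pdist(flat, metric="sqeuclidean"))
        return np.sqrt(sq / sub.shape[1])
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pairwise_rmsd(coords[i], coords[j], ridx, aidx)
    return d


def local_scaling_sigmas(d: np.ndarray, k_nn: int = 10) -> np.ndarray:
    """Per-point scale sigma_i = distance to the k_nn-th nearest neighbor.

    Self-distances are excluded; degenerate zero scales are floored at 1e-8.
    """
    d = _check_distance_matrix(d)
    n = d.shape[0]
    if k_nn < 1:
        raise ValidationError("k_nn must be >= 1")
    if n <= k_nn:
        raise ValidationError(f"need more than k_nn={k_nn} points, got {n}")
    # sort each row; column 0 is the self-distance (0), so the k_nn-th
    # neighbor sits at column k_nn
    part = np.sort(d, axis=1)[:, k_nn]
    return np.maximum(part, SIGMA_FLOOR)


def build_affinity(d: np.ndarray, sigmas: np.ndarray) -> Affinity:
    """Locally scaled Gaussian affinity A_ij = exp(-d_ij^2/(sigma_i sigma_j))."""
    d = _check_distance_matrix(d)
    sigmas = np.asarray(sigmas, dtype=float)
    if sigmas.shape != (d.shape[0],):
        raise ValidationError("sigmas must have one entry per point")
    if np.any(sigmas <= 0):
        raise ValidationError("sigmas must be positive")
    a = np.exp(-(d * d) / np.outer(sigmas, sigmas))
    np.fill_diagonal(a, 1.0)
    if not np.all(np.isfinite(a)):
        raise NumericError("affinity matrix contains non-finite values")
    return Affinity(values=a, sigmas=sigmas)


def _affinity_values(a) -> np.ndarray:
    v = a.values if isinstance(a, Affinity) else np.asarray(a, dtype=float)
    if v.ndim != 2 or v.shape[0] != v.shape[1]:
        raise ValidationError("affinity matrix must be square")
    return v


def laplacian_eigenvalues(a) -> np.ndarray:
    """Ascending spectrum of the symmetric normalized Laplacian of A."""
    v = _affinity_values(a)
    deg = v.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(np.maximum(deg, 1e-300))
    lap = np.eye(v.shape[0]) - (inv_sqrt[:, None] * v * inv_sqrt[None, :])
    return np.linalg.eigvalsh((lap + lap.T) / 2.0)


def rank_eigengaps(eigenvalues: np.ndarray, k_min: int = 1, k_max: int = 25) -> list[int]:
    """Rank cluster counts by descending eigengap lambda_{k+1} - lambda_k.

    Ties break toward smaller k. ``k_min=1`` exposes the single-cluster gap
    (used to warn when the data show no cluster structure); model selection
    proper uses ``k_min=2`` because the silhouette is undefined at k=1.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    n = lam.size
    ks = np.arange(k_min, min(k_max, n - 1) + 1)
    if ks.size == 0:
        return []
    gaps = lam[ks] - lam[ks - 1]  # lambda_{k+1} - lambda_k with 0-based lam
    order = np.lexsort((ks, -gaps))  # primary: largest gap; tie: smaller k
    return [int(ks[i]) for i in order]


def select_candidate_ks(a, k_max: int = 25, n_candidates: int = 5) -> list[int]:
    """Eigengap-ranked candidate cluster counts (k >= 2), largest gap first."""
    v = _affinity_values(a)
    n = v.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 points")
    if n == 2:
        return [2]
    lam = laplacian_eigenvalues(v)
    ranked_all = rank_eigengaps(lam, k_min=1, k_max=k_max)
    if ranked_all and ranked_all[0] == 1:
        warnings.warn(
            "largest eigengap is at k=1: the ensemble shows no cluster structure",
            stacklevel=2,
        )
    ranked = [k for k in ranked_all if k >= 2]
    if not ranked:
        ranked = [2]
    return ranked[: max(1, n_candidates)]


def spectral_cluster(a, k: int, seed: int = 0) -> np.ndarray:
    """Partition points into k clusters via the normalized spectral embedding.

    Embeds each point in the k eigenvectors of the smallest Laplacian
    eigenvalues, row-normalizes, and runs k-means with 10 seeded restarts.
    """
    v = _affinity_values(a)
    n = v.shape[0]
    if not (2 <= k <= n):
        raise ValidationError(f"k must be in [2, {n}], got {k}")
    if k == n:
        return np.arange(n)
    deg = v.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(np.maximum(deg, 1e-300))
    lap = np.eye(n) - (inv_sqrt[:, None] * v * inv_sqrt[None, :])
    _, vecs = np.linalg.eigh((lap + lap.T) / 2.0)
    emb = vecs[:, :k]
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    emb = emb / np.maximum(norms, 1e-300)
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=k, n_init=10, random_state=int(seed) % (2**32))
    return km.fit_predict(emb)


def silhouette(d: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette score from a precomputed distance matrix.

    s_i = (b_i - a_i)/max(a_i, b_i) with a_i the mean intra-cluster distance
    (self excluded) and b_i the smallest mean distance to another cluster.
    Singleton clusters and 0/0 cases contribute 0. Raises for fewer than two
    clusters, where the score is undefined.
    """
    d = _check_distance_matrix(d)
    labels = np.asarray(labels)
    n = d.shape[0]
    if labels.shape != (n,):
        raise ConsistencyError("labels must have one entry per point")
    uniq, inv = np.unique(labels, return_inverse=True)
    k = uniq.size
    if k < 2:
        raise ValidationError("silhouette is undefined for a single cluster")
    counts = np.bincount(inv, minlength=k).astype(float)
    # sums[i, c] = total distance from point i to cluster c
    member = np.zeros((n, k))
    member[np.arange(n), inv] = 1.0
    sums = d @ member
    own = inv
    a = np.zeros(n)
    multi = counts[own] > 1
    a[multi] = sums[np.arange(n), own][multi] / (counts[own][multi] - 1.0)
    mean_other = sums / counts[None, :]
    mean_other[np.arange(n), own] = np.inf
    b = mean_other.min(axis=1)
    denom = np.maximum(a, b)
    s = np.zeros(n)
    ok = denom > 0
    s[ok] = (b[ok] - a[ok]) / denom[ok]
    s[counts[own] == 1] = 0.0  # singleton convention
    return float(s.mean())


def select_best_clustering(
    d: np.ndarray,
    a=None,
    k_max: int = 25,
    n_repeats: int = 25,
    seed: int = 0,
    k_nn: int = 10,
    n_candidates: int = 5,
) -> ClusteringResult:
    """Run the repeated-trial model selection and return the best partition.

    Draws ``n_repeats`` (candidate-k, restart-seed) trials - cycling through
    the eigengap-ranked candidate list while varying the k-means seed - and
    keeps the maximum-silhouette partition. Ties break toward smaller k, then
    the earlier trial.

    ``a`` may be omitted, in which case the affinity is built from ``d`` with
    local scaling (``k_nn`` nearest neighbors).
    """
    d = _check_distance_matrix(d)
    n = d.shape[0]
    if n < 3:
        raise ValidationError("need at least 3 points for model selection")
    if a is None:
        a = build_affinity(d, local_scaling_sigmas(d, k_nn=k_nn))
    v = _affinity_values(a)
    lam = laplacian_eigenvalues(v)
    candidates = select_candidate_ks(a, k_max=k_max, n_candidates=n_candidates)
    candidates = [k for k in candidates if k <= n] or [min(2, n)]
    best = None
    trials: list[dict] = []
    for t in range(n_repeats):
        k = candidates[t % len(candidates)]
        trial_seed = derive_seed(seed, "cluster", t)
        labels = spectral_cluster(v, k, seed=trial_seed)
        k_eff = np.unique(labels).size
        score = silhouette(d, labels) if k_eff >= 2 else -np.inf
        trials.append({"trial": t, "k": k, "seed": trial_seed, "silhouette": score})
        key = (-score, k, t)
        if best is None or key < best[0]:
            best = (key, labels, k_eff, score)
    _, labels, k_eff, score = best
    # relabel to consecutive ints in [0, k)
    _, labels = np.unique(labels, return_inverse=True)
    return ClusteringResult(
        labels=labels,
        k=int(k_eff),
        silhouette=float(score),
        eigenvalues=lam,
        candidate_ks=candidates,
        trials=trials,
    )
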