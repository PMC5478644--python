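"""Conformational clustering of trajectory frames.

Frames are clustered by average-linkage hierarchical clustering on the matrix
of pairwise superposed RMSDs, and the cluster count is selected with the
Kelley penalty: at each hierarchy level the average within-cluster spread
(mean pairwise RMSD over clusters with at least two members) is rescaled onto
[1, n-1] across levels and added to the cluster count; the level minimizing
this penalty wins, with ties broken toward fewer clusters.

Clusters are ranked by member count.  Per-cluster average structures are
coordinate-wise means after superposing every member onto the cluster's first
frame; they feed the model-vs-crystal comparison (superpose + segment_rmsd).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import InsufficientFramesError, SelectionError
from .structio import AtomSelector, Structure, Trajectory, atom_indices
from .trajgeom import _kabsch, kabsch_rmsd

__all__ = [
    "RmsdMatrix",
    "Clustering",
    "pairwise_rmsd_matrix",
    "kelley_cluster",
    "kelley_penalty_curve",
    "cluster_average_structures",
]


@dataclass
class RmsdMatrix:
    """Symmetric matrix of pairwise superposed RMSDs (Angstrom)."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("RMSD matrix must be square")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("RMSD matrix must be symmetric")
        if np.any(np.diag(v) > 1e-9) or np.any(v < 0):
            raise ValueError("RMSD matrix needs a zero diagonal and no negatives")
        self.values = (v + v.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return self.values.shape[0]


def pairwise_rmsd_matrix(traj: Trajectory, sel: AtomSelector | None = None) -> RmsdMatrix:
    """Pairwise superpose-optimal RMSD between all frame pairs on a selection.

    Default selection: CA atoms; falls back to all atoms when the topology has
    no CA atoms (synthetic fixtures).
    """
    if traj.n_frames < 2:
        raise InsufficientFramesError("pairwise RMSD needs at least 2 frames")
    if sel is None:
        idx = atom_indices(traj.topology, AtomSelector(name="CA"))
        if not idx:
            idx = list(range(len(traj.topology.atoms)))
    else:
        idx = atom_indices(traj.topology, sel)
        if not idx:
            raise SelectionError("RMSD selection resolved no atoms")
    coords = [f[idx] for f in traj.frames]
    n = len(coords)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = kabsch_rmsd(coords[i], coords[j])
    return RmsdMatrix(values=m)


@dataclass
class Clustering:
    labels: np.ndarray  # per-frame cluster id in [1..k]
    k: int
    penalty_curve: dict  # candidate k -> penalty
    ranked_sizes: list  # cluster sizes, descending

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)


def _average_spread(matrix: np.ndarray, labels: np.ndarray) -> float | None:
    """Mean over clusters (with >= 2 members) of mean pairwise distance."""
    spreads = []
    for cid in np.unique(labels):
        members = np.nonzero(labels == cid)[0]
        if len(members) < 2:
            continue
        sub = matrix[np.ix_(members, members)]
        iu = np.triu_indices(len(members), k=1)
        spreads.append(float(sub[iu].mean()))
    return float(np.mean(spreads)) if spreads else None


#: spread ranges below this (Angstrom) are structurally meaningless: the
#: penalty is treated as flat and the smallest k wins
_FLAT_SPREAD_TOL = 1e-3


def kelley_penalty_curve(matrix: RmsdMatrix, labels_by_k: dict) -> dict:
    """Kelley penalty per candidate k from precomputed label assignments.

    Average spreads are min-max rescaled onto [1, n-1] across all hierarchy
    levels — including the single-cluster level, whose spread (the full-data
    mean pairwise RMSD) anchors the top of the scale — then the cluster count
    is added.  Levels whose clusters are all singletons take the maximal
    normalized spread (they carry no spread information).  When the spread
    range across levels is negligible (< 1e-3 Angstrom) the curve is flat and
    the penalty reduces to the cluster count.
    """
    n = matrix.n
    iu = np.triu_indices(n, k=1)
    spreads = {1: float(matrix.values[iu].mean())}
    for k, labels in labels_by_k.items():
        if k != 1:
            spreads[k] = _average_spread(matrix.values, labels)
    finite = [s for s in spreads.values() if s is not None]
    smin, smax = min(finite), max(finite)
    flat = (smax - smin) < _FLAT_SPREAD_TOL
    curve = {}
    for k, s in spreads.items():
        if k == 1:
            continue
        if s is None:
            norm = float(n - 1)
        elif flat:
            norm = 1.0
        else:
            norm = (n - 2) * (s - smin) / (smax - smin) + 1.0
        curve[k] = norm + k
    return curve


def kelley_cluster(matrix: RmsdMatrix) -> Clustering:
    """Average-linkage clustering with Kelley-penalty selection of k.

    Deterministic: the penalty is evaluated for k = 2..n-1 and ties break
    toward smaller k.
    """
    n = matrix.n
    if n < 3:
        raise InsufficientFramesError(f"Kelley clustering needs >= 3 frames, got {n}")
    z = linkage(squareform(matrix.values, checks=False), method="average")
    labels_by_k = {k: fcluster(z, t=k, criterion="maxclust") for k in range(2, n)}
    curve = kelley_penalty_curve(matrix, labels_by_k)
    best_k = min(curve, key=lambda k: (curve[k], k))
    labels = labels_by_k[best_k]
    k = int(labels.max())
    sizes = sorted((int((labels == cid).sum()) for cid in np.unique(labels)), reverse=True)
    return Clustering(labels=labels, k=k, penalty_curve=curve, ranked_sizes=sizes)


def cluster_average_structures(
    traj: Trajectory, clustering: Clustering, top_k: int
) -> list[Structure]:
    """Average structures of the top_k largest clusters (size rank order).

    Every member frame is superposed onto the cluster's first frame before the
    coordinate-wise mean; ties in size rank break toward the lower cluster id.
    """
    if top_k > clustering.k:
        raise ValueError(f"top_k={top_k} exceeds cluster count k={clustering.k}")
    order = sorted(
        np.unique(clustering.labels),
        key=lambda cid: (-(clustering.labels == cid).sum(), cid),
    )
    out = []
    for cid in order[:top_k]:
        members = np.nonzero(clustering.labels == cid)[0]
        ref = traj.frames[members[0]]
        stack = [ref]
        for m in members[1:]:
            fit = _kabsch(traj.frames[m], ref)
            stack.append(fit.transform(traj.frames[m]))
        mean = np.mean(stack, axis=0)
        out.append(
            traj.topology.with_coords(
                mean, title=f"cluster {int(cid)} average ({len(members)} members)"
            )
        )
    return out
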