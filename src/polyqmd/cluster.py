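"""Single-linkage clustering of conformations on pairwise Cα RMSD.

Structures (subsampled from the compact ensemble so that consecutive picks
are ≥50 ps apart) are nodes; the distance between two nodes is their
minimal RMSD over rigid superposition (Kabsch, proper rotations only,
Cα beads). Single-linkage clusters at a cutoff are exactly the connected
components of the graph with edges RMSD < cutoff. Each cluster's centroid —
the member minimising total distance to the others — represents it; the
centroid of the largest cluster is the model's overall representative, and
its population fraction gauges how common that conformation is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform

__all__ = [
    "kabsch_rmsd",
    "pairwise_rmsd",
    "DistanceMatrix",
    "ClusterResult",
    "subsample_frames",
    "single_linkage",
    "cluster_curve",
    "suggest_cutoff",
    "centroid",
    "representative_fraction",
    "ca_coordinates",
    "DEFAULT_RMSD_CUTOFF",
    "DELTA_POLYP_Q47_CUTOFF",
    "DEFAULT_MIN_SEPARATION_TU",
]

DEFAULT_RMSD_CUTOFF = 2.0        # Å, all models ...
DELTA_POLYP_Q47_CUTOFF = 2.5     # ... except the ΔpolyP n=47 variant
DEFAULT_MIN_SEPARATION_TU = 1000.0   # 50 ps at 50 fs per tu


def ca_coordinates(frames: np.ndarray) -> np.ndarray:
    """Extract Cα-bead coordinates from (..., 3n, 3) backbone frames."""
    frames = np.asarray(frames, dtype=float)
    return frames[..., 1::3, :]


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimal RMSD between two coordinate sets over rigid motions.

    Uses the optimal orthogonal superposition restricted to proper
    rotations (determinant +1). Atom orderings must correspond.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must both be (n, 3)")
    return float(pairwise_rmsd(np.stack([a, b]))[0, 1])


def pairwise_rmsd(coords: np.ndarray) -> np.ndarray:
    """Dense symmetric matrix of superposed RMSDs for a (m, n, 3) stack.

    Batched Kabsch: for every pair, RMSD² = (|A|² + |B|² − 2·Σσ̃)/n where
    σ̃ are the singular values of the cross-covariance with the smallest
    one sign-flipped if the rotation would otherwise be improper.
    """
    x = np.asarray(coords, dtype=float)
    if x.ndim != 3 or x.shape[2] != 3:
        raise ValueError("need an (m, n, 3) coordinate stack")
    m, n, _ = x.shape
    xc = x - x.mean(axis=1, keepdims=True)
    sq = np.einsum("mij,mij->m", xc, xc)
    ii, jj = np.triu_indices(m, k=1)
    out = np.zeros((m, m))
    # batched 3x3 cross-covariances and SVDs, chunked to bound memory
    chunk = 200_000
    for s in range(0, len(ii), chunk):
        a = xc[ii[s:s + chunk]]
        b = xc[jj[s:s + chunk]]
        h = np.einsum("pni,pnj->pij", a, b)
        u, sig, vt = np.linalg.svd(h)
        det = np.linalg.det(u) * np.linalg.det(vt)
        sig[:, 2] *= np.sign(det)
        msd = (sq[ii[s:s + chunk]] + sq[jj[s:s + chunk]]
               - 2.0 * sig.sum(axis=1)) / n
        out[ii[s:s + chunk], jj[s:s + chunk]] = np.sqrt(np.maximum(msd, 0.0))
    return out + out.T


@dataclass(frozen=True)
class DistanceMatrix:
    """Pairwise RMSDs (Å) with references back to the source frames."""

    condensed: np.ndarray            # scipy condensed upper-triangle form
    frame_indices: np.ndarray        # indices into the pooled frame list

    def __post_init__(self) -> None:
        if np.any(self.condensed < 0):
            raise ValueError("negative distances")

    @property
    def n(self) -> int:
        return len(self.frame_indices)

    def dense(self) -> np.ndarray:
        if self.n == 1:
            return np.zeros((1, 1))
        return squareform(self.condensed)

    @classmethod
    def from_frames(cls, frames: np.ndarray,
                    frame_indices: np.ndarray | None = None,
                    ca_only: bool = True) -> "DistanceMatrix":
        frames = np.asarray(frames, dtype=float)
        pts = ca_coordinates(frames) if ca_only else frames
        d = pairwise_rmsd(pts)
        idx = (np.arange(len(frames)) if frame_indices is None
               else np.asarray(frame_indices))
        cond = squareform(d, checks=False) if len(frames) > 1 else np.empty(0)
        return cls(cond, idx)


def subsample_frames(times: np.ndarray, min_separation: float
                     ) -> np.ndarray:
    """Greedy earliest-first subsampling with a minimum time gap.

    Returns indices into ``times`` (assumed sorted) such that consecutive
    selected frames are at least ``min_separation`` apart; with the default
    gap of 1000 tu (50 ps) and 10 tu saves this keeps every 100th frame.
    """
    times = np.asarray(times, dtype=float)
    keep = []
    last = -np.inf
    for i, t in enumerate(times):
        if t - last >= min_separation or not keep:
            keep.append(i)
            last = t
    return np.array(keep, dtype=int)


@dataclass(frozen=True)
class ClusterResult:
    """Partition of structures at one RMSD cutoff."""

    cutoff: float
    clusters: tuple[tuple[int, ...], ...]   # sorted by size desc, then index
    centroids: tuple[int, ...]              # one member index per cluster

    @property
    def n_structures(self) -> int:
        return sum(len(c) for c in self.clusters)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def largest_fraction(self) -> float:
        return len(self.clusters[0]) / self.n_structures

    @property
    def representative(self) -> int:
        """Centroid of the largest cluster: the overall representative."""
        return self.centroids[0]


def single_linkage(dist: DistanceMatrix | np.ndarray,
                   cutoff: float) -> ClusterResult:
    """Single-linkage clusters: components of the graph with RMSD < cutoff.

    Agglomerating while the minimum inter-cluster (closest-member) distance
    is below the cutoff is equivalent to taking connected components of the
    thresholded distance graph, which is how it is computed here.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    d = dist.dense() if isinstance(dist, DistanceMatrix) else np.asarray(dist)
    n = d.shape[0]
    adj = csr_matrix((d < cutoff) & ~np.eye(n, dtype=bool))
    n_comp, labels = connected_components(adj, directed=False)
    groups: list[list[int]] = [[] for _ in range(n_comp)]
    for i, lab in enumerate(labels):
        groups[lab].append(i)
    groups.sort(key=lambda g: (-len(g), g[0]))
    cents = tuple(centroid(g, d) for g in groups)
    return ClusterResult(float(cutoff), tuple(tuple(g) for g in groups),
                         cents)


def centroid(members, dist: np.ndarray) -> int:
    """Member minimising total distance to the rest (ties: lowest index)."""
    members = list(members)
    if not members:
        raise ValueError("empty cluster")
    sub = dist[np.ix_(members, members)]
    sums = sub.sum(axis=1)
    return int(members[int(np.argmin(sums))])


def cluster_curve(dist: DistanceMatrix | np.ndarray,
                  cutoffs: np.ndarray) -> np.ndarray:
    """(cutoff, n_clusters) pairs for an ascending list of cutoffs."""
    cutoffs = np.asarray(cutoffs, dtype=float)
    if np.any(np.diff(cutoffs) < 0):
        raise ValueError("cutoffs must be ascending")
    d = dist.dense() if isinstance(dist, DistanceMatrix) else np.asarray(dist)
    n = d.shape[0]
    out = np.empty((len(cutoffs), 2))
    for i, c in enumerate(cutoffs):
        adj = csr_matrix((d < c) & ~np.eye(n, dtype=bool))
        out[i] = (c, connected_components(adj, directed=False)[0])
    return out


def suggest_cutoff(curve: np.ndarray) -> float:
    """Knee of the cutoff-vs-cluster-count curve.

    Picks the cutoff farthest (in the normalised plane) from the chord
    joining the curve's endpoints: past the steep descent where similar
    structures merge, before the flat tail where unlike ones would.
    """
    c = np.asarray(curve, dtype=float)
    if len(c) < 3:
        return float(c[-1, 0])
    x = (c[:, 0] - c[0, 0]) / max(c[-1, 0] - c[0, 0], 1e-12)
    y = (c[:, 1] - c[-1, 1]) / max(c[0, 1] - c[-1, 1], 1e-12)
    # distance from the line through (0, 1) and (1, 0)
    dist = np.abs(x + y - 1.0)
    return float(c[int(np.argmax(dist)), 0])


def representative_fraction(result: ClusterResult) -> float:
    """|largest cluster| / number of clustered structures."""
    return result.largest_fraction
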