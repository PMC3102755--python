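"""Stage 3: conformational ensembles.

RMSD-cutoff structural clustering (the iterative neighbor-count algorithm
standard in the simulation ecosystem: repeatedly take the conformer with
the most neighbors within the cutoff as a cluster center and remove it with
its neighbors), basin extraction from the free-energy landscape, and the
integration of the two into labeled conformational ensembles (A, B, C, …)
— a cluster and a basin are linked when more than half of the cluster's
frames project into the basin's bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structio import ConformerSet
from .essential_dynamics import FELGrid

__all__ = [
    "ClusterSet",
    "BasinSet",
    "EnsembleLabeling",
    "pairwise_rmsd_matrix",
    "gromos_cluster",
    "find_basins",
    "integrate_ensembles",
]


@dataclass
class ClusterSet:
    """Partition of frames into RMSD-cutoff clusters, ordered by population."""

    assignment: np.ndarray  # per-frame cluster id; cluster 0 most populated
    centers: np.ndarray  # central frame index per cluster
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return len(self.centers)

    def populations(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.n_clusters)

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == cluster)


@dataclass
class BasinSet:
    """Basins of a free-energy landscape.

    ``labels`` assigns each grid bin a basin id (−1 = unassigned/masked);
    ``minima`` lists (row, col, ΔG) per basin in basin-id order.
    """

    labels: np.ndarray
    minima: list[tuple[int, int, float]]
    depth_cut: float
    found: bool = True

    @property
    def n_basins(self) -> int:
        return len(self.minima)


@dataclass
class EnsembleLabeling:
    """Clusters and basins merged into labeled conformational ensembles."""

    labels: dict[str, np.ndarray]  # label -> frame indices
    links: dict[str, tuple[int, int]]  # label -> (cluster id, basin id)
    unmatched_clusters: list[int]
    unmatched_basins: list[int]
    congruence: float

    @property
    def n_labels(self) -> int:
        return len(self.labels)

    def to_frame(self, n_frames: int) -> pd.DataFrame:
        lab = np.array(["-"] * n_frames, dtype=object)
        for name, idx in self.labels.items():
            lab[idx] = name
        return pd.DataFrame({"frame": np.arange(n_frames), "ensemble": lab})


# ---------------------------------------------------------------------------
# Pairwise RMSD and clustering
# ---------------------------------------------------------------------------

def pairwise_rmsd_matrix(cs: ConformerSet, selection=None) -> np.ndarray:
    """All-pairs minimum (superposed) RMSD over the selection, batched.

    Uses the closed-form Kabsch RMSD: for centered frames X_i, X_j,
    rmsd² = (tr X_iᵀX_i + tr X_jᵀX_j − 2 Σ_k σ_k±) / n, where σ_k are the
    singular values of X_iᵀX_j with the smallest sign-flipped when the
    optimal orthogonal transform would be a reflection.
    """
    if selection is None:
        selection = np.arange(cs.n_atoms)
    X = cs.frames[:, selection, :].astype(float)
    X = X - X.mean(axis=1, keepdims=True)
    F, n, _ = X.shape
    E = np.einsum("fij,fij->f", X, X)
    H = np.einsum("fai,gaj->fgij", X, X)  # (F, F, 3, 3)
    U, S, Vt = np.linalg.svd(H)
    signs = np.sign(np.linalg.det(U) * np.linalg.det(Vt))
    traces = S[..., 0] + S[..., 1] + signs * S[..., 2]
    sq = (E[:, None] + E[None, :] - 2.0 * traces) / n
    np.fill_diagonal(sq, 0.0)
    return np.sqrt(np.clip(sq, 0.0, None))


def gromos_cluster(cs: ConformerSet, selection=None, cutoff: float = 1.0) -> ClusterSet:
    """Iterative neighbor-count clustering under a pairwise-RMSD cutoff.

    At each round the remaining frame with the most remaining neighbors
    within ``cutoff`` (ties → lowest frame index) becomes a cluster
    center; it and its neighbors are removed.  Every frame is assigned, so
    populations sum to the frame count.  Clusters are renumbered by
    descending population (ties → earlier center).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    D = pairwise_rmsd_matrix(cs, selection)
    F = D.shape[0]
    neighbors = D <= cutoff
    remaining = np.ones(F, dtype=bool)
    assignment = np.full(F, -1)
    centers = []
    cid = 0
    while remaining.any():
        counts = (neighbors & remaining[None, :] & remaining[:, None]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes the first maximum
        members = np.flatnonzero(neighbors[center] & remaining)
        assignment[members] = cid
        centers.append(center)
        remaining[members] = False
        cid += 1
    pops = np.bincount(assignment, minlength=cid)
    order = np.lexsort((centers, -pops))
    relabel = np.empty(cid, dtype=int)
    relabel[order] = np.arange(cid)
    return ClusterSet(
        assignment=relabel[assignment],
        centers=np.asarray(centers)[order],
        cutoff=cutoff,
    )


# ---------------------------------------------------------------------------
# Basins
# ---------------------------------------------------------------------------

_NEIGHBOR_OFFSETS = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]


def _smooth(grid: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """3×3 box average over unmasked bins (masked bins stay masked)."""
    out = np.full_like(grid, np.inf)
    rows, cols = grid.shape
    acc = np.zeros_like(grid)
    cnt = np.zeros_like(grid)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            src = grid[
                max(0, -di) : rows - max(0, di), max(0, -dj) : cols - max(0, dj)
            ]
            msk = ~mask[
                max(0, -di) : rows - max(0, di), max(0, -dj) : cols - max(0, dj)
            ]
            acc[max(0, di) : rows - max(0, -di), max(0, dj) : cols - max(0, -dj)] += np.where(msk, src, 0.0)
            cnt[max(0, di) : rows - max(0, -di), max(0, dj) : cols - max(0, -dj)] += msk
    ok = (~mask) & (cnt > 0)
    out[ok] = acc[ok] / cnt[ok]
    return out


def find_basins(fel: FELGrid, depth_cut: float | None = None, smooth: bool = True) -> BasinSet:
    """Basins: flood fill of low-energy bins around local minima.

    Local minima of the (optionally 3×3-smoothed) grid with ΔG within
    ``depth_cut`` (kJ/mol, default 1 kT) of the global minimum seed the
    basins; every unmasked bin within the depth cut is assigned to exactly
    one minimum by an ascending watershed over the 8-neighborhood, with
    saddle-sharing bins going to the lower minimum (ties to the earlier,
    row-major, minimum).  Returns an empty BasinSet with ``found=False``
    when no bin lies below the cut.
    """
    if depth_cut is None:
        depth_cut = fel.kT
    mask = fel.mask
    if mask.all():
        raise ValueError("free-energy grid has no occupied bins")
    grid = _smooth(fel.energy, mask) if smooth else np.where(mask, np.inf, fel.energy)
    gmin = grid[~mask].min()
    threshold = gmin + depth_cut
    eligible = (~mask) & (grid <= threshold)
    if not eligible.any():
        return BasinSet(labels=np.full(grid.shape, -1), minima=[], depth_cut=depth_cut, found=False)

    rows, cols = grid.shape

    def nbrs(i, j):
        for di, dj in _NEIGHBOR_OFFSETS:
            a, b = i + di, j + dj
            if 0 <= a < rows and 0 <= b < cols and not mask[a, b]:
                yield a, b

    # minima: no unmasked neighbor is lower, and no earlier (row-major)
    # neighbor is equal — so a flat plateau yields a single minimum
    minima: list[tuple[int, int, float]] = []
    is_min = np.zeros(grid.shape, dtype=bool)
    for i in range(rows):
        for j in range(cols):
            if not eligible[i, j]:
                continue
            ok = True
            for a, b in nbrs(i, j):
                if grid[a, b] < grid[i, j] or (
                    grid[a, b] == grid[i, j] and (a, b) < (i, j)
                ):
                    ok = False
                    break
            if ok:
                is_min[i, j] = True
                minima.append((i, j, float(grid[i, j])))

    labels = np.full(grid.shape, -1)
    for bid, (i, j, _) in enumerate(minima):
        labels[i, j] = bid
    # ascending watershed over eligible bins
    order = sorted(
        ((i, j) for i in range(rows) for j in range(cols) if eligible[i, j]),
        key=lambda ij: (grid[ij], ij),
    )
    min_energy = {bid: g for bid, (_, _, g) in enumerate(minima)}
    for i, j in order:
        if labels[i, j] != -1:
            continue
        candidates = {
            labels[a, b] for a, b in nbrs(i, j) if labels[a, b] != -1
        }
        if candidates:
            labels[i, j] = min(candidates, key=lambda b: (min_energy[b], b))
    return BasinSet(labels=labels, minima=minima, depth_cut=depth_cut)


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def integrate_ensembles(
    clusters: ClusterSet,
    basins: BasinSet,
    p2: np.ndarray,
    fel: FELGrid,
    match_fraction: float = 0.5,
) -> EnsembleLabeling:
    """Link clusters with free-energy basins into labeled ensembles.

    A cluster matches a basin when strictly more than ``match_fraction``
    of its frames fall into the basin's bins.  Matched pairs become labels
    A, B, … in order of descending cluster population; unmatched clusters
    and basins are listed.  The congruence score is the fraction of all
    frames that belong to a matched cluster *and* lie inside its linked
    basin.
    """
    p2 = np.asarray(p2, dtype=float)
    if p2.shape[0] != clusters.assignment.size:
        raise ValueError("projections and cluster assignment disagree on frame count")
    bi, bj = fel.bin_of(p2)
    frame_basin = basins.labels[bi, bj]

    links: dict[str, tuple[int, int]] = {}
    labels: dict[str, np.ndarray] = {}
    unmatched_clusters: list[int] = []
    matched_basins: set[int] = set()
    congruent = 0
    next_label = 0
    for cid in range(clusters.n_clusters):  # already population-ordered
        members = clusters.members(cid)
        fb = frame_basin[members]
        fb = fb[fb >= 0]
        matched = None
        if fb.size:
            ids, counts = np.unique(fb, return_counts=True)
            best = int(np.argmax(counts))
            if counts[best] > match_fraction * members.size:
                matched = int(ids[best])
        if matched is None:
            unmatched_clusters.append(cid)
            continue
        name = chr(ord("A") + next_label) if next_label < 26 else f"Z{next_label}"
        next_label += 1
        labels[name] = members
        links[name] = (cid, matched)
        matched_basins.add(matched)
        congruent += int(np.sum(frame_basin[members] == matched))
    unmatched_basins = [b for b in range(basins.n_basins) if b not in matched_basins]
    return EnsembleLabeling(
        labels=labels,
        links=links,
        unmatched_clusters=unmatched_clusters,
        unmatched_basins=unmatched_basins,
        congruence=congruent / max(1, clusters.assignment.size),
    )
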