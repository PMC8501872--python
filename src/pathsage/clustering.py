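"""Fixed-radius clustering and representative-frame selection.

``fixed_radius_cluster`` is the sequential-seeding scheme used to carve a
transition path into metastable substates: walking through the items in
order, an item joins the nearest existing cluster if its distance to that
cluster's centroid is below the radius, otherwise it founds a new cluster.
After each full pass the centroids are recomputed as medoids and the
assignment pass repeats until stable.  Because items are visited in path
order, well-separated metastable segments come out as contiguous clusters.

``representative_structure`` picks the single most representative frame of
a trajectory: average-linkage hierarchical clustering of the pairwise
(superposed) RMSD matrix, cut at the largest merge-height gap, then the
medoid of the largest cluster.
"""

from __future__ import annotations

from typing import Callable, List, Sequence, Tuple

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .geometry import superpose
from .structure import Trajectory

__all__ = ["fixed_radius_cluster", "representative_structure", "pairwise_rmsd_matrix"]


def _distance_matrix(items: Sequence, distance_fn: Callable) -> np.ndarray:
    n = len(items)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = float(distance_fn(items[i], items[j]))
            if not np.isfinite(v):
                raise ValueError(f"non-finite distance between items {i} and {j}")
            d[i, j] = d[j, i] = v
    return d


def fixed_radius_cluster(
    items: Sequence,
    distance_fn: Callable,
    radius: float,
    max_passes: int = 100,
) -> Tuple[np.ndarray, List[int]]:
    """Cluster items with the fixed-radius sequential-seeding scheme.

    Returns ``(assignments, medoid_indices)``: per-item cluster labels
    (0-based, in order of cluster creation) and the index of each
    cluster's medoid.
    """
    if len(items) == 0:
        raise ValueError("no items to cluster")
    if radius <= 0:
        raise ValueError("radius must be positive")
    d = _distance_matrix(items, distance_fn)
    n = len(items)

    # initial sequential seeding
    centroids = [0]
    assign = np.zeros(n, dtype=int)
    for i in range(1, n):
        dists = [d[i, c] for c in centroids]
        j = int(np.argmin(dists))
        if dists[j] < radius:
            assign[i] = j
        else:
            centroids.append(i)
            assign[i] = len(centroids) - 1

    for _ in range(max_passes):
        # medoid update
        new_centroids = []
        for c in range(len(centroids)):
            members = np.where(assign == c)[0]
            sub = d[np.ix_(members, members)]
            new_centroids.append(int(members[np.argmin(sub.sum(axis=1))]))
        # reassignment (items may still found new clusters if they fall
        # outside every radius)
        new_assign = np.empty(n, dtype=int)
        cents = list(new_centroids)
        for i in range(n):
            dists = [d[i, c] for c in cents]
            j = int(np.argmin(dists))
            if dists[j] < radius or len(cents) >= n:
                new_assign[i] = j
            else:
                cents.append(i)
                new_assign[i] = len(cents) - 1
        stable = len(cents) == len(centroids) and np.array_equal(new_assign, assign)
        assign, centroids = new_assign, cents
        if stable:
            break
    # drop empty clusters and relabel in order of first appearance
    labels = []
    remap = {}
    for a in assign:
        if a not in remap:
            remap[a] = len(remap)
            labels.append(centroids[a])
    assign = np.array([remap[a] for a in assign])
    return assign, labels


def pairwise_rmsd_matrix(traj: Trajectory, selection: str = "name CA") -> np.ndarray:
    """Pairwise post-superposition RMSD between all frame pairs."""
    mask = traj.mask(selection)
    coords = traj.coords[:, mask, :]
    n = coords.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                _, _, rmsd = superpose(coords[j], coords[i])
            except ValueError:
                rmsd = float(np.sqrt(np.mean(np.sum((coords[j] - coords[i]) ** 2, axis=1))))
            d[i, j] = d[j, i] = rmsd
    return d


def representative_structure(
    traj: Trajectory,
    selection: str = "name CA",
    metric: str = "rmsd",
) -> int:
    """Index of the most representative frame of a trajectory.

    Average-linkage clustering of the pairwise RMSD matrix, cut at the
    largest gap between successive merge heights (a proxy for the most
    stable cluster count); the medoid of the largest cluster is returned.
    Identical frames collapse to frame 0.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    if metric != "rmsd":
        raise ValueError(f"unsupported metric {metric!r}")
    d = pairwise_rmsd_matrix(traj, selection)
    if np.allclose(d, 0.0, atol=1e-12):
        return 0
    Z = linkage(squareform(d, checks=False), method="average")
    heights = Z[:, 2]
    if len(heights) >= 2:
        gaps = np.diff(heights)
        cut_idx = int(np.argmax(gaps))
        threshold = 0.5 * (heights[cut_idx] + heights[cut_idx + 1])
        labels = fcluster(Z, t=threshold, criterion="distance")
    else:
        labels = np.ones(traj.n_frames, dtype=int)
    counts = np.bincount(labels)
    biggest = int(np.argmax(counts))
    members = np.where(labels == biggest)[0]
    sub = d[np.ix_(members, members)]
    return int(members[np.argmin(sub.sum(axis=1))])
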