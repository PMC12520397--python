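"""Local clustering and feature-point sampling in whitened space.

The 2-D whitened log-difference samples are condensed into k clusters by a
bounded variant of k-means: centers are seeded as means of contiguous windows
of the samples in their raster order, and each sample only competes among the
±r centers neighboring its current center index.  Iteration stops once fewer
than 1% of samples change label.  Sampling m members per cluster then yields
the reduced point set handed to FastICA; the shrinkage (n → ≤ k·m points) is
what stabilizes the fixed-point iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ClusterState",
    "FeatureSet",
    "init_centers",
    "init_labels",
    "assign_labels",
    "update_centers",
    "cluster",
    "sample_feature_points",
]


@dataclass
class ClusterState:
    centers: np.ndarray  # k×2
    labels: np.ndarray  # length n, ints in [0, k)
    k: int
    r: int
    iteration: int
    changed_fraction: float
    converged: bool


@dataclass
class FeatureSet:
    points: np.ndarray  # (≤ k·m)×2
    m: int
    source_indices: np.ndarray  # provenance into the clustered sample array
    seed: int | None


def _window_bounds(n: int, k: int) -> np.ndarray:
    """Boundaries of k contiguous windows of width ⌊n/k⌋; tail goes to the last."""
    w = n // k
    bounds = np.arange(0, k + 1) * w
    bounds[-1] = n
    return bounds


def init_centers(Z: np.ndarray, k: int) -> np.ndarray:
    """Seed k centers evenly along the sample order.

    Center i is the mean of the i-th contiguous window of ⌊n/k⌋ samples taken
    in their given (raster) order; leftover tail samples join the last window.
    """
    n = Z.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    bounds = _window_bounds(n, k)
    return np.array([Z[bounds[i] : bounds[i + 1]].mean(axis=0) for i in range(k)])

def init_labels(n: int, k: int) -> np.ndarray:
    """Initial labels matching the seeding windows of :func:`init_centers`."""
    bounds = _window_bounds(n, k)
    labels = np.empty(n, dtype=np.intp)
    for i in range(k):
        labels[bounds[i] : bounds[i + 1]] = i
    return labels


def assign_labels(Z: np.ndarray, centers: np.ndarray, labels: np.ndarray, r: int) -> np.ndarray:
    """Reassign each sample to the nearest center within ±r of its current one.

    Candidate center indices are clipped to [0, k−1]; ties go to the lowest
    center index.
    """
    k = centers.shape[0]
    offsets = np.arange(-r, r + 1)
    cand = np.clip(labels[:, None] + offsets[None, :], 0, k - 1)
    diff = Z[:, None, :] - centers[cand]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    # candidate indices are nondecreasing along the window, so argmin's
    # first-occurrence rule realizes the lowest-index tie-break
    pick = np.argmin(d2, axis=1)
    return cand[np.arange(len(labels)), pick]


def update_centers(
    Z: np.ndarray, labels: np.ndarray, k: int, centers: np.ndarray | None = None
) -> np.ndarray:
    """Move each center to the mean of its members; empty clusters keep theirs."""
    counts = np.bincount(labels, minlength=k).astype(float)
    sums = np.zeros((k, Z.shape[1]))
    np.add.at(sums, labels, Z)
    nonempty = counts > 0
    new = np.array(centers, dtype=float, copy=True) if centers is not None else np.zeros((k, Z.shape[1]))
    new[nonempty] = sums[nonempty] / counts[nonempty, None]
    return new


def cluster(
    Z: np.ndarray,
    k: int,
    r: int = 2,
    max_iter: int = 100,
    change_tol: float = 0.01,
) -> ClusterState:
    """Alternate label assignment and center updates until fewer than
    ``change_tol`` of the samples change cluster, or ``max_iter`` is hit."""
    n = Z.shape[0]
    centers = init_centers(Z, k)
    labels = init_labels(n, k)
    changed = 1.0
    converged = False
    iteration = 0
    for iteration in range(1, max_iter + 1):
        new_labels = assign_labels(Z, centers, labels, r)
        changed = float(np.mean(new_labels != labels))
        labels = new_labels
        centers = update_centers(Z, labels, k, centers)
        if changed < change_tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"local clustering did not reach <{change_tol:.0%} label changes "
            f"within {max_iter} iterations (last change fraction {changed:.4f})",
            stacklevel=2,
        )
    return ClusterState(
        centers=centers,
        labels=labels,
        k=k,
        r=r,
        iteration=iteration,
        changed_fraction=changed,
        converged=converged,
    )


def sample_feature_points(
    Z: np.ndarray, state: ClusterState, m: int = 3, seed: int | None = None
) -> FeatureSet:
    """Draw m members per cluster uniformly without replacement.

    Clusters with fewer than m members contribute all of their points; empty
    clusters contribute none.  Deterministic under a fixed seed.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    rng = np.random.default_rng(seed)
    order = np.argsort(state.labels, kind="stable")
    counts = np.bincount(state.labels, minlength=state.k)
    bounds = np.concatenate([[0], np.cumsum(counts)])
    chosen: list[np.ndarray] = []
    for i in range(state.k):
        members = order[bounds[i] : bounds[i + 1]]
        if len(members) == 0:
            continue
        if len(members) <= m:
            chosen.append(members)
        else:
            chosen.append(rng.choice(members, size=m, replace=False))
    idx = np.concatenate(chosen) if chosen else np.empty(0, dtype=np.intp)
    return FeatureSet(points=Z[idx], m=m, source_indices=idx, seed=seed)
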