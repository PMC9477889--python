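"""Density-Peaks clustering with automatic center selection by the ρδ index.

Every point gets a local density ρ (Gaussian-kernel sum over all other
points) and a distance δ to its nearest strictly-denser neighbor n_up; the
global density maximum instead takes the largest distance to any point and
points to itself. Cluster centers are the K points with the largest index
λ = ρδ; every other point inherits the label of n_up, processed in
decreasing-density order so the label is always already assigned.

Distances follow the squared-Euclidean convention d_ij = (y_i−y_j)'(y_i−y_j),
and the kernel cutoff dc is read from the same sorted squared-distance list,
so the kernel argument d_ij/dc is internally consistent. ``metric="euclidean"``
switches to the root convention of the original density-peaks formulation.

Density ties are broken by point index (lower index counts as denser), which
makes the density maximum unique and the δ/n_up definitions total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DPState",
    "pairwise_distances",
    "cutoff_distance",
    "local_density",
    "delta_neighbor",
    "dp_index",
    "select_centers",
    "assign_labels",
    "dp_cluster",
]


@dataclass
class DPState:
    """Per-point quantities of one density-peaks run."""

    D: np.ndarray  # n×n pairwise distances
    dc: float
    rho: np.ndarray
    delta: np.ndarray
    n_up: np.ndarray  # index of nearest denser neighbor (self for the density max)
    lam: np.ndarray  # λ = ρδ
    centers: np.ndarray  # K point indices, in decreasing-λ order


def pairwise_distances(Y: np.ndarray, metric: str = "squared") -> np.ndarray:
    """All pairwise distances of the feature rows.

    ``squared`` (default) is the literal (y_i−y_j)'(y_i−y_j); ``euclidean``
    takes the square root. Computed by explicit differencing (not the Gram
    trick) so the matrix is exactly symmetric with an exactly zero diagonal.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    diff = Y[:, None, :] - Y[None, :, :]
    D = (diff**2).sum(axis=-1)
    if metric == "euclidean":
        D = np.sqrt(D)
    elif metric != "squared":
        raise ValueError(f"unknown metric {metric!r}")
    return D


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def cutoff_distance(D: np.ndarray, t: float, rank_basis: str = "pairs") -> float:
    """Cutoff dc = the rank-round(count·t) smallest pairwise distance.

    ``count`` is the number of distinct pairs M = n(n−1)/2 (default) or the
    number of points n (``rank_basis="points"``); the rank is clamped to
    [1, M]. t is the cutoff-distance index, typically 0.01–0.02.
    """
    if not (0 < t < 1):
        raise ValueError(f"cutoff index t must be in (0, 1), got {t}")
    if not (0.01 <= t <= 0.02):
        warnings.warn(f"cutoff index t={t} outside the usual 0.01–0.02 range", stacklevel=2)
    n = D.shape[0]
    d_sort = np.sort(D[np.triu_indices(n, k=1)])
    M = d_sort.size
    if M == 0:
        raise ValueError("need at least 2 points")
    count = M if rank_basis == "pairs" else n
    if rank_basis not in ("pairs", "points"):
        raise ValueError(f"unknown rank_basis {rank_basis!r}")
    rank = min(max(_round_half_away(count * t), 1), M)
    dc = float(d_sort[rank - 1])
    if dc == 0.0:
        positive = d_sort[d_sort > 0]
        if positive.size == 0:
            warnings.warn("all pairwise distances are zero; dc set to tiny", stacklevel=2)
            return float(np.finfo(float).tiny)
        warnings.warn("cutoff rank fell on a zero distance; using smallest positive", stacklevel=2)
        dc = float(positive[0])
    return dc


def local_density(D: np.ndarray, dc: float) -> np.ndarray:
    """Gaussian-kernel local density ρ_i = Σ_{j≠i} exp(−(d_ij/dc)²) − 1.

    Implemented as the full-row kernel sum minus 2: the j = i term
    contributes exp(0) = 1, so the two forms are identical.
    """
    if dc <= 0:
        raise ValueError(f"dc must be positive, got {dc}")
    K = np.exp(-((D / dc) ** 2))
    return K.sum(axis=1) - 2.0


def _density_order(rho: np.ndarray) -> np.ndarray:
    """Point indices in decreasing density, ties broken by lower index."""
    n = rho.shape[0]
    return np.lexsort((np.arange(n), -rho))


def delta_neighbor(D: np.ndarray, rho: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """δ and the nearest-denser neighbor n_up for every point.

    The (tie-broken) density maximum gets δ = max_j d_ij and n_up = itself;
    every other point gets the minimum distance to a denser point, with
    distance ties resolved toward the denser candidate.
    """
    n = rho.shape[0]
    order = _density_order(rho)
    delta = np.empty(n)
    n_up = np.empty(n, dtype=int)
    top = order[0]
    delta[top] = D[top].max() if n > 1 else 0.0
    n_up[top] = top
    for k in range(1, n):
        i = order[k]
        candidates = order[:k]
        dists = D[i, candidates]
        j = int(np.argmin(dists))  # first minimum → densest among ties
        delta[i] = dists[j]
        n_up[i] = candidates[j]
    return delta, n_up


def dp_index(rho: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """The center-selection index λ = ρδ, elementwise."""
    rho = np.asarray(rho, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if rho.shape != delta.shape:
        raise ValueError("rho and delta must have the same shape")
    return delta * rho


def select_centers(lam: np.ndarray, K: int, rho: np.ndarray | None = None) -> np.ndarray:
    """Indices of the K largest-λ points, in decreasing λ order.

    Ties are broken by larger ρ (when given), then by lower index.
    """
    n = lam.shape[0]
    if K > n:
        raise ValueError(f"K={K} exceeds number of points {n}")
    idx = np.arange(n)
    keys = (idx, -lam) if rho is None else (idx, -rho, -lam)
    return np.lexsort(keys)[:K]


def assign_labels(
    rho: np.ndarray,
    n_up: np.ndarray,
    centers: np.ndarray,
    D: np.ndarray | None = None,
) -> np.ndarray:
    """Propagate labels from centers down the density ordering.

    Centers get labels 1..K in the order given (decreasing λ); non-centers,
    visited in decreasing ρ, inherit the label of their denser neighbor.
    A self-pointing non-center (possible only for the density maximum when
    it was not selected as a center) is assigned to its nearest center.
    """
    n = rho.shape[0]
    labels = np.zeros(n, dtype=int)
    for rank, c in enumerate(centers, start=1):
        labels[c] = rank
    for i in _density_order(rho):
        if labels[i] != 0:
            continue
        j = int(n_up[i])
        if j == i:
            if D is None:
                raise ValueError("self-pointing non-center needs D to find nearest center")
            warnings.warn(
                "density maximum is not a center; assigning it to the nearest center",
                stacklevel=2,
            )
            j = int(np.asarray(centers)[np.argmin(D[i, centers])])
        if labels[j] == 0:
            raise RuntimeError("label propagation hit an unlabeled denser neighbor")
        labels[i] = labels[j]
    return labels


def dp_cluster(
    Y: np.ndarray,
    t: float = 0.015,
    K: int = 4,
    metric: str = "squared",
    rank_basis: str = "pairs",
) -> tuple[np.ndarray, DPState]:
    """One full density-peaks pass over the feature rows Y.

    Returns the 1..K label vector and the DPState with every per-point
    quantity (useful for decision-graph plots and for the merge step, which
    needs the center exemplars).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n = Y.shape[0]
    if n < K:
        raise ValueError(f"need at least K={K} points, got {n}")
    D = pairwise_distances(Y, metric=metric)
    dc = cutoff_distance(D, t, rank_basis=rank_basis)
    rho = local_density(D, dc)
    delta, n_up = delta_neighbor(D, rho)
    lam = dp_index(rho, delta)
    centers = select_centers(lam, K, rho)
    labels = assign_labels(rho, n_up, centers, D)
    state = DPState(D=D, dc=dc, rho=rho, delta=delta, n_up=n_up, lam=lam, centers=centers)
    return labels, state
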