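"""Cluster merging: fixes the number of units without user input.

Initial clustering deliberately over-splits (K is an upper bound on the
number of units a sparse electrode sees); similar clusters are then fused.
Similarity of clusters a, b is the Davies–Bouldin-style ratio

    R_ab = (CP_a + CP_b) / SP_ab

of their compactness (mean member distance to the cluster center, plain
Euclidean norm) to their separation (distance between the centers). Rounds
repeat: recompute R, set the threshold Rth = α · mean(R) over cluster pairs,
merge the most similar pair if R > Rth, keep the surviving exemplar as the
merged center. Because Rth is proportional to the mean with α > 1, merging
can never fire at K = 2, so the loop terminates with K ≥ 2 whenever it
starts there.

"Center" here is the density-peaks exemplar point, not the centroid — the
merge rule explicitly keeps the absorbing cluster's exemplar. Pass
``use_centroid=True`` to use cluster means instead for both CP and SP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MergeReport",
    "compactness",
    "separation",
    "similarity",
    "merge_threshold",
    "merge_clusters",
]


@dataclass
class MergeReport:
    """Audit trail of the merge stage: one R matrix and threshold per round
    (including the final round that decided to stop), the executed merges as
    (kept_label, absorbed_label, round) in pre-merge label terms, and the
    final cluster count."""

    R_history: list[np.ndarray] = field(default_factory=list)
    Rth_history: list[float] = field(default_factory=list)
    merges: list[tuple[int, int, int]] = field(default_factory=list)
    final_K: int = 0


def compactness(Y: np.ndarray, L: np.ndarray, centers_pos: np.ndarray) -> np.ndarray:
    """CP_k: mean Euclidean distance of cluster members to their center.

    ``centers_pos[k-1]`` is the center coordinate of cluster k (labels 1..K).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    L = np.asarray(L, dtype=int)
    centers_pos = np.atleast_2d(np.asarray(centers_pos, dtype=float))
    K = centers_pos.shape[0]
    cp = np.empty(K)
    for k in range(1, K + 1):
        members = Y[L == k]
        if members.shape[0] == 0:
            raise ValueError(f"cluster {k} is empty")
        cp[k - 1] = float(np.mean(np.linalg.norm(members - centers_pos[k - 1], axis=1)))
    return cp


def separation(centers_pos: np.ndarray) -> np.ndarray:
    """SP_ab: Euclidean distance between cluster centers, all pairs."""
    C = np.atleast_2d(np.asarray(centers_pos, dtype=float))
    if C.shape[0] < 2:
        raise ValueError("need at least 2 centers")
    diff = C[:, None, :] - C[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def similarity(CP: np.ndarray, SP: np.ndarray) -> np.ndarray:
    """R_ab = (CP_a + CP_b)/SP_ab for a ≠ b; coincident centers give +inf.

    The diagonal is set to 0 and carries no meaning.
    """
    CP = np.asarray(CP, dtype=float)
    K = CP.shape[0]
    R = np.zeros((K, K))
    for a in range(K):
        for b in range(a + 1, K):
            R[a, b] = R[b, a] = (CP[a] + CP[b]) / SP[a, b] if SP[a, b] > 0 else np.inf
    return R


def merge_threshold(
    R: np.ndarray, alpha: float = 1.6, denominator: str = "pairs", n_points: int | None = None
) -> float:
    """Rth = α × mean of the upper-triangle similarities.

    ``denominator="pairs"`` (default) divides by the K(K−1)/2 cluster pairs;
    ``"literal_n"`` divides by n(n−1)/2 with n the point count (an
    alternative reading of the printed formula, for replication studies).
    """
    K = R.shape[0]
    if K < 2:
        raise ValueError("threshold needs at least 2 clusters")
    total = float(R[np.triu_indices(K, k=1)].sum())
    if denominator == "pairs":
        denom = K * (K - 1) / 2
    elif denominator == "literal_n":
        if n_points is None:
            raise ValueError("literal_n denominator needs n_points")
        denom = n_points * (n_points - 1) / 2
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return alpha * total / denom


def _upper_argmax(R: np.ndarray) -> tuple[int, int]:
    """Largest upper-triangle entry; ties go to the lexicographically first pair."""
    K = R.shape[0]
    best, pair = -np.inf, (0, 1)
    for a in range(K):
        for b in range(a + 1, K):
            if R[a, b] > best:
                best, pair = R[a, b], (a, b)
    return pair


def merge_clusters(
    Y: np.ndarray,
    L: np.ndarray,
    centers: np.ndarray,
    alpha: float = 1.6,
    use_centroid: bool = False,
    denominator: str = "pairs",
) -> tuple[np.ndarray, MergeReport]:
    """Iteratively fuse the most similar cluster pair while R_max > Rth.

    ``centers`` are the density-peaks exemplar point indices, ordered by the
    1..K labels in L. On a merge, the cluster with more members absorbs the
    other (ties: lower label) and keeps its exemplar; CP/SP/R/Rth are
    recomputed each round. An infinite similarity (coincident exemplars)
    merges unconditionally while K > 2. Surviving labels are finally
    renumbered 1..final_K in increasing original-label order.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    L = np.asarray(L, dtype=int).copy()
    if alpha <= 1:
        raise ValueError(f"alpha must exceed 1, got {alpha}")
    active = sorted(int(k) for k in np.unique(L))
    exemplar = {k: int(c) for k, c in zip(active, np.asarray(centers, dtype=int))}
    report = MergeReport()

    round_no = 0
    while len(active) >= 2:
        round_no += 1
        if use_centroid:
            centers_pos = np.array([Y[L == k].mean(axis=0) for k in active])
        else:
            centers_pos = np.array([Y[exemplar[k]] for k in active])
        relabel = {k: i + 1 for i, k in enumerate(active)}
        Lc = np.array([relabel[k] for k in L])
        CP = compactness(Y, Lc, centers_pos)
        SP = separation(centers_pos)
        R = similarity(CP, SP)
        finite = R[np.triu_indices(len(active), k=1)]
        Rth = merge_threshold(R, alpha, denominator=denominator, n_points=Y.shape[0])
        report.R_history.append(R)
        report.Rth_history.append(Rth)

        a_i, b_i = _upper_argmax(R)
        r_max = R[a_i, b_i]
        fire = r_max > Rth or (np.isinf(r_max) and len(active) > 2)
        if not fire:
            break
        la, lb = active[a_i], active[b_i]
        na, nb = int(np.sum(L == la)), int(np.sum(L == lb))
        keep, gone = (la, lb) if (na, -la) >= (nb, -lb) else (lb, la)
        L[L == gone] = keep
        report.merges.append((keep, gone, round_no))
        active.remove(gone)
        exemplar.pop(gone)

    final_map = {k: i + 1 for i, k in enumerate(active)}
    L_final = np.array([final_map[k] for k in L])
    report.final_K = len(active)
    return L_final, report
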