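"""Naive double-loop reference implementation of density-peaks clustering.

Written independently of the package's vectorized implementation, but with
the same arithmetic term ordering (e.g. the kernel row sum includes the
j = i term and subtracts 2), so agreement can be asserted exactly in
floating point, not just to a tolerance.
"""

from __future__ import annotations

import numpy as np


def reference_dp(Y: np.ndarray, t: float, K: int):
    """Return (labels, D, dc, rho, delta, n_up, lam, centers) by brute force."""
    Y = np.asarray(Y, dtype=float)
    n, dim = Y.shape

    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            diffs = [Y[i, k] - Y[j, k] for k in range(dim)]
            D[i, j] = np.array([d * d for d in diffs]).sum()

    # cutoff: rank round(M*t) (half away from zero) in the ascending pair list
    pair_d = sorted(D[i, j] for i in range(n) for j in range(i + 1, n))
    M = len(pair_d)
    rank = int(np.floor(M * t + 0.5))
    rank = min(max(rank, 1), M)
    dc = pair_d[rank - 1]

    rho = np.zeros(n)
    for i in range(n):
        ratios = [D[i, j] / dc for j in range(n)]
        rho[i] = np.array([np.exp(-(r * r)) for r in ratios]).sum() - 2.0

    order = sorted(range(n), key=lambda i: (-rho[i], i))
    delta = np.zeros(n)
    n_up = np.zeros(n, dtype=int)
    top = order[0]
    delta[top] = max(D[top, j] for j in range(n)) if n > 1 else 0.0
    n_up[top] = top
    for pos in range(1, n):
        i = order[pos]
        best_j, best_d = None, None
        for j in order[:pos]:  # all points denser than i (after tie-break)
            if best_d is None or D[i, j] < best_d:
                best_j, best_d = j, D[i, j]
        delta[i] = best_d
        n_up[i] = best_j

    lam = np.array([delta[i] * rho[i] for i in range(n)])
    centers = sorted(range(n), key=lambda i: (-lam[i], -rho[i], i))[:K]

    labels = np.zeros(n, dtype=int)
    for rank_c, c in enumerate(centers, start=1):
        labels[c] = rank_c
    for i in order:
        if labels[i] != 0:
            continue
        j = n_up[i]
        if j == i:  # density max that is not a center: nearest center
            j = min(centers, key=lambda c: D[i, c])
        labels[i] = labels[j]

    return labels, D, dc, rho, delta, n_up, lam, np.array(centers)
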