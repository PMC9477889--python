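"""Feature extraction: PCA initialization and label-supervised LDA updates.

The sorter alternates between clustering in a d-dimensional subspace and
re-estimating that subspace by linear discriminant analysis from the current
cluster labels. The discriminant criterion is the trace ratio

    J(W) = tr(W' Sb W) / tr(W' Sw W)

with Sw the raw within-class scatter sum and Sb the between-class scatter
normalized by the total point count. By default W is obtained from the
standard ratio-trace relaxation (generalized eigenproblem of (Sb, Sw)); an
optional Dinkelbach refinement solves the trace-ratio problem itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = [
    "ProjectionMatrix",
    "ScatterPair",
    "pca_init",
    "scatter_matrices",
    "lda_fit",
    "project",
    "discriminant_ratio",
]


@dataclass
class ProjectionMatrix:
    """A p×d linear map from waveform space to feature space.

    ``source`` records how it was obtained ("pca" or "lda"); PCA columns are
    orthonormal, LDA columns are generalized eigenvectors (Sw-orthogonal).
    """

    W: np.ndarray
    source: str = "pca"

    @property
    def d(self) -> int:
        return self.W.shape[1]


@dataclass
class ScatterPair:
    Sw: np.ndarray
    Sb: np.ndarray
    class_means: dict[int, np.ndarray]
    grand_mean: np.ndarray
    counts: dict[int, int]
    n: int


def _fix_signs(W: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: the largest-magnitude entry of each
    column is made positive."""
    W = W.copy()
    for j in range(W.shape[1]):
        k = int(np.argmax(np.abs(W[:, j])))
        if W[k, j] < 0:
            W[:, j] = -W[:, j]
    return W


def pca_init(X: np.ndarray, d: int) -> ProjectionMatrix:
    """Top-d principal directions of the column-centered waveform matrix."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= d:
        raise ValueError(f"need more than d={d} spikes, got {n}")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = s[0] * max(n, p) * np.finfo(float).eps if s.size and s[0] > 0 else 0.0
    rank = int(np.sum(s > tol))
    if rank < d:
        raise ValueError(f"centered data has rank {rank} < requested d={d}")
    return ProjectionMatrix(W=_fix_signs(Vt[:d].T), source="pca")


def scatter_matrices(Y: np.ndarray, L: np.ndarray) -> ScatterPair:
    """Within-class scatter (raw sum over members) and between-class scatter
    (count-weighted outer products of mean offsets, divided by total n)."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    L = np.asarray(L, dtype=int)
    if Y.shape[0] != L.shape[0]:
        raise ValueError("Y and L lengths differ")
    labels = np.unique(L)
    if set(range(1, labels.max() + 1)) - set(labels.tolist()):
        missing = sorted(set(range(1, labels.max() + 1)) - set(labels.tolist()))
        raise ValueError(f"empty cluster(s): labels {missing} have no members")
    n, p = Y.shape
    mu = Y.mean(axis=0)
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    means: dict[int, np.ndarray] = {}
    counts: dict[int, int] = {}
    for k in labels:
        Yk = Y[L == k]
        mu_k = Yk.mean(axis=0)
        means[int(k)] = mu_k
        counts[int(k)] = Yk.shape[0]
        dk = Yk - mu_k
        Sw += dk.T @ dk
        dm = mu_k - mu
        Sb += Yk.shape[0] * np.outer(dm, dm)
    Sb /= n
    return ScatterPair(Sw=Sw, Sb=Sb, class_means=means, grand_mean=mu, counts=counts, n=n)


def discriminant_ratio(W: np.ndarray, Sw: np.ndarray, Sb: np.ndarray) -> float:
    """The trace-ratio objective J(W) = tr(W'SbW)/tr(W'SwW)."""
    num = float(np.trace(W.T @ Sb @ W))
    den = float(np.trace(W.T @ Sw @ W))
    return num / den if den > 0 else np.inf


def lda_fit(
    X: np.ndarray,
    L: np.ndarray,
    d: int,
    trace_ratio: bool = False,
    reg: float = 1e-6,
) -> ProjectionMatrix:
    """Discriminant subspace from waveforms X and labels L.

    Sw is regularized by ``reg * tr(Sw)/p`` on the diagonal before the
    generalized eigenproblem (Sw can be singular for tight clusters or
    p > n). With ``trace_ratio=True``, Dinkelbach iterations refine the
    ratio-trace solution to a stationary point of J itself.
    """
    X = np.asarray(X, dtype=float)
    if np.unique(L).size < 2:
        raise ValueError("LDA needs at least 2 clusters")
    p = X.shape[1]
    if d > p:
        raise ValueError(f"d={d} exceeds waveform dimension {p}")
    pair = scatter_matrices(X, L)
    Sw, Sb = pair.Sw, pair.Sb
    tr_sw = np.trace(Sw)
    Sw_reg = Sw + (reg * tr_sw / p if tr_sw > 0 else reg) * np.eye(p)

    w, V = linalg.eigh(Sb, Sw_reg)
    W = V[:, np.argsort(w)[::-1][:d]]

    if trace_ratio:
        lam = discriminant_ratio(W, Sw_reg, Sb)
        for _ in range(100):
            w2, V2 = linalg.eigh(Sb - lam * Sw_reg)
            W = V2[:, np.argsort(w2)[::-1][:d]]
            lam_new = discriminant_ratio(W, Sw_reg, Sb)
            if abs(lam_new - lam) < 1e-12 * max(1.0, abs(lam)):
                lam = lam_new
                break
            lam = lam_new

    return ProjectionMatrix(W=_fix_signs(W), source="lda")


def project(X: np.ndarray, W: ProjectionMatrix | np.ndarray) -> np.ndarray:
    """Project column-centered waveforms into the feature subspace:
    Y = (X − mean) W."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Wm = W.W if isinstance(W, ProjectionMatrix) else np.asarray(W, dtype=float)
    if X.shape[1] != Wm.shape[0]:
        raise ValueError(f"shape mismatch: X has {X.shape[1]} columns, W has {Wm.shape[0]} rows")
    return (X - X.mean(axis=0)) @ Wm
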