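"""The full sorter: alternating LDA feature extraction and density-peaks
clustering, then cluster merging.

The loop starts from a PCA subspace, clusters the projected waveforms with
density peaks at a fixed over-split K, re-fits the discriminant subspace
from those labels, and repeats until the labeling stabilizes (or an
iteration cap is reached). Convergence is judged by permutation-matched
label agreement between successive iterations, since density-peaks center
order — and hence raw label ids — may permute between passes. A minimum
iteration count forces the subspace to actually adapt before stopping.
Merging runs once, after the loop, and determines the final unit count.

The whole procedure is deterministic: PCA, the eigenproblems, density peaks
and merging contain no random state, so repeated runs on the same input are
identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .data_io import RunConfig
from .density_peaks import DPState, dp_cluster
from .detection import SpikeWaveformMatrix
from .features import ProjectionMatrix, lda_fit, pca_init, project
from .merging import MergeReport, merge_clusters

__all__ = ["SortResult", "label_agreement", "lda_dp_sort"]


@dataclass
class SortResult:
    """Outcome of one sorting run.

    ``labels`` is the final (post-merge) 1..n_clusters assignment;
    ``pre_merge_labels`` the assignment at loop exit; ``agreement_trace``
    holds the matched label agreement of each iteration against the
    previous one (starting at iteration 2).
    """

    labels: np.ndarray
    pre_merge_labels: np.ndarray
    n_clusters: int
    iterations: int
    converged: bool
    agreement_trace: list[float]
    W: ProjectionMatrix
    features: np.ndarray
    dp_state: DPState
    merge_report: MergeReport
    config: RunConfig


def label_agreement(L: np.ndarray, L_pre: np.ndarray) -> float:
    """Maximum fraction of identically assigned points over all one-to-one
    matchings of the two labelings (optimal assignment on the contingency
    table) — 1.0 for labelings equal up to a permutation of ids."""
    L = np.asarray(L)
    L_pre = np.asarray(L_pre)
    if L.shape != L_pre.shape:
        raise ValueError("label vectors differ in length")
    a, ai = np.unique(L, return_inverse=True)
    b, bi = np.unique(L_pre, return_inverse=True)
    C = np.zeros((a.size, b.size), dtype=int)
    np.add.at(C, (ai, bi), 1)
    rows, cols = linear_sum_assignment(-C)
    return float(C[rows, cols].sum()) / L.size


def lda_dp_sort(
    X: SpikeWaveformMatrix | np.ndarray,
    config: RunConfig | None = None,
    feature_update: str = "lda",
) -> SortResult:
    """Sort aligned spike waveforms.

    ``feature_update="lda"`` is the full method; ``"none"`` freezes the
    subspace at its PCA initialization (the PCA+density-peaks ablation,
    useful as a baseline — with a frozen subspace the labeling repeats
    exactly, so the loop converges as soon as the minimum iteration count
    allows).
    """
    config = config or RunConfig()
    waves = X.waves if isinstance(X, SpikeWaveformMatrix) else np.atleast_2d(np.asarray(X, float))
    if not np.all(np.isfinite(waves)):
        raise ValueError("waveform matrix contains non-finite values")
    n = waves.shape[0]
    if n <= config.K_init:
        raise ValueError(f"need more than K_init={config.K_init} spikes, got {n}")
    if feature_update not in ("lda", "none"):
        raise ValueError(f"unknown feature_update {feature_update!r}")

    W = pca_init(waves, config.d)
    L_pre: np.ndarray | None = None
    agreement_trace: list[float] = []
    converged = False
    iterations = 0
    for ite in range(1, config.max_ite + 1):
        iterations = ite
        Y = project(waves, W)
        L, state = dp_cluster(Y, t=config.t, K=config.K_init)
        if L_pre is not None:
            agr = label_agreement(L, L_pre)
            agreement_trace.append(agr)
            if ite >= config.min_ite and agr >= config.convergence:
                converged = True
                break
        L_pre = L
        if feature_update == "lda":
            W = lda_fit(waves, L, config.d)

    labels, report = merge_clusters(Y, L, state.centers, alpha=config.alpha)
    return SortResult(
        labels=labels,
        pre_merge_labels=L,
        n_clusters=report.final_K,
        iterations=iterations,
        converged=converged,
        agreement_trace=agreement_trace,
        W=W,
        features=Y,
        dp_state=state,
        merge_report=report,
        config=config,
    )
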