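# Methods

## The sorting model

`ldadp` assigns detected extracellular spikes to putative neurons by
alternating two steps until the labeling stabilizes:

1. **Density-peaks clustering** of the spikes projected into a
   d-dimensional feature subspace. Each point i gets a local density
   ρ_i = Σ_{j≠i} exp(−(d_ij/d_c)²) − 1 and a distance δ_i to its nearest
   strictly-denser neighbor (the global density maximum instead takes its
   largest distance to any point). The K points with the largest index
   λ = ρδ become cluster exemplars; every other point, visited in
   decreasing density, inherits the label of its nearest denser neighbor.
2. **Discriminant re-estimation** of the subspace: with the current labels,
   the projection W maximizes the trace ratio
   J(W) = tr(WᵀS_b W)/tr(WᵀS_w W), where S_w is the raw within-cluster
   scatter sum and S_b the count-weighted between-cluster scatter divided
   by the total spike count.

The subspace is initialized by PCA. Iterations stop once the
permutation-matched agreement between consecutive labelings reaches a
threshold (default 0.99) — density-peaks may renumber clusters between
passes, so raw equality would be the wrong test — subject to a minimum of
5 and a maximum of 50 iterations. Non-convergence at the cap is not an
error; the last labeling proceeds to merging and the result records
`converged=False`.

After the loop, a **merge stage** determines the number of units: cluster
similarity is the Davies–Bouldin-style ratio R_ab = (CP_a + CP_b)/SP_ab
(mean member distance to the cluster exemplar, over the distance between
exemplars), and the most similar pair is fused while R_max exceeds
R_th = α · mean(R) over cluster pairs. K therefore starts at an over-split
upper bound (default 4, suitable for sparse electrodes) and the final unit
count emerges with no user input. Because R_th is proportional to the mean
with α > 1, a two-cluster configuration can never merge; the loop always
terminates with K ≥ 2 when it starts there.

## Assumptions

- Spikes are cut and aligned (absolute peak at a fixed sample), one channel,
  no electrode drift, and overlapping spikes are not decomposed — the usual
  regime for sparse probes (microwires, Utah arrays).
- Clusters need not be Gaussian or spherical (density peaks makes no
  distributional assumption), but each unit should form a contiguous
  high-density region in the feature subspace.
- The merge rule is scale-free: it compares pair similarities only against
  their mean. It therefore assumes the true units are comparably spaced in
  the feature space; a configuration in which one pair of genuine units is
  several times relatively closer than every other pair can be merged
  erroneously even when absolutely well separated. This is the method's
  main failure mode and is visible in the degradation experiments.

## Numerical conventions

- **Distances** in the clustering stage are squared Euclidean,
  d_ij = (y_i−y_j)ᵀ(y_i−y_j), and the cutoff d_c is drawn from the same
  squared-distance list, so the kernel argument is internally consistent.
  `metric="euclidean"` switches to the root convention of the original
  density-peaks formulation. The merge stage and the Davies–Bouldin metric
  use plain Euclidean norms (‖·‖₂), as their formulas state.
- **Cutoff rank**: d_c is the ascending pairwise distance of rank
  round(M·t) (half-away-from-zero, clamped to [1, M]) among the
  M = n(n−1)/2 pairs; t defaults to 0.015, the midpoint of the customary
  0.01–0.02 range. `rank_basis="points"` instead ranks by round(n·t), an
  alternative reading of the published index.
- **Density ties** are broken by point index (lower index counts denser),
  making the density maximum unique and the δ/n_up recursion total;
  center-selection ties prefer larger ρ, then lower index. All stages are
  deterministic; two runs on the same input are bit-identical.
- **The "−1" shift** in ρ is kept literally. It never changes the ρ
  ordering, but it does change λ = ρδ (ρ may even be negative for isolated
  points); the λ ranking is part of the method as published.
- **LDA solver**: the ratio-trace relaxation — generalized symmetric
  eigenproblem (S_b, S_w + εI) with ε = 10⁻⁶·tr(S_w)/p — whose top-d
  eigenvectors scipy returns S_w-normalized (vᵀS_w v = 1). This whitened
  scaling is retained deliberately: features are measured in units of
  within-cluster spread, which is what makes highly similar templates
  separable. An optional Dinkelbach refinement (`trace_ratio=True`)
  iterates to a stationary point of the trace-ratio objective itself; on
  the data used here it changes results negligibly. Eigenvector signs are
  fixed (largest-magnitude entry positive) for reproducibility.
- **Merging**: "center" is the density-peaks exemplar point, and the
  absorbing cluster keeps its exemplar (the cluster with more members
  absorbs; ties prefer the lower label). `use_centroid=True` switches both
  CP and SP to cluster means. A coincident-exemplar pair (SP = 0, R = ∞)
  merges unconditionally while K > 2. The threshold averages over the
  K(K−1)/2 cluster pairs; `denominator="literal_n"` divides by n(n−1)/2
  with n the spike count instead, for replication experiments (it makes
  the threshold vanish, so merging then always proceeds down to K = 2).
- **Convergence of label agreement** uses optimal assignment (Hungarian)
  on the contingency table, as does sorting accuracy in the metrics module.

## Detection

Traces are band-pass filtered with a 4th-order Butterworth applied
forward–backward (zero phase; the order is a package choice, configurable),
default band 300–3000 Hz. The threshold is V_th = m·median(|x|)/0.6745
(m = 4 by default; 0.6745 is the median absolute value of a unit normal,
so the quotient estimates the noise σ robustly), applied at both
polarities. Within each supra-threshold excursion the sample of maximal
|x| is the peak; windows of 64 samples are cut with the peak re-centred at
sample 20 (1-based) until stable, edge events are dropped, and peaks
within a refractory window (default 1 ms) are merged keeping the larger.
Alignment uses the literal sample peak — no sub-sample interpolation.
Extracellular detections are matched to intracellular ground-truth peaks
one-to-one, nearest first, within 0.3 ms.

## The synthetic-data generator

The generator emulates the construction of the widely used simulated
benchmark for sparse-probe sorting: a bank of spike templates, Poisson
spike trains, and background noise that is *spectrally similar to the
spikes* because it is itself a superposition of randomly timed,
randomly scaled spike shapes. Quantities it reproduces:

- **Templates**: parametric difference-of-Gaussians shapes (positive peak,
  delayed trough, optional after-wave), peak-normalized to 1 at the
  alignment sample (the trough is shrunk if it would dominate the peak, so
  the alignment convention is well defined). "low" similarity banks draw
  jittered variants of four structurally distinct base shapes and accept
  when all pairwise Pearson correlations are below 0.7 (realized ≈
  0.15–0.65, comparably low across pairs); "high" banks place templates at
  the vertices of a simplex in (trough delay, trough width, after-wave)
  parameter space and accept when all pairwise correlations are ≥ 0.85
  (realized ≈ 0.90–0.95, comparably high across pairs). The pairwise
  *homogeneity* is intentional: the benchmark's template sets are
  comparably distinct, and the scale-free merge rule is sensitive to one
  pair being relatively much closer than the rest.
- **Spike trains**: per-unit Poisson event times (default 5 Hz) with a
  2 ms dead-time deletion; a warning is raised if deletion removes more
  than half the events.
- **Noise**: a sparse superposition (0.02 events/sample, ~1.3 overlapping
  constituents per sample) of shapes from a library comprising the bank's
  own templates plus 24 random biphasic shapes, rescaled so the trace
  standard deviation equals the requested level (quoted relative to the
  unit spike peak; study levels 0.05–0.40). The sparseness keeps the noise
  covariance strongly spike-structured — the regime in which a whitened
  discriminant subspace separates similar templates but a fixed PCA
  subspace does not, matching the published behavior of the benchmark. A
  much denser superposition would be nearly Gaussian and makes highly
  similar templates unsortable by either method at level 0.2.
- **Waveform sets** (`generate_waveform_set`): template plus a noise
  segment, re-aligned on the absolute peak as the detector would, so
  alignment jitter at high noise is part of the data. Ground-truth labels
  are exact.

What the generator does **not** emulate: electrode drift, bursting
amplitude decay, overlapping-spike waveform superposition in the cut sets,
multi-channel geometry, and real spike-shape variability. Passing tests on
this data therefore demonstrate the algorithm's behavior under controlled
noise and similarity, not performance on drifting or overlap-heavy
recordings. The bursty (non-stationary) background also means a threshold
detector fires on noise bursts; detection quality on synthetic traces is
accordingly quoted as recall against the inserted ground truth.

## Parameters that matter

| parameter | default | meaning / why |
| --- | --- | --- |
| `K_init` | 4 | over-split upper bound on units per channel; sparse electrodes rarely see more than 4 |
| `d` | 3 | feature dimension; with K_init = 4 clusters, d ≤ K−1 keeps all discriminant directions informative |
| `t` | 0.015 | cutoff-distance index (fraction of sorted pairwise distances); customary range 0.01–0.02, warning outside |
| `alpha` | 1.6 | merge-threshold coefficient; must exceed 1, values above ~1.4 are customary |
| `min_ite`/`max_ite` | 5 / 50 | iteration floor (forces the subspace to adapt) and cap |
| `convergence` | 0.99 | matched label agreement that counts as "stable" |
| `band` | 300–3000 Hz | detection band-pass |
| `thresh_mult` | 4 | threshold in robust noise sigmas |
| `wave_len`/`peak_index` | 64 / 20 | samples per waveform; 1-based alignment sample |
| `refractory_ms` | 1.0 | detector dead time; the generator's spike trains use 2 ms |
| `match_tol_ms` | 0.3 | ground-truth matching tolerance |

## Problem sizes used in tests and the acceptance script

Experiments run at 3 templates × 200 spikes per cluster (600 spikes per
sort), 10 seeds per condition, noise levels 0.05–0.20 — sizes at which one
full sort takes well under a second and the complete acceptance script a
few minutes on one core. Distance matrices are formed densely
(O(n²·d) memory), which is comfortable up to a few thousand spikes per
channel; beyond that, block-wise distance computation would be the first
change to make.

## Known limitations

- The α·mean merge rule can fuse genuine units whose relative (not
  absolute) separation is an outlier; at very low noise with heterogeneous
  template discriminability this occasionally reduces K by one and costs
  about a cluster's worth of accuracy on one seed in a sweep.
- Overlapping spikes are neither detected as such nor decomposed; the
  generator records ground truth before overlap, so heavily overlapping
  events count against accuracy.
- LDA is fit on raw 64-sample waveforms; for much longer waveforms the
  S_w regularization constant may need retuning.
- The exact trace-ratio solver is exposed but not the default; the
  ratio-trace relaxation is standard practice and indistinguishable here.
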