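# ldadp — spike sorting by joint LDA / density-peaks optimization

Spike sorting assigns each detected extracellular action potential to the
neuron ("unit") that fired it. When background noise is high or two units
have similar waveforms, the classic recipe — project waveforms with PCA,
then cluster — breaks down, because PCA knows nothing about cluster
structure. `ldadp` implements a sorter that couples the two steps and lets
them improve each other:

- **Density-peaks (DP) clustering** labels the projected spikes. Each point
  gets a local density ρ (Gaussian kernel over pairwise distances, cutoff
  d_c) and a distance δ to its nearest denser neighbor; the K points with
  the largest index λ = ρδ are taken as cluster exemplars and every other
  point inherits the label of its nearest denser neighbor.
- **Linear discriminant analysis (LDA)** then re-fits the projection W to
  maximize J(W) = tr(WᵀS_bW)/tr(WᵀS_wW), the between- over within-cluster
  scatter of the *current* labels, and DP runs again in the new subspace.

The loop stops when successive labelings agree (up to label permutation) at
≥ 0.99, then a **merge stage** fuses over-split clusters: pair similarity
R_ab = (CP_a + CP_b)/SP_ab (compactness over separation) is compared
against the threshold R_th = α·mean(R), α = 1.6, and the most similar pair
merges until none exceeds the threshold. The number of units is therefore
determined automatically — the user supplies only an upper bound
(default K = 4, suited to sparse electrodes).

The package also provides spike detection (zero-phase 300–3000 Hz
Butterworth; threshold ±4·median(|x|)/0.6745; 64-sample peak-aligned
windows), evaluation metrics (permutation-matched accuracy, Davies–Bouldin
index, precision/recall against partial ground truth, template
correlation), file I/O (MAT v5/v7.3 recordings, delimited waveform
matrices, JSON results), and a synthetic-data generator that emulates the
standard simulated benchmark (template banks with controlled similarity,
Poisson spike trains, spike-spectrum-matched background noise at levels
0.05–0.40 of the spike peak) so the whole pipeline is testable without
downloads.

## Worked example

```python
import numpy as np
from ldadp import make_templates, generate_waveform_set, lda_dp_sort
from ldadp.metrics import dbi, sorting_accuracy

bank = make_templates(3, similarity="low", seed=0)   # 3 distinct spike shapes
spikes, truth = generate_waveform_set(bank, n_per_cluster=200,
                                      noise_level=0.05, seed=0)
result = lda_dp_sort(spikes)
print(result.n_clusters, result.iterations,
      sorting_accuracy(result.labels, truth), dbi(result.features, result.labels))
```

Running `python examples/01_sort_synthetic_spikes.py` (the same experiment
with narration) prints:

```
spikes sorted      : 600
iterations         : 9 (converged=True)
clusters found     : 3  (started from K_init=4)
merges executed    : 1
sorting accuracy   : 1.0000
Davies-Bouldin idx : 0.092  (lower = cleaner)
```

DP was forced to over-split into 4 clusters; the merge stage detected that
two of them were halves of one unit (their similarity exceeded 1.6× the
mean pair similarity) and fused them, recovering the true 3 units with
every spike correctly assigned. The other examples cover detection on a
continuous trace (`02`), the merge stage round by round (`03`), and noise
robustness with the frozen-PCA ablation (`04`) — on similar templates
(pairwise correlation ≈ 0.9) at noise 0.20, the adaptive subspace keeps
accuracy near 78% where the PCA baseline falls to ~57%.

A thin CLI mirrors the pipeline: `ldadp simulate | detect | cluster |
sort | evaluate` (see `ldadp --help`).

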