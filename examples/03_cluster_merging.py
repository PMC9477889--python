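"""Watch the merge stage fix the number of clusters.

Density peaks is run with a deliberately over-split K = 4 on three
well-separated feature blobs, so one blob ends up cut in two. The merge
stage then compares every cluster pair by the similarity ratio
R = (CP_a + CP_b) / SP_ab (compactness over separation) against the
threshold Rth = 1.6 x mean(R), fuses the over-split pair, and stops —
determining K = 3 with no user input.
"""

import numpy as np

from ldadp import dp_cluster, merge_clusters

rng = np.random.default_rng(7)
Y = np.vstack(
    [
        0.3 * rng.standard_normal((120, 3)),
        np.array([8.0, 0.0, 0.0]) + 0.3 * rng.standard_normal((90, 3)),
        np.array([0.0, 8.0, 0.0]) + 0.3 * rng.standard_normal((90, 3)),
    ]
)

labels, state = dp_cluster(Y, t=0.015, K=4)
print("cluster sizes before merging:", np.bincount(labels)[1:])

merged, report = merge_clusters(Y, labels, state.centers, alpha=1.6)
for rnd, (R, rth) in enumerate(zip(report.R_history, report.Rth_history), start=1):
    tri = R[np.triu_indices(R.shape[0], k=1)]
    print(f"round {rnd}: pair similarities R = {np.round(tri, 3)}  threshold Rth = {rth:.3f}")
for kept, gone, rnd in report.merges:
    print(f"  -> round {rnd}: cluster {gone} absorbed into cluster {kept}")
print("cluster sizes after merging :", np.bincount(merged)[1:])
print(f"final number of units: {report.final_K}")
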