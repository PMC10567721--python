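"""Choosing the cluster number K and the training epoch.

Scans K over 2..12 on data with 5 planted clusters, showing the silhouette
peak at the planted K with the Calinski-Harabasz index as a cross-check;
then applies the epoch-selection rule (10-epoch moving average of validation
loss between a minimum of 50 and a maximum of 150 epochs) to a simulated
loss curve.
"""

import numpy as np

from gliopatch import choose_k, early_stop_rule, gen_blobs, score_k

X, _ = gen_blobs(600, 5, dim=16, separation=8.0, seed=0)
quality = score_k(X, range(2, 13), seed=0)
print(quality.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(f"chosen K = {choose_k(quality)} (planted K = 5)")

rng = np.random.default_rng(0)
epochs = np.arange(1, 151)
loss = 0.4 + 0.6 * np.exp(-epochs / 25) + 0.002 * np.maximum(epochs - 80, 0)
loss += rng.normal(0, 0.01, 150)  # noisy validation loss with a minimum near 80
res = early_stop_rule(loss)
print(f"training stops at epoch {res.stop_epoch}; "
      f"selected model = epoch {res.selected_epoch} "
      f"(best 10-epoch window {res.best_window}, mean loss {res.best_average:.3f})")
print("-> the retained model is the last epoch of the lowest moving-average "
      "window after the 50-epoch minimum.")
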