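"""Exact-likelihood density estimation on a tabular view.

Builds a coupling flow on a 2-D correlated Gaussian, trains it briefly, and
compares the bits-per-dimension (BPD) against the analytic differential
entropy rate of the data — the closer the BPD, the better the flow has
captured the density.
"""

import numpy as np

from mvflow import bits_per_dimension
from mvflow.trainer import TrainingConfig, train_tabular

rng = np.random.default_rng(0)
rho = 0.9
cov = np.array([[1.0, rho], [rho, 1.0]])
x = rng.multivariate_normal([0, 0], cov, size=4000)

cfg = TrainingConfig(iterations=800, microbatch_size=256, learning_rate=5e-3,
                     warmup_steps=100, coupling_depth=4, hidden_channels=64,
                     seed=0, val_interval=200)
result = train_tabular({"idp": x}, cfg)

bpd = bits_per_dimension(result.flows["idp"], x[result.val_idx])
analytic = 0.5 * np.log2((2 * np.pi * np.e) ** 2 * np.linalg.det(cov)) / 2
print(f"model BPD on held-out data : {bpd:.3f} bits/dim")
print(f"analytic entropy rate      : {analytic:.3f} bits/dim")
print(f"gap                        : {bpd - analytic:+.3f}")
# The gap is the excess code length the flow pays over the true density;
# a well-trained flow sits within ~0.1 bits of the analytic rate.
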