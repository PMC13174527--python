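"""Cross-view imputation via low-rank Gaussian conditioning.

Two smoothly coupled tabular views are modelled by per-view flows; a
low-rank-plus-diagonal Gaussian over the concatenated latents then gives
the exact conditional mean of the missing view's latents, which is decoded
through that view's inverse flow.  Printed: the per-feature correlation of
the imputed view with the held-out truth.
"""

import numpy as np

from mvflow import SharedFactorSpec, fit_latent_model, impute_views, make_multiview_tabular
from mvflow.trainer import TrainingConfig, train_tabular

tv = make_multiview_tabular(SharedFactorSpec(
    n_subjects=1000, shared_dim=3, private_dim=0, view_dims=(6,),
    noise_sd=0.05, seed=3))
x1 = tv.views["view0"]
x2 = x1 + 0.5 * np.tanh(x1)  # second view: smooth monotone map of the first

train = {"a": x1[:500], "b": x2[:500]}
test = {"a": x1[500:], "b": x2[500:]}

cfg = TrainingConfig(iterations=500, microbatch_size=128, learning_rate=3e-3,
                     warmup_steps=50, coupling_depth=3, hidden_channels=32,
                     seed=0, val_interval=200)
result = train_tabular(train, cfg)

gauss = fit_latent_model(result.flows, train, rank=8)
imputed = impute_views(result.flows, gauss, {"a": test["a"]}, ["b"])["b"]

for j in range(6):
    r = np.corrcoef(imputed[:, j], test["b"][:, j])[0, 1]
    print(f"feature {j}: imputed-vs-true correlation = {r:.3f}")
# Correlations near 1 mean the conditional mean transfers subject-specific
# information across views, not just the population average.
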