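import numpy as np
import pytest

from mvflow.flow_tabular import build_tabular_flow
from mvflow.synthetic import PhantomSpec, SharedFactorSpec, make_multiview_tabular, make_phantoms


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_flow(rng):
    """A dim-5 coupling flow with non-trivial (perturbed) parameters."""
    m = build_tabular_flow(5, coupling_depth=3, hidden_channels=16, seed=1)
    for p in m.parameters():
        p.data += 0.1 * rng.standard_normal(p.data.shape)
    return m


@pytest.fixture(scope="session")
def shared_factor_views():
    """Two subject-matched tabular views with a planted 2-D shared factor."""
    return make_multiview_tabular(
        SharedFactorSpec(n_subjects=500, shared_dim=2, private_dim=2,
                         view_dims=(8, 8), noise_sd=0.1, seed=0)
    )


@pytest.fixture(scope="session")
def phantoms():
    """64 two-view 16x16 phantoms with shared geometry, view-specific contrast."""
    return make_phantoms(PhantomSpec(n_subjects=64, size=(16, 16), n_views=2, seed=0))
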