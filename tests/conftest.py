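import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted dataset shared by network/module tests."""
    import pivotnet as pn

    expr, truth = pn.generate_stage_expression(
        n_genes=400, modules=[(20, 0.9), (20, 0.9)], n_pivots=3,
        de_spec={("4cell", "8cell"): (10, 3.0)}, seed=11,
    )
    ppi = pn.generate_ppi(truth, seed=12)
    go = pn.generate_go_annotations(truth, seed=13)
    return expr, truth, ppi, go


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
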