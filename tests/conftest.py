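import pytest


@pytest.fixture
def lv_params():
    """Classic Lotka-Volterra predator-prey parameters of the worked example;
    coexistence point (H*, P*) = (d/(e a), r/a) = (15, 5)."""
    return {"r": 0.5, "a": 0.1, "e": 0.2, "d": 0.3}


@pytest.fixture
def rm_params():
    """Rosenzweig-MacArthur defaults with enrichment threshold K_crit = 1100/3."""
    return {"r": 0.5, "a": 0.02, "T_h": 0.3, "e": 0.4, "d": 0.5}


@pytest.fixture
def rm_k_crit():
    return 1100.0 / 3.0
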