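import numpy as np
import pytest

from aoamacro.synthetic import SurveyConfig, build_metacommunity, simulate_survey


@pytest.fixture(scope="session")
def small_survey():
    """A small structured survey shared by read-only tests."""
    cfg = SurveyConfig(
        n_stations=16,
        n_otus=80,
        depths_per_station=(50.0, 500.0, 1500.0, 2500.0),
        seed=42,
    )
    mc = build_metacommunity(cfg)
    counts, fingerprint, meta = simulate_survey(mc, cfg)
    return cfg, mc, counts, fingerprint, meta


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
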