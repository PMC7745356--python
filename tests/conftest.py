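import numpy as np
import pytest
from hypothesis import settings

import sesindex as si

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

#: one fixed seed for every stochastic fixture in the suite
SEED = 1


@pytest.fixture(scope="session")
def grid():
    return si.QuadratureGrid.normal()


@pytest.fixture(scope="session")
def default_cfg():
    return si.default_config(seed=SEED)


@pytest.fixture(scope="session")
def cohort10k(default_cfg):
    """Pooled 7-site synthetic cohort at the acceptance-scale n."""
    return si.simulate_responses(default_cfg, 10_000, seed=SEED)


@pytest.fixture(scope="session")
def calibrated(cohort10k):
    """Full pipeline on the pooled cohort: design, calibration, tables."""
    stats = si.empirical_site_stats(cohort10k)
    design = si.assign_anchors(stats)
    result = si.multigroup_calibrate(cohort10k, design, reference_site="Nagpur")
    tables = si.build_scoring_tables(result, design=design)
    return stats, design, result, tables


def one_site_config(prevalences: dict, loadings: dict, seed: int = SEED, **kwargs):
    """Single-site generator config helper for unit tests."""
    return si.calibrate_generator(
        {"A": prevalences}, {"A": loadings}, {"A": 1.0}, seed=seed, **kwargs
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(SEED)
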