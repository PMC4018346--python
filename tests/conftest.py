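import numpy as np
import pytest

from snplasso import synthetic_cohort as sc


@pytest.fixture(scope="session")
def small_cohort():
    """Null cohort: 150/150 samples, 10 SNPs (session-shared, read-only)."""
    cfg = sc.default_sim_config(n_cases=150, n_controls=150, n_snps=10, seed=11)
    return sc.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def effect_cohort():
    """Cohort with a strong planted additive effect on rs6567355."""
    cfg = sc.default_sim_config(
        n_cases=400, n_controls=400, n_snps=12, seed=7,
        log_or_of={"rs6567355": 0.6},
    )
    return sc.simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
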