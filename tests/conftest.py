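import numpy as np
import pytest

from gwgrowth.synthetic_cohort import SimConfig, TruthParams

SHAPE = ("m0", "k", "b_pre", "b_post")


def zero_re(**overrides):
    """Random-effect SDs all zero (pure fixed-effects truth)."""
    sds = {g: {p: 0.0 for p in SHAPE} for g in ("pregnancy", "female", "season")}
    for key, val in overrides.items():
        g, p = key.split("_", 1)
        sds[g][p] = val
    return sds


@pytest.fixture(scope="session")
def fixed_truth():
    """Population curve with no covariate effects and no random effects."""
    return TruthParams(coef={}, litter_effect_on_slope=0.0, re_sd=zero_re())


@pytest.fixture(scope="session")
def small_cohort(fixed_truth):
    from gwgrowth.synthetic_cohort import simulate_cohort

    cfg = SimConfig(n_pregnancies=12, n_females=6, seed=42, truth=fixed_truth,
                    noise_sd=10.0, weighings_per_pregnancy=14, weighings_sd=1)
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
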