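"""Growth-estimate extraction, age standardization, and posterior pooling."""

import numpy as np
import pandas as pd
import pytest

from gwgrowth.growth_model import ModelSpec, build_design
from gwgrowth.inference import PosteriorSamples, fit_logistic
from gwgrowth.pup_fates import (
    PooledPosterior,
    PregnancyGrowthEstimate,
    extract_growth_estimates,
    fit_outcome_model,
    pool_posteriors,
    standardize_emergence_mass,
    validate_pups,
)


def toy_pregnancies(n=4, litter=None):
    return pd.DataFrame(
        {
            "pregnancy_id": [f"P{i}" for i in range(n)],
            "female_id": [f"F{i // 2}" for i in range(n)],
            "season": ["S0", "S1"] * (n // 2 + 1)[:1] * n if False else ["S0"] * n,
            "status": ["dominant"] * n,
            "litter_size": litter if litter is not None else [4] * n,
            "maternal_age": np.linspace(900, 2000, n),
            "group_size": np.linspace(8, 20, n),
        }
    )


def fake_growth_posterior(preg, k_draws, bpost_draws, k_dev=None, bpost_dev=None):
    """A growth posterior with optional per-pregnancy deviations.

    ``k_draws``/``bpost_draws`` are 1-D population draws; deviations are
    per-pregnancy constants added via dev columns.
    """
    spec = ModelSpec(
        random={"k": ("pregnancy",), "b_post": ("pregnancy",)}
        if k_dev is not None
        else {}
    )
    designs = build_design(spec, preg)
    n = len(k_draws)
    cols = {
        "chain": [0] * n,
        "draw": list(range(n)),
        "m0:intercept": 740.0,
        "k:intercept": np.asarray(k_draws, float),
        "b_pre:intercept": -0.26,
        "b_post:intercept": np.asarray(bpost_draws, float),
    }
    if k_dev is not None:
        for pid, dk, db in zip(preg["pregnancy_id"], k_dev, bpost_dev):
            cols[f"dev:pregnancy:k:{pid}"] = dk
            cols[f"dev:pregnancy:b_post:{pid}"] = db
    draws = pd.DataFrame(cols)
    diag = pd.DataFrame({"rhat": [1.0], "ess": [n]}, index=["k:intercept"])
    return PosteriorSamples(draws=draws, diagnostics=diag, spec=spec,
                            designs=designs, pregnancies=preg)


class TestExtraction:
    def test_per_capita_rate_is_slope_over_litter(self, rng):
        preg = toy_pregnancies(2, litter=[4, 2])
        post = fake_growth_posterior(preg, np.full(200, 30.83), np.full(200, 5.20))
        est = extract_growth_estimates(post, preg, n_draws=50, seed=1)
        assert est[0].per_capita_rate[0] == pytest.approx(1.30)
        assert est[1].per_capita_rate[0] == pytest.approx(2.60)
        # exact inverse scaling with litter size
        np.testing.assert_allclose(est[0].per_capita_rate * 2,
                                   est[1].per_capita_rate)

    def test_duration_is_horizon_minus_k(self):
        preg = toy_pregnancies(1)
        post = fake_growth_posterior(preg, np.full(10, 30.83), np.full(10, 5.2))
        est = extract_growth_estimates(post, preg, n_draws=10, seed=0)
        np.testing.assert_allclose(est[0].duration, 44.17)

    def test_requesting_too_many_draws_rejected(self):
        preg = toy_pregnancies(1)
        post = fake_growth_posterior(preg, np.full(10, 31.0), np.full(10, 5.0))
        with pytest.raises(ValueError, match="posterior has 10"):
            extract_growth_estimates(post, preg, n_draws=11, seed=0)

    def test_degenerate_posterior_gives_identical_estimates(self):
        preg = toy_pregnancies(2)
        post = fake_growth_posterior(preg, np.full(500, 31.0), np.full(500, 5.0))
        est = extract_growth_estimates(post, preg, n_draws=100, seed=3)
        for e in est:
            assert np.ptp(e.duration) == 0.0
            assert np.ptp(e.per_capita_rate) == 0.0

    def test_reproducible_under_seed(self, rng):
        preg = toy_pregnancies(2)
        post = fake_growth_posterior(preg, rng.normal(31, 1, 400),
                                     rng.normal(5.2, 0.2, 400))
        a = extract_growth_estimates(post, preg, n_draws=100, seed=5)
        b = extract_growth_estimates(post, preg, n_draws=100, seed=5)
        np.testing.assert_array_equal(a[0].duration, b[0].duration)

    def test_joint_draw_indices_shared_across_pregnancies(self, rng):
        """Within one retained draw all pregnancies see the same population
        draw, so duration differences equal the deviation differences."""
        preg = toy_pregnancies(2)
        post = fake_growth_posterior(preg, rng.normal(31, 1, 300),
                                     rng.normal(5.2, 0.2, 300),
                                     k_dev=[1.0, -2.0], bpost_dev=[0.0, 0.0])
        est = extract_growth_estimates(post, preg, n_draws=80, seed=2)
        np.testing.assert_allclose(est[0].duration - est[1].duration, -3.0)


class TestStandardizeEmergenceMass:
    def test_pup_at_target_age_unchanged(self):
        pups = pd.DataFrame({"emergence_mass_g": [100.0, 120.0, 80.0],
                             "emergence_age_d": [25.0, 20.0, 30.0]})
        adj = standardize_emergence_mass(pups)
        assert adj.iloc[0] == pytest.approx(100.0)

    def test_same_residual_same_adjusted_mass(self):
        # a known line mass = 10 + 4*age; both pups sit exactly on it
        pups = pd.DataFrame({"emergence_mass_g": [90.0, 130.0, 110.0],
                             "emergence_age_d": [20.0, 30.0, 25.0]})
        adj = standardize_emergence_mass(pups)
        assert adj.iloc[0] == pytest.approx(adj.iloc[1])

    def test_adjusted_mass_age_independent(self, rng):
        age = rng.integers(12, 31, 300).astype(float)
        mass = 40.0 + 5.0 * age + rng.normal(0, 8, 300)
        pups = pd.DataFrame({"emergence_mass_g": mass, "emergence_age_d": age})
        adj = standardize_emergence_mass(pups)
        slope = np.polyfit(age, adj, 1)[0]
        assert slope == pytest.approx(0.0, abs=1e-10)

    def test_constant_age_is_identity(self):
        pups = pd.DataFrame({"emergence_mass_g": [100.0, 90.0],
                             "emergence_age_d": [20.0, 20.0]})
        np.testing.assert_allclose(standardize_emergence_mass(pups),
                                   [100.0, 90.0])


class TestPooling:
    def _fake_fit(self, mean, sd, n=300, seed=0):
        rng = np.random.default_rng(seed)
        draws = pd.DataFrame({"chain": 0, "draw": range(n),
                              "beta:per_capita_rate": rng.normal(mean, sd, n)})
        diag = pd.DataFrame({"rhat": [1.0], "ess": [n]},
                            index=["beta:per_capita_rate"])
        return PosteriorSamples(draws=draws, diagnostics=diag)

    def test_law_of_total_variance(self):
        fits = [self._fake_fit(m, 0.5, seed=i) for i, m in enumerate((1.0, 2.0, 4.0))]
        pooled = pool_posteriors(fits)
        x = pooled.scalar("beta:per_capita_rate")
        within = np.mean([f.scalar("beta:per_capita_rate").var(ddof=1) for f in fits])
        assert x.var(ddof=1) >= within

    def test_equal_draw_counts_per_dataset(self):
        fits = [self._fake_fit(0.0, 1.0, n=300), self._fake_fit(0.0, 1.0, n=200)]
        pooled = pool_posteriors(fits)
        assert (pooled.draws.groupby("dataset").size() == 200).all()


class TestBernoulliModel:
    def test_intercept_only_survival_probability(self, rng):
        y = (rng.random(600) < 0.7).astype(float)
        X = pd.DataFrame({"intercept": np.ones(600)})
        post = fit_logistic(y, X, seed=2, n_steps=800, n_keep=400)
        p_hat = 1 / (1 + np.exp(-post.scalar("beta:intercept")))
        se = np.sqrt(0.7 * 0.3 / 600)
        assert p_hat.mean() == pytest.approx(y.mean(), abs=3 * se)

    def test_non_binary_response_rejected(self):
        with pytest.raises(ValueError, match="0/1"):
            fit_logistic(np.array([0.0, 0.5, 1.0]),
                         pd.DataFrame({"intercept": np.ones(3)}))


class TestOutcomeModel:
    def test_inconsistent_survival_flags_rejected(self):
        pups = pd.DataFrame({"pup_id": ["a"], "pregnancy_id": ["P0"],
                             "emergence_mass_g": [100.0], "emergence_age_d": [20.0],
                             "survived_90d": [0], "survived_1y": [1]})
        with pytest.raises(ValueError, match="alive at 1 year"):
            validate_pups(pups)

    def test_unknown_outcome_rejected(self):
        with pytest.raises(ValueError, match="outcome"):
            fit_outcome_model("weaning_mass", pd.DataFrame(), pd.DataFrame(), [])

    def test_degenerate_estimates_give_single_dataset_equivalent(self, rng):
        """Zero-spread growth posterior: pooling several identical datasets
        reproduces the single-dataset posterior up to Monte-Carlo error."""
        preg = toy_pregnancies(6, litter=[2, 3, 4, 5, 3, 4])
        post = fake_growth_posterior(
            preg, np.full(300, 31.0), np.full(300, 5.2),
            k_dev=list(rng.normal(0, 2, 6)), bpost_dev=list(rng.normal(0, 0.6, 6)),
        )
        est = extract_growth_estimates(post, preg, n_draws=20, seed=1)
        rows = []
        for i, e in enumerate(est):
            for j in range(12):
                rate = e.per_capita_rate[0]
                rows.append({"pup_id": f"{e.pregnancy_id}-{j}",
                             "pregnancy_id": e.pregnancy_id,
                             "emergence_mass_g": 100 + 3.55 * rate + rng.normal(0, 6),
                             "emergence_age_d": float(rng.integers(12, 31))})
        pups = pd.DataFrame(rows)
        pooled = fit_outcome_model(
            "emergence_mass", pups, preg, est, covariates=(),
            random_effects=(), n_datasets=3, n_keep=400, seed=9,
        )
        single = fit_outcome_model(
            "emergence_mass", pups, preg, est, covariates=(),
            random_effects=(), n_datasets=1, n_keep=400, seed=10,
        )
        a = pooled.summarize("beta:per_capita_rate")
        b = single.summarize("beta:per_capita_rate")
        assert a.mean == pytest.approx(b.mean, abs=0.3 * b.sd)
        assert a.sd == pytest.approx(b.sd, rel=0.25)

    def test_rate_effect_on_emergence_mass_recovered_at_study_scale(self):
        """~900 pups with a 3.55 g per (g/day/pup) effect: the pooled
        posterior recovers it within two pooled posterior SDs."""
        from gwgrowth.synthetic_cohort import SimConfig, simulate_cohort

        from conftest import zero_re
        from gwgrowth.synthetic_cohort import TruthParams

        truth = TruthParams(coef={}, re_sd=zero_re(pregnancy_b_post=1.0))
        cfg = SimConfig(n_pregnancies=250, n_females=100, seed=61, truth=truth,
                        weighings_per_pregnancy=12, weighings_sd=0)
        preg, _, pups = simulate_cohort(cfg)
        pm = preg.set_index("pregnancy_id")
        est = [
            PregnancyGrowthEstimate(
                pregnancy_id=pid,
                duration=np.full(1, 75.0 - pm.loc[pid, "true_k"]),
                per_capita_rate=np.full(
                    1, pm.loc[pid, "true_b_post"] / pm.loc[pid, "litter_size"]),
            )
            for pid in preg["pregnancy_id"]
        ]
        pooled = fit_outcome_model(
            "emergence_mass", pups, preg, est,
            covariates=("maternal_age", "maternal_age^2", "status", "group_size"),
            random_effects=(), n_datasets=1, n_steps=400, n_keep=400, seed=8,
        )
        s = pooled.summarize("beta:per_capita_rate")
        rate_sd = (pm["true_b_post"] / pm["litter_size"]).reindex(
            pups["pregnancy_id"]).std(ddof=1)
        per_unit_mean = s.mean / rate_sd
        per_unit_sd = s.sd / rate_sd
        assert abs(per_unit_mean - 3.55) < 2 * per_unit_sd
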