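"""The broken-stick curve, design matrices and the hierarchical likelihood."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from gwgrowth.growth_model import (
    ModelSpec,
    ParameterVector,
    ShapeParams,
    build_design,
    log_likelihood,
    model1,
    model3,
    model5,
    predict_mass,
)

shape_strategy = st.builds(
    ShapeParams,
    m0=st.floats(400, 1100),
    k=st.floats(1, 74),
    b_pre=st.floats(-3, 3),
    b_post=st.floats(0, 12),
)


class TestPredictMass:
    def test_intercept_at_conception(self):
        s = ShapeParams(m0=700.0, k=30.0, b_pre=-0.5, b_post=5.0)
        assert predict_mass(s, 0.0) == 700.0

    def test_worked_example_final_day(self):
        # 739.70 - 0.26*30.83 + 5.20*(75 - 30.83) = 961.3682
        s = ShapeParams(m0=739.70, k=30.83, b_pre=-0.26, b_post=5.20)
        assert predict_mass(s, 75.0) == pytest.approx(961.37, abs=0.005)

    @given(shape_strategy)
    @settings(max_examples=50, deadline=None)
    def test_continuous_at_inflection(self, s):
        eps = 1e-7
        left = predict_mass(s, s.k - eps)
        right = predict_mass(s, s.k + eps)
        assert right - left == pytest.approx(0.0, abs=1e-4)
        assert predict_mass(s, s.k) == pytest.approx(s.m0 + s.b_pre * s.k, rel=1e-12)

    @given(shape_strategy)
    @settings(max_examples=30, deadline=None)
    def test_single_breakpoint(self, s):
        """Second differences vanish on any grid cell not containing k."""
        t = np.linspace(0, 75, 151)
        y = predict_mass(s, t)
        d2 = np.abs(np.diff(y, 2))
        inside = np.abs(t[1:-1] - s.k) <= (t[1] - t[0])
        assert np.all(d2[~inside] < 1e-8)
        assert np.count_nonzero(d2 > 1e-8) <= 2

    def test_negative_day_rejected(self):
        s = ShapeParams(m0=700.0, k=30.0, b_pre=0.0, b_post=5.0)
        with pytest.raises(ValueError, match="non-negative"):
            predict_mass(s, -1.0)


def toy_pregnancies(n=3, **extra):
    base = {
        "pregnancy_id": [f"P{i}" for i in range(n)],
        "female_id": [f"F{i % 2}" for i in range(n)],
        "season": ["S0"] * n,
        "litter_size": list(range(2, 2 + n)),
        "status": ["dominant", "subordinate", "dominant"][:n] * (n // 3 + 1),
    }
    base["status"] = base["status"][:n]
    base.update(extra)
    return pd.DataFrame(base)


class TestBuildDesign:
    def test_standardization_sample_sd(self):
        """{1,2,3} standardizes to {-1, 0, 1} under the n-1 SD convention."""
        preg = toy_pregnancies(3, litter_size=[1, 2, 3])
        spec = ModelSpec(fixed={"b_post": ("litter_size",)})
        d = build_design(spec, preg)
        np.testing.assert_allclose(
            d.matrices["b_post"]["litter_size"].to_numpy(), [-1.0, 0.0, 1.0]
        )
        assert d.standardization["litter_size"] == (2.0, 1.0)

    def test_zero_variance_covariate_named(self):
        preg = toy_pregnancies(3, litter_size=[4, 4, 4])
        spec = ModelSpec(fixed={"k": ("litter_size",)})
        with pytest.raises(ValueError, match="litter_size"):
            build_design(spec, preg)

    def test_missing_covariate_named(self):
        spec = ModelSpec(fixed={"k": ("ndvi",)})
        with pytest.raises(ValueError, match="ndvi"):
            build_design(spec, toy_pregnancies(3))

    def test_interaction_is_product_of_processed_columns(self):
        preg = toy_pregnancies(3)
        spec = ModelSpec(fixed={"b_post": ("status", "litter_size", "status:litter_size")})
        m = build_design(spec, preg).matrices["b_post"]
        np.testing.assert_allclose(
            m["status[subordinate]:litter_size"].to_numpy(),
            m["status[subordinate]"].to_numpy() * m["litter_size"].to_numpy(),
        )

    def test_quadratic_of_standardized_value(self):
        preg = toy_pregnancies(3, litter_size=[1, 2, 3])
        spec = ModelSpec(fixed={"k": ("litter_size", "litter_size^2")})
        m = build_design(spec, preg).matrices["k"]
        np.testing.assert_allclose(
            m["litter_size^2"].to_numpy(), m["litter_size"].to_numpy() ** 2
        )

    def test_gestation_length_left_raw_in_model5(self):
        preg = toy_pregnancies(3, gestation_length=[72.0, 75.0, 78.0])
        m = build_design(model5(), preg).matrices["k"]
        np.testing.assert_allclose(m["gestation_length"].to_numpy(), [72.0, 75.0, 78.0])

    def test_dominant_is_reference_level(self):
        preg = toy_pregnancies(3)
        spec = ModelSpec(fixed={"m0": ("status",)})
        col = build_design(spec, preg).matrices["m0"]["status[subordinate]"]
        np.testing.assert_allclose(col.to_numpy(), [0.0, 1.0, 0.0])


def _params_for(spec, preg, sigma=12.0, seed=0):
    """A ParameterVector with arbitrary but reproducible values."""
    rng = np.random.default_rng(seed)
    designs = build_design(spec, preg)
    coefs = {}
    base = {"m0": 740.0, "k": 31.0, "b_pre": -0.3, "b_post": 5.0}
    for p, m in designs.matrices.items():
        vals = [base[p]] + list(0.5 * rng.standard_normal(m.shape[1] - 1))
        coefs[p] = pd.Series(vals, index=m.columns)
    deviations = {}
    for p, groups in spec.random.items():
        for g in groups:
            col = {"pregnancy": "pregnancy_id", "female": "female_id", "season": "season"}[g]
            levels = preg[col].unique()
            scale = {"m0": 20.0, "k": 2.0, "b_pre": 0.1, "b_post": 0.5}[p]
            deviations[(p, g)] = pd.Series(
                scale * rng.standard_normal(len(levels)), index=levels
            )
    return ParameterVector(coefs=coefs, sigma=sigma, deviations=deviations)


class TestLogLikelihood:
    def test_single_point_on_curve_closed_form(self):
        preg = toy_pregnancies(1)
        spec = ModelSpec()
        params = _params_for(spec, preg, sigma=7.0)
        mass = 740.0 + (-0.3) * 10.0  # on the curve at day 10 (k=31)
        w = pd.DataFrame({"pregnancy_id": ["P0"], "day": [10.0], "mass_g": [mass]})
        expected = -0.5 * np.log(2 * np.pi * 7.0**2)
        assert log_likelihood(params, spec, w, preg) == pytest.approx(expected, rel=1e-12)

    def test_matches_brute_force_pointwise_sum(self, small_cohort):
        """Hierarchical likelihood equals an independent per-observation loop."""
        preg, weigh, _ = small_cohort
        spec = model1()
        params = _params_for(spec, preg, sigma=9.0, seed=3)
        got = log_likelihood(params, spec, weigh, preg)

        # oracle: scalar normal log-densities, curve rebuilt by hand
        designs = build_design(spec, preg)
        total = 0.0
        for _, row in weigh.iterrows():
            pid = row["pregnancy_id"]
            prow = preg.set_index("pregnancy_id").loc[pid]
            vals = {}
            for p in ("m0", "k", "b_pre", "b_post"):
                x = designs.matrices[p].loc[pid]
                v = float(np.dot(x.to_numpy(), params.coefs[p].to_numpy()))
                for g in spec.random.get(p, ()):
                    col = {"pregnancy": pid, "female": prow["female_id"],
                           "season": prow["season"]}[g]
                    v += float(params.deviations[(p, g)][col])
                vals[p] = v
            t = row["day"]
            mu = vals["m0"] + vals["b_pre"] * min(t, vals["k"]) + vals["b_post"] * max(
                0.0, t - vals["k"])
            total += norm.logpdf(row["mass_g"], mu, params.sigma)
        assert got == pytest.approx(total, rel=1e-12, abs=1e-9)

    def test_doubling_sigma_with_zero_residuals(self):
        preg = toy_pregnancies(1)
        spec = ModelSpec()
        days = np.array([5.0, 20.0, 40.0, 60.0])
        p1 = _params_for(spec, preg, sigma=4.0)
        mass = [predict_mass(ShapeParams(740.0, 31.0, -0.3, 5.0), t) for t in days]
        w = pd.DataFrame({"pregnancy_id": "P0", "day": days, "mass_g": mass})
        l1 = log_likelihood(p1, spec, w, preg)
        p2 = _params_for(spec, preg, sigma=8.0)
        l2 = log_likelihood(p2, spec, w, preg)
        assert l1 - l2 == pytest.approx(len(days) * np.log(2.0), rel=1e-12)

    def test_invariant_to_record_order(self, small_cohort, rng):
        preg, weigh, _ = small_cohort
        spec = model1()
        params = _params_for(spec, preg, seed=5)
        shuffled = weigh.sample(frac=1.0, random_state=11).reset_index(drop=True)
        assert log_likelihood(params, spec, weigh, preg) == pytest.approx(
            log_likelihood(params, spec, shuffled, preg), rel=1e-13
        )

    def test_collapses_to_fixed_effects_with_zero_deviations(self, small_cohort):
        preg, weigh, _ = small_cohort
        spec = model1()
        params = _params_for(spec, preg, seed=7)
        for key in params.deviations:
            params.deviations[key][:] = 0.0
        flat = ModelSpec(fixed=spec.fixed)
        flat_params = _params_for(flat, preg, seed=7)
        assert log_likelihood(params, spec, weigh, preg) == pytest.approx(
            log_likelihood(flat_params, flat, weigh, preg), rel=1e-12
        )

    def test_observation_past_horizon_rejected(self):
        preg = toy_pregnancies(1)
        spec = ModelSpec()
        params = _params_for(spec, preg)
        w = pd.DataFrame({"pregnancy_id": ["P0"], "day": [80.0], "mass_g": [700.0]})
        with pytest.raises(ValueError, match="horizon"):
            log_likelihood(params, spec, w, preg)

    def test_unknown_pregnancy_rejected(self):
        preg = toy_pregnancies(1)
        spec = ModelSpec()
        params = _params_for(spec, preg)
        w = pd.DataFrame({"pregnancy_id": ["PX"], "day": [10.0], "mass_g": [700.0]})
        with pytest.raises(ValueError, match="unknown"):
            log_likelihood(params, spec, w, preg)


class TestModelSpec:
    def test_yaml_round_trip(self):
        spec = model3()
        again = ModelSpec.from_yaml(spec.to_yaml())
        assert again == spec

    def test_invalid_shape_parameter_rejected(self):
        with pytest.raises(ValueError, match="unknown shape parameter"):
            ModelSpec(fixed={"slope": ("litter_size",)})

    def test_invalid_correlation_matrix_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="correlation"):
            ParameterVector(coefs={}, sigma=1.0, re_corr=bad)
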