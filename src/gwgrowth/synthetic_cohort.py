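"""Simulation of study-like meerkat pregnancy cohorts with known ground truth.

The generator emulates the structure of longitudinal field records of pregnant
meerkats: repeated morning body-mass weighings over a 75-day gestation,
pregnancy-level covariates (litter size, dominance status, maternal age, body
condition, group size, reproductive competition, NDVI, temperature), and
per-pup outcome records (emergence mass, relative telomere length, survival).
Maternal mass follows the continuous biphasic curve — a plateau to inflection
day ``k`` then linear gain — with Gaussian observation noise, covariate
effects on the curve parameters, and random effects at the pregnancy, female
and season levels.

Defaults reproduce the study conditions: 381 pregnancies from 135 females,
31.8 ± 8.9 weighings per pregnancy, litter sizes averaging 3.57 ± 1.35 pups
(range 1–7), 81% of pregnancies to dominant females, conception mass
739.70 g, inflection at day 30.83, slopes −0.26 and +5.20 g/day, and a litter
effect of +0.66 g/day per foetus on the post-inflection slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .growth_model import SHAPE_PARAMS

#: generating mean and SD used to apply "per 1 SD" covariate effects
_COVARIATE_SCALES = {
    "maternal_age": (1500.0, 600.0),
    "body_condition": (0.0, 25.0),
    "group_size": (15.0, 7.0),
    "n_concurrent": (0.5, 0.8),
    "ndvi": (0.25, 0.08),
    "temperature": (25.0, 5.0),
}


def _check_corr(corr, what="correlation matrix"):
    c = np.asarray(corr, dtype=float)
    if c.shape != (4, 4) or not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0) \
            or np.any(np.linalg.eigvalsh(c) < -1e-10):
        raise ValueError(f"invalid {what} (must be symmetric PSD with unit diagonal):\n{c}")
    return c


@dataclass(frozen=True)
class TruthParams:
    """Population-level truth for the growth curve and its covariate effects.

    Covariate effects are per 1 SD of the generating distribution; the litter
    effects are per foetus, applied centred at the configured mean litter size
    so that the slope/inflection intercepts describe an average litter.
    """

    m0_mean: float = 739.70
    k_mean: float = 30.83
    b_pre: float = -0.26
    b_post: float = 5.20
    litter_effect_on_slope: float = 0.66  # g/day per foetus
    litter_effect_on_k: float = 0.0  # days per foetus
    #: extra per-foetus slope for subordinate mothers (status x litter interaction)
    subordinate_litter_shift: float = 0.0
    coef: dict = field(default_factory=lambda: {
        "k": {"body_condition": 0.92},
        "b_post": {"ndvi": 0.14},
    })
    re_sd: dict = field(default_factory=lambda: {
        "pregnancy": {"m0": 60.0, "k": 3.0, "b_pre": 0.15, "b_post": 0.8},
        "female": {"m0": 0.0, "k": 0.0, "b_pre": 0.0, "b_post": 0.0},
        "season": {"m0": 0.0, "k": 0.0, "b_pre": 0.0, "b_post": 0.0},
    })
    corr: tuple | None = None  # 4x4, order (m0, k, b_pre, b_post); None = identity

    def __post_init__(self):
        for g, d in self.re_sd.items():
            for p, v in d.items():
                if v < 0:
                    raise ValueError(f"random-effect SD for {g}/{p} must be >= 0")
        if self.corr is not None:
            _check_corr(self.corr, "pregnancy-effect correlation matrix")

    def corr_matrix(self):
        return np.eye(4) if self.corr is None else np.asarray(self.corr, float)


@dataclass(frozen=True)
class PupTruthParams:
    """Truth for the pup-outcome models, driven by each pregnancy's true
    per-capita prenatal growth rate (post-inflection slope / litter size)."""

    emergence_mass_intercept: float = 110.0  # g at 25 days, average rate
    effect_of_per_capita_rate_on_mass: float = 3.55  # g per (g/day/pup)
    age_slope: float = 3.5  # g/day of emergence age
    mass_noise_sd: float = 10.0
    telomere_intercept: float = 1.20  # T/S ratio
    telomere_effect_of_rate: float = -0.002
    telomere_noise_sd: float = 0.15
    survival90_logit_intercept: float = 1.4
    survival90_logit_effect_of_mass: float = 1.06  # per SD of emergence mass
    survival1y_logit_intercept: float = 0.2
    survival1y_logit_effect_of_mass: float = 0.67
    #: direct effect of the per-capita rate on survival (per SD of the rate);
    #: zero by default so survival acts only through emergence mass
    direct_rate_effect_on_survival: float = 0.0

    def __post_init__(self):
        if self.mass_noise_sd <= 0 or self.telomere_noise_sd <= 0:
            raise ValueError("outcome noise SDs must be positive")


@dataclass(frozen=True)
class GestationTruth:
    """Truth for known-length pregnancies (observed oestrus to birth)."""

    mean: float = 74.71  # days
    resid_sd: float = 2.6
    coef: dict = field(default_factory=lambda: {
        "group_size": -1.08,
        "body_condition": -0.68,
        "ndvi": 0.64,
        "temperature": -0.9,
        "temperature^2": 0.45,
    })
    #: day shift of the inflection per day of gestation length (>0.5 means
    #: longer pregnancies extend mostly the pre-inflection phase)
    k_shift_per_day: float = 0.73


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the cohort generator; one integer seed governs everything."""

    n_females: int = 135
    n_pregnancies: int = 381
    gestation_days: float = 75.0
    weighings_per_pregnancy: float = 31.8
    weighings_sd: float = 8.9
    truth: TruthParams = field(default_factory=TruthParams)
    noise_sd: float = 15.0  # g; residual mass noise around the curve
    seed: int = 0
    pup_truth: PupTruthParams = field(default_factory=PupTruthParams)
    litter_mean: float = 3.57
    litter_sd: float = 1.35
    litter_range: tuple = (1, 7)
    dominant_fraction: float = 0.81
    known_length_fraction: float = 0.0
    gestation_truth: GestationTruth | None = None
    n_groups: int | None = None
    n_seasons: int | None = None
    min_per_trimester: int = 4
    # feeding-experiment hooks (used via simulate_feeding_experiment)
    treatment_arms: bool = False
    treatment_slope_effect: float = 0.0  # g/day added to fed mothers
    treatment_k_effect: float = 0.0  # days added to fed mothers' inflection

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        """Build a config from plain (YAML-loaded) nested dictionaries."""
        d = dict(d)
        if isinstance(d.get("truth"), dict):
            d["truth"] = TruthParams(**{
                **d["truth"],
                **({"corr": tuple(map(tuple, d["truth"]["corr"]))}
                   if d["truth"].get("corr") is not None else {}),
            })
        if isinstance(d.get("pup_truth"), dict):
            d["pup_truth"] = PupTruthParams(**d["pup_truth"])
        if isinstance(d.get("gestation_truth"), dict):
            d["gestation_truth"] = GestationTruth(**d["gestation_truth"])
        if isinstance(d.get("litter_range"), list):
            d["litter_range"] = tuple(d["litter_range"])
        return cls(**d)

    def __post_init__(self):
        if not (self.n_pregnancies >= self.n_females >= 1):
            raise ValueError("need n_pregnancies >= n_females >= 1")
        if self.gestation_days <= 0:
            raise ValueError("gestation_days must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.weighings_per_pregnancy < 3 * self.min_per_trimester:
            raise ValueError(
                "weighings_per_pregnancy must allow at least "
                f"{3 * self.min_per_trimester} records so the trimester filter can pass"
            )
        if not 0 < self.truth.k_mean < self.gestation_days:
            raise ValueError("truth.k_mean must lie inside the gestation window")


def _zscore(name, values):
    mu, sd = _COVARIATE_SCALES[name]
    return (np.asarray(values, float) - mu) / sd


def _covariate_shift(truth_coef, param, z):
    out = 0.0
    for cov, beta in truth_coef.get(param, {}).items():
        base = cov.removesuffix("^2")
        out = out + beta * (z[base] ** 2 if cov.endswith("^2") else z[base])
    return out


def simulate_cohort(config: SimConfig):
    """Generate (pregnancies, weighings, pups) tables for one synthetic cohort.

    Weighing days are irregular integer days with at least
    ``config.min_per_trimester`` in each 25-day trimester, so the standard
    inclusion filter passes by construction.  Identical config and seed give
    byte-identical tables.
    """
    rng = np.random.default_rng(config.seed)
    tr = config.truth
    G = config.gestation_days
    nF, nP = config.n_females, config.n_pregnancies
    n_groups = config.n_groups or max(2, nF // 3)
    n_seasons = config.n_seasons or max(2, nP // 12)

    female_ids = [f"F{i:04d}" for i in range(nF)]
    female_group = rng.integers(0, n_groups, nF)
    n_dom = int(round(config.dominant_fraction * nF))
    female_status = rng.permutation(
        np.array(["dominant"] * n_dom + ["subordinate"] * (nF - n_dom))
    )

    # every female has at least one pregnancy; the rest are spread uniformly
    owners = np.concatenate([np.arange(nF), rng.integers(0, nF, nP - nF)])

    litter = np.clip(
        np.round(rng.normal(config.litter_mean, config.litter_sd, nP)),
        config.litter_range[0], config.litter_range[1],
    ).astype(int)

    cov = {
        name: rng.normal(mu, sd, nP)
        for name, (mu, sd) in _COVARIATE_SCALES.items()
    }
    cov["group_size"] = np.clip(cov["group_size"], 2.0, None)
    cov["n_concurrent"] = np.clip(np.round(cov["n_concurrent"]), 0, None)
    cov["maternal_age"] = np.clip(cov["maternal_age"], 300.0, None)
    z = {name: _zscore(name, cov[name]) for name in cov}

    status = female_status[owners]
    treatment = np.full(nP, "none", dtype=object)
    if config.treatment_arms:
        if nP % 2:
            raise ValueError("treatment arms require an even number of pregnancies")
        arm = np.array(["fed", "unfed"] * (nP // 2), dtype=object)
        treatment = rng.permutation(arm)

    # conception calendar: sequential pregnancies per female
    conception = np.zeros(nP)
    order_by_female = {}
    for f in range(nF):
        idx = np.flatnonzero(owners == f)
        start = rng.uniform(0, 2000)
        day = start
        for j, pi in enumerate(idx):
            if j > 0:
                day = day + G + 1 + rng.exponential(34.5)
            conception[pi] = np.round(day)
            day = conception[pi]

    season = (conception // 365).astype(int)
    season = np.mod(season, n_seasons)

    # random effects
    C = tr.corr_matrix()
    L = np.linalg.cholesky(C + 1e-12 * np.eye(4))
    sd_vec = {
        g: np.array([tr.re_sd[g][p] for p in SHAPE_PARAMS]) for g in tr.re_sd
    }
    preg_dev = (rng.standard_normal((nP, 4)) @ L.T) * sd_vec["pregnancy"]
    female_dev = rng.standard_normal((nF, 4)) * sd_vec["female"]
    season_dev = rng.standard_normal((n_seasons, 4)) * sd_vec["season"]

    dev = preg_dev + female_dev[owners] + season_dev[season]

    litter_c = litter - config.litter_mean
    litter_slope = np.where(
        status == "subordinate",
        tr.litter_effect_on_slope + tr.subordinate_litter_shift,
        tr.litter_effect_on_slope,
    )
    fed = (treatment == "fed").astype(float)

    m0 = tr.m0_mean + _covariate_shift(tr.coef, "m0", z) + dev[:, 0]
    cov_shift_k = _covariate_shift(tr.coef, "k", z) + np.zeros(nP)
    k = (
        tr.k_mean
        + tr.litter_effect_on_k * litter_c
        + cov_shift_k
        + config.treatment_k_effect * fed
        + dev[:, 1]
    )
    b_pre = tr.b_pre + _covariate_shift(tr.coef, "b_pre", z) + dev[:, 2]
    b_post = (
        tr.b_post
        + litter_slope * litter_c
        + _covariate_shift(tr.coef, "b_post", z)
        + config.treatment_slope_effect * fed
        + dev[:, 3]
    )

    # known-length subset: gestation length from its own covariate model,
    # inflection shifted along with it
    gl = np.full(nP, np.nan)
    if config.known_length_fraction > 0:
        gt = config.gestation_truth or GestationTruth()
        n_known = int(round(config.known_length_fraction * nP))
        known_idx = rng.choice(nP, size=n_known, replace=False)
        shift = np.zeros(nP)
        for cname, beta in gt.coef.items():
            base = cname.removesuffix("^2")
            shift += beta * (z[base] ** 2 if cname.endswith("^2") else z[base])
        gl_all = gt.mean + shift + rng.normal(0, gt.resid_sd, nP)
        gl[known_idx] = np.round(gl_all[known_idx], 1)
        # for known-length pregnancies, covariates act on the inflection only
        # through gestation length (the direct shift is replaced by the
        # GL-mediated one) so the per-day decomposition parameter is exact
        k = k + np.where(
            np.isnan(gl), 0.0, gt.k_shift_per_day * (gl - gt.mean) - cov_shift_k
        )

    horizon = np.where(np.isnan(gl), G, gl)
    birth = conception + horizon

    pregnancies = pd.DataFrame(
        {
            "pregnancy_id": [f"P{i:04d}" for i in range(nP)],
            "female_id": [female_ids[o] for o in owners],
            "group_id": [f"G{g:03d}" for g in female_group[owners]],
            "season": [f"S{s:03d}" for s in season],
            "status": status,
            "treatment": treatment,
            "litter_size": litter,
            "maternal_age": np.round(cov["maternal_age"], 1),
            "body_condition": np.round(cov["body_condition"], 2),
            "group_size": np.round(cov["group_size"], 2),
            "n_concurrent": cov["n_concurrent"].astype(int),
            "ndvi": np.round(cov["ndvi"], 4),
            "temperature": np.round(cov["temperature"], 2),
            "conception_day": conception,
            "birth_day": birth,
            "gestation_length": gl,
            "true_m0": m0,
            "true_k": k,
            "true_b_pre": b_pre,
            "true_b_post": b_post,
        }
    )

    # weighing days: irregular integer days, >= min_per_trimester per trimester
    w_preg, w_day = [], []
    for i in range(nP):
        n_w = int(max(3 * config.min_per_trimester,
                      round(rng.normal(config.weighings_per_pregnancy,
                                       config.weighings_sd))))
        h = horizon[i]
        bins = [
            np.arange(0, 25),
            np.arange(25, 50),
            np.arange(50, int(np.floor(h)) + 1),
        ]
        days = []
        for b in bins:
            take = min(config.min_per_trimester, len(b))
            days.append(rng.choice(b, size=take, replace=False))
        chosen = np.concatenate(days)
        pool = np.setdiff1d(np.arange(0, int(np.floor(h)) + 1), chosen)
        extra = n_w - len(chosen)
        if extra > 0 and len(pool):
            days.append(rng.choice(pool, size=min(extra, len(pool)), replace=False))
        all_days = np.sort(np.concatenate(days))
        w_preg.extend([pregnancies.loc[i, "pregnancy_id"]] * len(all_days))
        w_day.extend(all_days.tolist())

    w_day = np.asarray(w_day, dtype=float)
    shapes_rep = pregnancies.set_index("pregnancy_id").loc[
        w_preg, ["true_m0", "true_k", "true_b_pre", "true_b_post"]
    ].to_numpy()
    mu = (
        shapes_rep[:, 0]
        + shapes_rep[:, 2] * np.minimum(w_day, shapes_rep[:, 1])
        + shapes_rep[:, 3] * np.maximum(0.0, w_day - shapes_rep[:, 1])
    )
    weighings = pd.DataFrame(
        {
            "pregnancy_id": w_preg,
            "day": w_day,
            "mass_g": mu + rng.normal(0, config.noise_sd, len(w_day)),
        }
    )

    pups = _simulate_pups(rng, config, pregnancies)
    return pregnancies, weighings, pups


def _simulate_pups(rng, config, pregnancies):
    pt = config.pup_truth
    G = config.gestation_days
    rows = []
    rate = pregnancies["true_b_post"].to_numpy() / pregnancies["litter_size"].to_numpy()
    rate_ref = config.truth.b_post / config.litter_mean
    for i, (pid, n_pup) in enumerate(
        zip(pregnancies["pregnancy_id"], pregnancies["litter_size"])
    ):
        for j in range(int(n_pup)):
            age = int(rng.integers(12, 31))
            m25 = (
                pt.emergence_mass_intercept
                + pt.effect_of_per_capita_rate_on_mass * (rate[i] - rate_ref)
                + rng.normal(0, pt.mass_noise_sd)
            )
            mass = m25 + pt.age_slope * (age - 25)
            tel = (
                pt.telomere_intercept
                + pt.telomere_effect_of_rate * (rate[i] - rate_ref)
                + rng.normal(0, pt.telomere_noise_sd)
            )
            rows.append((f"{pid}-{j}", pid, mass, age, tel, m25, rate[i]))
    pups = pd.DataFrame(
        rows,
        columns=["pup_id", "pregnancy_id", "emergence_mass_g", "emergence_age_d",
                 "telomere_ts", "_m25", "_rate"],
    )
    z_mass = (pups["_m25"] - pups["_m25"].mean()) / max(pups["_m25"].std(ddof=1), 1e-9)
    z_rate = (pups["_rate"] - pups["_rate"].mean()) / max(pups["_rate"].std(ddof=1), 1e-9)
    logit90 = (
        pt.survival90_logit_intercept
        + pt.survival90_logit_effect_of_mass * z_mass
        + pt.direct_rate_effect_on_survival * z_rate
    )
    p90 = 1.0 / (1.0 + np.exp(-logit90))
    s90 = (rng.random(len(pups)) < p90).astype(int)
    logit1y = (
        pt.survival1y_logit_intercept
        + pt.survival1y_logit_effect_of_mass * z_mass
        + pt.direct_rate_effect_on_survival * z_rate
    )
    p1y = 1.0 / (1.0 + np.exp(-logit1y))
    s1y = s90 * (rng.random(len(pups)) < p1y).astype(int)
    pups["survived_90d"] = s90
    pups["survived_1y"] = s1y
    pups["emergence_mass_g"] = np.round(pups["emergence_mass_g"], 2)
    pups["telomere_ts"] = np.round(pups["telomere_ts"], 4)
    return pups.drop(columns=["_m25", "_rate"])


def simulate_feeding_experiment(
    config: SimConfig, n_per_arm: int, treatment_slope_effect: float,
    treatment_k_effect: float = 0.0,
):
    """Simulate a supplementary-feeding experiment with balanced fed/unfed arms.

    Emits ``2 * n_per_arm`` dominant pregnancies, one per female; the
    treatment adds ``treatment_slope_effect`` g/day to fed mothers'
    post-inflection slope (and optionally shifts their inflection day).
    """
    if n_per_arm < 2:
        raise ValueError("need at least 2 pregnancies per treatment arm")
    cfg = replace(
        config,
        n_pregnancies=2 * n_per_arm,
        n_females=2 * n_per_arm,
        dominant_fraction=1.0,
        treatment_arms=True,
        treatment_slope_effect=treatment_slope_effect,
        treatment_k_effect=treatment_k_effect,
        known_length_fraction=0.0,
    )
    return simulate_cohort(cfg)
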