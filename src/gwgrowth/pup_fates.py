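"""Two-stage propagation of growth-curve uncertainty into pup outcomes.

Stage one extracts, for every pregnancy, joint posterior draws of the duration
of gestational weight gain (horizon − inflection day) and the per-capita
prenatal growth rate (post-inflection slope / litter size) from a simplified
changepoint fit that excludes litter-size fixed effects (so the division by
litter size does not double-count it).  Stage two treats each retained
posterior draw as one imputed dataset, fits the requested pup-outcome model
to each, and pools by concatenating an equal number of posterior draws per
dataset — the multiple-imputation view of "fit the datasets individually and
combine the posteriors".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import (
    PosteriorSamples,
    Summary,
    credible_interval,
    fit_gaussian_lmm,
    fit_logistic,
    pd_interpretation,
    probability_of_direction,
)

OUTCOMES = ("emergence_mass", "telomere", "survival_90d", "survival_1y")

#: advisory window for the age at emergence weighing (days)
EMERGENCE_AGE_RANGE = (12.0, 30.0)

DEFAULT_COVARIATES = ("maternal_age", "maternal_age^2", "status", "group_size")


@dataclass(frozen=True)
class PregnancyGrowthEstimate:
    """Joint posterior draws of one pregnancy's GWG duration and per-capita rate."""

    pregnancy_id: str
    duration: np.ndarray  # days, one entry per retained draw
    per_capita_rate: np.ndarray  # g/day/pup, aligned with duration

    def __post_init__(self):
        if self.duration.shape != self.per_capita_rate.shape:
            raise ValueError("duration and rate draws must be aligned")


def validate_pups(pups: pd.DataFrame) -> None:
    age = pd.to_numeric(pups["emergence_age_d"], errors="coerce")
    bad = ((age < EMERGENCE_AGE_RANGE[0]) | (age > EMERGENCE_AGE_RANGE[1])).sum()
    if bad:
        warnings.warn(
            f"{bad} pup(s) weighed outside the {EMERGENCE_AGE_RANGE} day window",
            RuntimeWarning,
            stacklevel=2,
        )
    if "survived_1y" in pups.columns and "survived_90d" in pups.columns:
        viol = ((pups["survived_1y"] == 1) & (pups["survived_90d"] == 0)).sum()
        if viol:
            raise ValueError(
                f"{viol} pup(s) marked alive at 1 year but dead at 90 days"
            )


def extract_growth_estimates(
    posterior: PosteriorSamples,
    pregnancies: pd.DataFrame,
    n_draws: int = 100,
    seed: int = 0,
) -> list[PregnancyGrowthEstimate]:
    """Draw ``n_draws`` joint posterior samples of (duration, per-capita rate)
    per pregnancy.  Draw indices are shared across pregnancies within a draw,
    so between-parameter and between-pregnancy dependence is preserved."""
    shapes = posterior.pregnancy_shapes()
    k = shapes["k"]
    b_post = shapes["b_post"]
    total = k.shape[0]
    if n_draws > total:
        raise ValueError(f"requested {n_draws} draws but the posterior has {total}")
    rng = np.random.default_rng(seed)
    sel = np.sort(rng.choice(total, size=n_draws, replace=False))
    horizon = posterior.spec.horizon if posterior.spec is not None else 75.0
    litter = (
        pregnancies.set_index("pregnancy_id")["litter_size"]
        .reindex(posterior.pregnancies["pregnancy_id"])
        .to_numpy(float)
    )
    if np.any(~np.isfinite(litter)) or np.any(litter < 1):
        raise ValueError("every pregnancy needs a litter size >= 1")
    out = []
    for j, pid in enumerate(posterior.pregnancies["pregnancy_id"]):
        out.append(
            PregnancyGrowthEstimate(
                pregnancy_id=pid,
                duration=horizon - k[sel, j],
                per_capita_rate=b_post[sel, j] / litter[j],
            )
        )
    return out


def standardize_emergence_mass(pups: pd.DataFrame, target_age: float = 25.0) -> pd.Series:
    """Expected body mass at ``target_age`` days: a linear age adjustment.

    Fits mass ~ age across pups by least squares and returns each pup's
    residual plus the fitted value at the target age.  A pup weighed exactly
    at the target age keeps its observed mass.  With no age variation the
    adjustment reduces to a constant shift (slope taken as zero).
    """
    mass = pups["emergence_mass_g"].to_numpy(float)
    age = pups["emergence_age_d"].to_numpy(float)
    if np.ptp(age) == 0:
        return pd.Series(mass, index=pups.index, name="mass_at_25d")
    slope, intercept = np.polyfit(age, mass, 1)
    adjusted = mass - slope * (age - target_age)
    return pd.Series(adjusted, index=pups.index, name="mass_at_25d")


@dataclass
class PooledPosterior:
    """Equal-weight concatenation of per-imputed-dataset posteriors."""

    draws: pd.DataFrame  # columns: dataset, chain, draw, parameters
    per_dataset: list = field(default_factory=list, repr=False)
    attrs: dict = field(default_factory=dict)

    @property
    def parameter_names(self):
        return [c for c in self.draws.columns
                if c not in ("dataset", "chain", "draw") and not c.startswith("dev:")]

    def scalar(self, name: str) -> np.ndarray:
        if name not in self.draws.columns:
            raise KeyError(f"no parameter named {name!r}")
        return self.draws[name].to_numpy(float)

    def summarize(self, name: str, level: float = 0.95) -> Summary:
        x = self.scalar(name)
        lo, hi = credible_interval(x, level)
        return Summary(
            mean=float(np.mean(x)), sd=float(np.std(x, ddof=1)),
            lower=lo, upper=hi, pd=probability_of_direction(x), level=level,
        )

    def summary(self, params=None, level: float = 0.95) -> pd.DataFrame:
        rows = []
        for name in (params or self.parameter_names):
            s = self.summarize(name, level)
            rows.append({
                "parameter": name, "estimate": s.mean, "sd": s.sd,
                "lower": s.lower, "upper": s.upper, "pd": float(s.pd),
                "direction": s.pd.sign, "interpretation": pd_interpretation(s.pd),
            })
        return pd.DataFrame(rows).set_index("parameter")


def pool_posteriors(posteriors: list[PosteriorSamples]) -> PooledPosterior:
    """Concatenate equal numbers of draws from each per-dataset posterior."""
    n_min = min(len(p.draws) for p in posteriors)
    frames = []
    for d, p in enumerate(posteriors):
        f = p.draws.iloc[:n_min].copy()
        f.insert(0, "dataset", d)
        frames.append(f)
    return PooledPosterior(draws=pd.concat(frames, ignore_index=True),
                           per_dataset=posteriors)


def _z(x):
    x = np.asarray(x, float)
    sd = np.std(x, ddof=1)
    return (x - np.mean(x)) / sd if sd > 0 else x - np.mean(x)


def _pup_design(pups, pregnancies, covariates, duration, rate, outcome):
    """Design for one imputed dataset; duration and rate are per-pregnancy
    scalars for this draw, standardized within the dataset."""
    merged = pups.merge(pregnancies, on="pregnancy_id", how="left", validate="m:1")
    n = len(merged)
    dur = duration.reindex(merged["pregnancy_id"]).to_numpy(float)
    rat = rate.reindex(merged["pregnancy_id"]).to_numpy(float)
    cols = {"intercept": np.ones(n), "gwg_duration": _z(dur), "per_capita_rate": _z(rat)}
    zcache = {}
    for term in covariates:
        base = term.removesuffix("^2")
        if base == "status":
            cols["status[subordinate]"] = (
                merged["status"].astype(str) == "subordinate"
            ).to_numpy(float)
            continue
        if base not in zcache:
            zcache[base] = _z(merged[base])
        cols[term] = zcache[base] ** 2 if term.endswith("^2") else zcache[base]
    if outcome in ("emergence_mass", "telomere"):
        cols["emergence_age"] = _z(merged["emergence_age_d"])
    if outcome in ("survival_90d", "survival_1y"):
        cols["emergence_mass25"] = _z(standardize_emergence_mass(merged))
    return pd.DataFrame(cols), merged


def fit_outcome_model(
    outcome: str,
    pups: pd.DataFrame,
    pregnancies: pd.DataFrame,
    growth_estimates: list[PregnancyGrowthEstimate],
    covariates=DEFAULT_COVARIATES,
    *,
    random_effects: tuple | None = None,
    n_datasets: int | None = None,
    n_chains: int = 2,
    n_steps: int | None = None,
    n_keep: int = 200,
    seed: int = 0,
) -> PooledPosterior:
    """Fit one pup-outcome model across posterior-draw imputed datasets.

    ``emergence_mass`` and ``telomere`` are Gaussian mixed models (the former
    with the weighing age, the latter with the sampling age and no season
    effect); the survival outcomes are Bernoulli-logit models that additionally
    adjust for age-standardized emergence mass.  Each retained growth-posterior
    draw defines one dataset; posteriors are pooled with equal weight.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"outcome must be one of {OUTCOMES}")
    ycol = {
        "emergence_mass": "emergence_mass_g",
        "telomere": "telomere_ts",
        "survival_90d": "survived_90d",
        "survival_1y": "survived_1y",
    }[outcome]
    if ycol not in pups.columns:
        raise ValueError(f"pup table has no column {ycol!r}")
    validate_pups(pups)
    pups = pups.dropna(subset=[ycol]).reset_index(drop=True)

    if random_effects is None:
        random_effects = ("pregnancy", "female") if outcome == "telomere" else (
            "pregnancy", "female", "season")

    est = {e.pregnancy_id: e for e in growth_estimates}
    missing = set(pups["pregnancy_id"]) - set(est)
    if missing:
        raise ValueError(f"no growth estimates for pregnancies: {sorted(missing)[:5]}")
    n_avail = len(next(iter(est.values())).duration)
    n_datasets = n_avail if n_datasets is None else n_datasets
    if n_datasets > n_avail:
        raise ValueError("n_datasets exceeds the available growth-posterior draws")

    pids = list(est)
    dur_mat = pd.DataFrame({p: est[p].duration for p in pids}).T  # pregnancies x draws
    rate_mat = pd.DataFrame({p: est[p].per_capita_rate for p in pids}).T

    ss = np.random.SeedSequence(seed)
    fit_seeds = ss.generate_state(n_datasets)
    fits = []
    for d in range(n_datasets):
        X, merged = _pup_design(
            pups, pregnancies, covariates, dur_mat[d], rate_mat[d], outcome
        )
        groups = {}
        for g in random_effects:
            col = {"pregnancy": "pregnancy_id", "female": "female_id", "season": "season"}[g]
            groups[g] = merged[col].astype(str).to_numpy()
        y = merged[ycol].to_numpy(float)
        s = int(fit_seeds[d] % (2**31))
        if outcome in ("survival_90d", "survival_1y"):
            fits.append(
                fit_logistic(y, X, groups or None, n_chains=n_chains,
                             n_steps=n_steps or 1200, n_keep=n_keep, seed=s)
            )
        else:
            fits.append(
                fit_gaussian_lmm(y, X, groups or None, n_chains=n_chains,
                                 n_steps=n_steps or 500, n_keep=n_keep, seed=s)
            )
    pooled = pool_posteriors(fits)
    pooled.attrs.update({"outcome": outcome, "n_datasets": n_datasets, "seed": seed})
    return pooled
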