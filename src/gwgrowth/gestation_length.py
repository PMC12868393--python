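"""Analyses of pregnancies with an observed start (oestrus or copulation).

Three pieces: a Gaussian mixed model for gestation length itself (maternal,
social and environmental predictors, female identity as a random intercept);
the decomposition of gestational extension into pre- and post-inflection
phases from the changepoint model fitted on oestrus-origin time (Model-5
style); and the regression of the following inter-pregnancy interval on
gestation length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import (
    PosteriorSamples,
    credible_interval,
    fit_gaussian_lmm,
    probability_of_direction,
)

#: default plausibility window for observed gestation lengths (days)
PLAUSIBLE_GESTATION = (70.0, 81.0)

DEFAULT_PREDICTORS = (
    "litter_size",
    "body_condition",
    "group_size",
    "n_concurrent",
    "ndvi",
    "temperature",
    "temperature^2",
)


def validate_gestation_lengths(pregnancies: pd.DataFrame,
                               bounds: tuple = PLAUSIBLE_GESTATION) -> pd.DataFrame:
    """Warn about gestation lengths outside the plausibility window; returns
    the offending rows (never drops them — the bounds are advisory)."""
    gl = pd.to_numeric(pregnancies["gestation_length"], errors="coerce")
    bad = pregnancies[(gl < bounds[0]) | (gl > bounds[1])]
    if len(bad):
        warnings.warn(
            f"{len(bad)} gestation length(s) outside the plausible window "
            f"[{bounds[0]:g}, {bounds[1]:g}] days",
            RuntimeWarning,
            stacklevel=2,
        )
    return bad


def _standardized_design(pregnancies: pd.DataFrame, predictors) -> pd.DataFrame:
    cols = {"intercept": np.ones(len(pregnancies))}
    zcache: dict = {}
    for term in predictors:
        base = term.removesuffix("^2")
        if base not in pregnancies.columns:
            raise ValueError(f"pregnancy table is missing covariate column {base!r}")
        if base not in zcache:
            x = pd.to_numeric(pregnancies[base], errors="raise").astype(float)
            sd = x.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                raise ValueError(f"covariate {base!r} has zero variance")
            zcache[base] = (x - x.mean()) / sd
        cols[term] = zcache[base] ** 2 if term.endswith("^2") else zcache[base]
    return pd.DataFrame(cols, index=pregnancies.index)


def fit_gestation_length_model(
    pregnancies: pd.DataFrame,
    predictors=DEFAULT_PREDICTORS,
    *,
    n_chains: int = 2,
    n_steps: int = 500,
    n_keep: int = 500,
    seed: int = 0,
) -> PosteriorSamples:
    """Gaussian mixed model of observed gestation length.

    Continuous predictors are standardized (n−1 SD); temperature enters with a
    quadratic.  Female identity is a random intercept — degenerate (and
    warned about) with fewer than two females.
    """
    data = pregnancies.dropna(subset=["gestation_length"]).reset_index(drop=True)
    if len(data) == 0:
        raise ValueError("no pregnancies with observed gestation length")
    validate_gestation_lengths(data)
    X = _standardized_design(data, predictors)
    y = data["gestation_length"].to_numpy(float)
    groups = {"female": data["female_id"].astype(str).to_numpy()}
    return fit_gaussian_lmm(
        y, X, groups, n_chains=n_chains, n_steps=n_steps, n_keep=n_keep, seed=seed
    )


@dataclass(frozen=True)
class ExtensionDecomposition:
    """How one extra day of gestation is split across the two phases.

    ``share_pre`` is the posterior of the gestation-length coefficient on the
    inflection day (days of inflection shift per day of gestation); a value
    above 0.5 means extended pregnancies lengthen mostly the pre-inflection
    plateau.  ``share_post`` is its complement; the two sum to one draw-wise.
    """

    share_pre: np.ndarray
    share_post: np.ndarray
    level: float = 0.95

    @property
    def mean_shares(self) -> tuple:
        return float(np.mean(self.share_pre)), float(np.mean(self.share_post))

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, draws in (("share_pre", self.share_pre), ("share_post", self.share_post)):
            lo, hi = credible_interval(draws, self.level)
            rows.append({"phase": name, "estimate": float(np.mean(draws)),
                         "lower": lo, "upper": hi,
                         "pd": float(probability_of_direction(draws))})
        return pd.DataFrame(rows).set_index("phase")


def decompose_extension(
    model5_posterior: PosteriorSamples,
    coefficient: str = "k:gestation_length",
) -> ExtensionDecomposition:
    """Split gestational extension into pre-/post-inflection shares from the
    (unstandardized) gestation-length effect on the inflection day."""
    beta = np.asarray(model5_posterior.scalar(coefficient), dtype=float)
    return ExtensionDecomposition(share_pre=beta, share_post=1.0 - beta)


def fit_ipi_model(
    ipis: pd.DataFrame,
    *,
    include_female_effect: bool = False,
    n_chains: int = 2,
    n_steps: int = 500,
    n_keep: int = 500,
    seed: int = 0,
) -> PosteriorSamples:
    """Gaussian regression of the inter-pregnancy interval on gestation length.

    Expects the table produced by :func:`gwgrowth.cohort_qc.inter_pregnancy_intervals`.
    Gestation length enters in raw days.  A female random intercept is
    available but off by default.
    """
    data = ipis.dropna(subset=["ipi", "gestation_length"]).reset_index(drop=True)
    X = pd.DataFrame(
        {
            "intercept": np.ones(len(data)),
            "gestation_length": data["gestation_length"].to_numpy(float),
        }
    )
    groups = (
        {"female": data["female_id"].astype(str).to_numpy()}
        if include_female_effect
        else None
    )
    return fit_gaussian_lmm(
        data["ipi"].to_numpy(float), X, groups,
        n_chains=n_chains, n_steps=n_steps, n_keep=n_keep, seed=seed,
    )
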