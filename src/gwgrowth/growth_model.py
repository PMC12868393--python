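"""Biphasic (broken-stick) gestational growth curves and their hierarchical extension.

Maternal body mass during gestation is modelled as a continuous piecewise-linear
("broken stick") trajectory with a single inflection at day ``k``:

    mass(t) = m0 + b_pre * min(t, k) + b_post * max(0, t - k)

``m0`` is the body mass at the time origin (conception, or observed oestrus for
known-length pregnancies), ``b_pre`` the slope of the initial plateau phase and
``b_post`` the linear gain rate after the onset of gestational weight gain.
Continuity at ``k`` is structural (one intercept, two slopes), not estimated.

Each shape parameter may carry pregnancy-level covariates (fixed effects) and
random effects grouped by pregnancy, female or breeding season.  The observation
model is Gaussian with residual scale ``sigma``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

SHAPE_PARAMS = ("m0", "k", "b_pre", "b_post")

#: grouping-factor name -> column of the pregnancy table holding its labels
GROUP_COLUMNS = {"pregnancy": "pregnancy_id", "female": "female_id", "season": "season"}

#: categorical covariates with their pinned reference level (first) and the
#: level that gets the indicator column
CATEGORICAL_LEVELS = {
    "status": ("dominant", "subordinate"),
    "treatment": ("unfed", "fed"),
}


@dataclass(frozen=True)
class ShapeParams:
    """The four curve parameters of one pregnancy."""

    m0: float
    k: float
    b_pre: float
    b_post: float

    def predict(self, t):
        return predict_mass(self, t)


def predict_mass(shape: ShapeParams, t):
    """Evaluate the broken-stick curve at day(s) ``t`` (days >= 0, grams out)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("gestation day must be non-negative")
    out = shape.m0 + shape.b_pre * np.minimum(t, shape.k) + shape.b_post * np.maximum(
        0.0, t - shape.k
    )
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ModelSpec:
    """Which fixed effects and random effects act on each curve parameter.

    ``fixed`` maps a shape parameter to covariate terms.  A term is a covariate
    name, ``name^2`` for a quadratic in the standardized covariate, or ``a:b``
    for an interaction (elementwise product of the processed columns).
    ``random`` maps a shape parameter to grouping factors among
    ``pregnancy``, ``female`` and ``season``.
    """

    fixed: dict = field(default_factory=dict)
    random: dict = field(default_factory=dict)
    correlated_pregnancy_effects: bool = False
    unstandardized: tuple = ()
    time_origin: str = "conception"  # or "oestrus"
    horizon: float = 75.0
    name: str = "custom"

    def __post_init__(self):
        for d in (self.fixed, self.random):
            for p in d:
                if p not in SHAPE_PARAMS:
                    raise ValueError(f"unknown shape parameter {p!r}")
        for p, groups in self.random.items():
            for g in groups:
                if g not in GROUP_COLUMNS:
                    raise ValueError(f"unknown grouping factor {g!r}")
        if self.time_origin not in ("conception", "oestrus"):
            raise ValueError("time_origin must be 'conception' or 'oestrus'")

    def fixed_terms(self, param: str) -> tuple:
        return tuple(self.fixed.get(param, ()))

    def random_groups(self, param: str) -> tuple:
        return tuple(self.random.get(param, ()))

    def to_yaml(self) -> str:
        d = {
            "name": self.name,
            "fixed": {p: list(v) for p, v in self.fixed.items()},
            "random": {p: list(v) for p, v in self.random.items()},
            "correlated_pregnancy_effects": self.correlated_pregnancy_effects,
            "unstandardized": list(self.unstandardized),
            "time_origin": self.time_origin,
            "horizon": self.horizon,
        }
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelSpec":
        d = yaml.safe_load(text)
        return cls(
            fixed={p: tuple(v) for p, v in (d.get("fixed") or {}).items()},
            random={p: tuple(v) for p, v in (d.get("random") or {}).items()},
            correlated_pregnancy_effects=bool(d.get("correlated_pregnancy_effects", False)),
            unstandardized=tuple(d.get("unstandardized", ())),
            time_origin=d.get("time_origin", "conception"),
            horizon=float(d.get("horizon", 75.0)),
            name=d.get("name", "custom"),
        )


def model1(**kw) -> ModelSpec:
    """Litter size on inflection and post-slope; correlated pregnancy effects."""
    return ModelSpec(
        fixed={"k": ("litter_size",), "b_post": ("litter_size",)},
        random={p: ("pregnancy",) for p in SHAPE_PARAMS},
        correlated_pregnancy_effects=True,
        name="model1",
        **kw,
    )


def model1_simplified(**kw) -> ModelSpec:
    """Model 1 without litter-size fixed effects, used for per-pregnancy extraction."""
    return ModelSpec(
        fixed={},
        random={p: ("pregnancy",) for p in SHAPE_PARAMS},
        correlated_pregnancy_effects=True,
        name="model1_simplified",
        **kw,
    )


def model2(**kw) -> ModelSpec:
    """Model 1 plus female and breeding-season random effects on every parameter."""
    return ModelSpec(
        fixed={"k": ("litter_size",), "b_post": ("litter_size",)},
        random={p: ("pregnancy", "female", "season") for p in SHAPE_PARAMS},
        correlated_pregnancy_effects=True,
        name="model2",
        **kw,
    )


_M3_COMMON = (
    "litter_size",
    "status",
    "maternal_age",
    "maternal_age^2",
    "group_size",
    "group_size^2",
    "n_concurrent",
    "status:litter_size",
    "status:n_concurrent",
)
_M3_EXTRA = ("body_condition", "ndvi", "temperature", "temperature^2")


def model3(**kw) -> ModelSpec:
    """Maternal, social and environmental covariates on m0, k and b_post."""
    return ModelSpec(
        fixed={
            "m0": _M3_COMMON,
            "k": _M3_COMMON + _M3_EXTRA,
            "b_post": _M3_COMMON + _M3_EXTRA,
        },
        random={p: ("pregnancy", "female", "season") for p in SHAPE_PARAMS},
        correlated_pregnancy_effects=True,
        name="model3",
        **kw,
    )


def model4(**kw) -> ModelSpec:
    """Feeding-experiment variant: treatment and litter size on k and b_post."""
    return ModelSpec(
        fixed={"k": ("treatment", "litter_size"), "b_post": ("treatment", "litter_size")},
        random={p: ("pregnancy",) for p in SHAPE_PARAMS},
        correlated_pregnancy_effects=False,
        name="model4",
        **kw,
    )


def model5(**kw) -> ModelSpec:
    """Known-length pregnancies, time re-zeroed at oestrus; gestation length raw.

    The gestation-length coefficient on ``k`` stays in days/day so that values
    above 0.5 read as gestational extension falling mostly before the inflection.
    """
    return ModelSpec(
        fixed={
            "k": ("gestation_length", "litter_size"),
            "b_post": ("gestation_length", "litter_size"),
        },
        random={p: ("pregnancy", "female") for p in SHAPE_PARAMS},
        correlated_pregnancy_effects=False,
        unstandardized=("gestation_length",),
        time_origin="oestrus",
        name="model5",
        **kw,
    )


PRESETS = {
    "model1": model1,
    "model1_simplified": model1_simplified,
    "model2": model2,
    "model3": model3,
    "model4": model4,
    "model5": model5,
}


@dataclass
class Designs:
    """Per-shape-parameter design matrices plus the standardization used."""

    matrices: dict  # shape param -> DataFrame indexed by pregnancy_id
    standardization: dict  # covariate -> (mean, sd)

    def to_csv(self, directory):
        import pathlib

        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for p, m in self.matrices.items():
            m.to_csv(directory / f"design_{p}.csv")


def _base_column(name, pregnancies, spec, stats):
    if name in CATEGORICAL_LEVELS:
        ref, other = CATEGORICAL_LEVELS[name]
        col = pregnancies[name].astype(str)
        bad = ~col.isin((ref, other))
        if bad.any():
            raise ValueError(f"column {name!r} has levels outside {{{ref!r}, {other!r}}}")
        return (col == other).astype(float).rename(f"{name}[{other}]")
    x = pd.to_numeric(pregnancies[name], errors="raise").astype(float)
    if name in spec.unstandardized:
        return x
    if name not in stats:
        mu, sd = x.mean(), x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"covariate {name!r} has zero variance; cannot standardize")
        stats[name] = (float(mu), float(sd))
    mu, sd = stats[name]
    return (x - mu) / sd


def _term_column(term, pregnancies, spec, stats):
    if ":" in term:
        a, b = term.split(":", 1)
        ca = _term_column(a, pregnancies, spec, stats)
        cb = _term_column(b, pregnancies, spec, stats)
        return (ca * cb).rename(f"{ca.name}:{cb.name}")
    if term.endswith("^2"):
        c = _base_column(term[:-2], pregnancies, spec, stats)
        return (c * c).rename(f"{c.name}^2")
    return _base_column(term, pregnancies, spec, stats)


def build_design(spec: ModelSpec, pregnancies: pd.DataFrame) -> Designs:
    """Build one design matrix per shape parameter (intercept column first).

    Continuous covariates are centred and scaled by the n-1 sample SD computed
    on the pregnancy table (covariates are pregnancy-level); quadratics and
    interactions are formed from the standardized values.  Covariates listed in
    ``spec.unstandardized`` (gestation length in Model 5) enter raw.
    """
    def _bases(term):
        return [part.removesuffix("^2") for part in term.split(":")]

    missing = [
        base
        for p in SHAPE_PARAMS
        for term in spec.fixed_terms(p)
        for base in _bases(term)
        if base not in pregnancies.columns
    ]
    if missing:
        raise ValueError(f"pregnancy table is missing covariate column(s): {sorted(set(missing))}")
    for g_param, groups in spec.random.items():
        for g in groups:
            if GROUP_COLUMNS[g] not in pregnancies.columns:
                raise ValueError(f"pregnancy table is missing id column {GROUP_COLUMNS[g]!r}")

    idx = pregnancies["pregnancy_id"]
    stats: dict = {}
    matrices = {}
    for p in SHAPE_PARAMS:
        cols = [pd.Series(1.0, index=pregnancies.index, name="intercept")]
        for term in spec.fixed_terms(p):
            cols.append(_term_column(term, pregnancies, spec, stats))
        m = pd.concat(cols, axis=1)
        m.index = pd.Index(idx, name="pregnancy_id")
        matrices[p] = m
    return Designs(matrices=matrices, standardization=stats)


@dataclass
class ParameterVector:
    """One full point in parameter space for the hierarchical model.

    ``coefs`` holds population coefficients per shape parameter, aligned with
    the design columns; ``deviations`` holds per-level random deviations keyed
    by (shape parameter, grouping factor).  ``re_sd``, ``re_corr`` and ``sigma``
    complete the vector; only ``coefs``, ``deviations`` and ``sigma`` enter the
    conditional data likelihood.
    """

    coefs: dict
    sigma: float
    re_sd: dict = field(default_factory=dict)
    re_corr: np.ndarray | None = None
    deviations: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.isfinite(self.sigma) or self.sigma <= 0:
            raise ValueError("sigma must be positive and finite")
        for v in self.re_sd.values():
            if v < 0:
                raise ValueError("random-effect SDs must be non-negative")
        if self.re_corr is not None:
            c = np.asarray(self.re_corr, float)
            if not np.allclose(np.diag(c), 1.0) or np.any(np.linalg.eigvalsh(c) < -1e-8):
                raise ValueError(f"invalid correlation matrix:\n{c}")


def shape_values(params: ParameterVector, spec: ModelSpec, designs: Designs,
                 pregnancies: pd.DataFrame) -> pd.DataFrame:
    """Per-pregnancy shape parameters implied by coefficients plus deviations."""
    out = {}
    for p in SHAPE_PARAMS:
        m = designs.matrices[p]
        beta = np.asarray([params.coefs[p][c] for c in m.columns], float)
        val = m.to_numpy() @ beta
        for g in spec.random_groups(p):
            dev = params.deviations.get((p, g))
            if dev is None:
                continue
            labels = pregnancies[GROUP_COLUMNS[g]].to_numpy()
            val = val + dev.reindex(labels).fillna(0.0).to_numpy()
        out[p] = pd.Series(val, index=m.index)
    return pd.DataFrame(out)


def log_likelihood(params: ParameterVector, spec: ModelSpec,
                   weighings: pd.DataFrame, pregnancies: pd.DataFrame) -> float:
    """Gaussian log-likelihood of the weighings given one parameter vector.

    Sum over observations of ``Normal(mass | curve(day), sigma)`` where each
    pregnancy's curve is assembled from population coefficients plus that
    pregnancy's random deviations.  Random-effect SDs do not enter here: this
    is the likelihood conditional on the deviations.
    """
    days = weighings["day"].to_numpy(float)
    if np.any(days < 0):
        raise ValueError("weighing days must be non-negative")
    horizons = None
    if "gestation_length" in pregnancies.columns and spec.time_origin == "oestrus":
        horizons = pregnancies.set_index("pregnancy_id")["gestation_length"]
    unknown = set(weighings["pregnancy_id"]) - set(pregnancies["pregnancy_id"])
    if unknown:
        raise ValueError(f"weighings reference unknown pregnancies: {sorted(unknown)[:5]}")

    designs = build_design(spec, pregnancies)
    shapes = shape_values(params, spec, designs, pregnancies)
    pid = weighings["pregnancy_id"].to_numpy()
    m0 = shapes["m0"].reindex(pid).to_numpy()
    k = shapes["k"].reindex(pid).to_numpy()
    b_pre = shapes["b_pre"].reindex(pid).to_numpy()
    b_post = shapes["b_post"].reindex(pid).to_numpy()

    limit = spec.horizon if horizons is None else horizons.reindex(pid).fillna(spec.horizon).to_numpy()
    if np.any(days > np.asarray(limit) + 1e-9):
        raise ValueError("weighing day beyond the gestation horizon")

    mu = m0 + b_pre * np.minimum(days, k) + b_post * np.maximum(0.0, days - k)
    resid = weighings["mass_g"].to_numpy(float) - mu
    n = resid.size
    s2 = params.sigma**2
    return float(-0.5 * n * np.log(2 * np.pi * s2) - 0.5 * np.sum(resid**2) / s2)
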