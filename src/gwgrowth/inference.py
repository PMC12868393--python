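"""Posterior sampling and posterior summaries for the growth models.

The sampler is a collapsed ensemble MCMC: emcee explores only the parameters
the likelihood is genuinely nonlinear in (changepoint coefficients, variance
components, correlation parameters and non-centred changepoint deviations),
while the Gaussian-linear block — all linear coefficients plus linear random
effects — is integrated out analytically and re-drawn from its conjugate
conditional for every retained draw.  This keeps the explored space small and
well mixed even for hierarchical specifications.

Summaries follow field conventions for Bayesian regression tables: posterior
mean, SD, equal-tailed credible interval, and the probability of direction
(the fraction of the posterior sharing the median's sign, reported as p+/p−).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, cholesky, solve_triangular

from .growth_model import (
    GROUP_COLUMNS,
    SHAPE_PARAMS,
    Designs,
    ModelSpec,
    build_design,
)

_LOG2PI = np.log(2.0 * np.pi)


class ConvergenceError(RuntimeError):
    """Raised when a summary is requested from a non-converged posterior."""


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------


class ProbabilityOfDirection(float):
    """pd value in [0.5, 1] carrying the median's sign as ``.sign`` (+/−/0)."""

    sign: str

    def __new__(cls, value: float, sign: str):
        obj = super().__new__(cls, value)
        obj.sign = sign
        return obj

    def label(self) -> str:
        return {"+": "p+", "-": "p-", "0": "p0"}[self.sign]


def probability_of_direction(draws) -> ProbabilityOfDirection:
    """Fraction of posterior draws matching the median's sign.

    Draws exactly equal to zero count toward neither sign: the fractions are
    computed among the non-zero draws.  An all-zero posterior returns 0.5 with
    sign ``0``.
    """
    x = np.asarray(draws, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("probability_of_direction requires at least one draw")
    n_pos = int(np.sum(x > 0))
    n_neg = int(np.sum(x < 0))
    if n_pos + n_neg == 0:
        return ProbabilityOfDirection(0.5, "0")
    p_pos = n_pos / (n_pos + n_neg)
    p_neg = n_neg / (n_pos + n_neg)
    med = np.median(x)
    if med > 0:
        sign = "+"
    elif med < 0:
        sign = "-"
    else:
        sign = "+" if p_pos >= p_neg else "-"
    return ProbabilityOfDirection(max(p_pos, p_neg), sign)


def pd_interpretation(pd_value: float) -> str:
    """Interpretation band for a probability of direction."""
    if pd_value < 0.90:
        return "highly unlikely"
    if pd_value <= 0.95:
        return "moderate probability of existing"
    return "high probability of existing"


def credible_interval(draws, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed credible interval using linear-interpolation quantiles."""
    if not 0 < level < 1:
        raise ValueError("credible level must be in (0, 1)")
    x = np.asarray(draws, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("credible_interval requires at least one draw")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(x, [alpha, 1.0 - alpha], method="linear")
    return float(lo), float(hi)


def gwg_duration(k_draws, horizon: float = 75.0):
    """Duration of gestational weight gain implied by inflection draws."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    return horizon - np.asarray(k_draws, dtype=float)


def duration_effect(k_coefficient_draws):
    """Translate a covariate effect on the inflection day into an effect on
    GWG duration (elementwise negation; pd is unchanged, its sign flips)."""
    return -np.asarray(k_coefficient_draws, dtype=float)


@dataclass(frozen=True)
class Summary:
    """Posterior summary of one scalar parameter."""

    mean: float
    sd: float
    lower: float
    upper: float
    pd: ProbabilityOfDirection
    level: float = 0.95

    @property
    def interpretation(self) -> str:
        return pd_interpretation(self.pd)


def summarize_draws(draws, level: float = 0.95) -> Summary:
    x = np.asarray(draws, dtype=float).ravel()
    lo, hi = credible_interval(x, level)
    return Summary(
        mean=float(np.mean(x)),
        sd=float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        lower=lo,
        upper=hi,
        pd=probability_of_direction(x),
        level=level,
    )


# ---------------------------------------------------------------------------
# collapsed Gaussian linear algebra
# ---------------------------------------------------------------------------


@dataclass
class _BlockStructure:
    """Contiguous random-effect blocks sharing one deviation-covariance factor.

    Rows of the data are sorted by block.  ``Zb`` holds the block-local
    random-effect design row by row; deviations of block ``i`` have prior mean
    ``m[i]`` and covariance ``B B'`` (``B`` may be rank deficient when an SD
    is zero — the algebra below never inverts it).
    """

    starts: np.ndarray | None  # (nb,) first row of each block; None = no blocks
    Zb: np.ndarray | None = None  # (n, q)
    B: np.ndarray | None = None  # (q, q)
    m: np.ndarray | None = None  # (nb, q) prior means of the deviations
    obs_block: np.ndarray | None = None  # (n,) block index of each row

    @property
    def offset(self):
        if self.Zb is None or self.m is None:
            return 0.0
        return np.einsum("nq,nq->n", self.Zb, self.m[self.obs_block])


_NO_BLOCKS = _BlockStructure(starts=None)


def _collapsed_evidence(y, A, mu0, v0, sigma2, bs: _BlockStructure = _NO_BLOCKS):
    """Log evidence of y ~ N(A·γ + Z·δ, σ²I) with γ ~ N(μ0, diag v0) and the
    blockwise Gaussian deviations δ integrated out (batched Woodbury)."""
    n, p = A.shape
    r = y - A @ mu0 - bs.offset
    if bs.Zb is None:
        ata = A.T @ A / sigma2
        atr = A.T @ r / sigma2
        quad = r @ r / sigma2
        logdet_s = n * np.log(sigma2)
        cache = (None,) * 4
    else:
        W = bs.Zb @ bs.B  # (n, q)
        q = W.shape[1]
        starts = bs.starts
        nb = len(starts)
        WtW = np.add.reduceat(
            (W[:, :, None] * W[:, None, :]).reshape(n, q * q), starts, axis=0
        ).reshape(nb, q, q)
        Mw = np.eye(q)[None] + WtW / sigma2
        Lw = np.linalg.cholesky(Mw)
        logdet_s = n * np.log(sigma2) + 2.0 * np.sum(
            np.log(np.diagonal(Lw, axis1=1, axis2=2))
        )
        WtA = np.add.reduceat(
            (W[:, :, None] * A[:, None, :]).reshape(n, q * p), starts, axis=0
        ).reshape(nb, q, p)
        Wtr = np.add.reduceat(W * r[:, None], starts, axis=0)  # (nb, q)
        SA = np.linalg.solve(Mw, WtA)
        Sr = np.linalg.solve(Mw, Wtr[..., None])[..., 0]
        ata = (A.T @ A - np.einsum("bqp,bqr->pr", WtA, SA) / sigma2) / sigma2
        atr = (A.T @ r - np.einsum("bqp,bq->p", WtA, Sr) / sigma2) / sigma2
        quad = (r @ r - np.einsum("bq,bq->", Wtr, Sr) / sigma2) / sigma2
        cache = (W, Mw, Lw, None)
    H = np.diag(1.0 / v0) + ata
    cH = cholesky(H, lower=True)
    hb = cho_solve((cH, True), atr)
    logdet = logdet_s + np.sum(np.log(v0)) + 2.0 * np.sum(np.log(np.diag(cH)))
    logp = -0.5 * (n * _LOG2PI + logdet + quad - atr @ hb)
    return float(logp), (cH, hb) + cache


def _conditional_draw(rng, y, A, mu0, v0, sigma2, bs, cache):
    """Draw (γ, per-block deviations) from their exact conditional given the
    data and the collapsed parameters."""
    cH, hb, W, Mw, Lw, _ = cache
    p = A.shape[1]
    gamma = mu0 + hb + solve_triangular(cH.T, rng.standard_normal(p), lower=False)
    if bs.Zb is None:
        return gamma, None
    e = y - A @ gamma - bs.offset
    q = W.shape[1]
    nb = len(bs.starts)
    Wte = np.add.reduceat(W * e[:, None], bs.starts, axis=0)
    mean_u = np.linalg.solve(Mw, Wte[..., None])[..., 0] / sigma2
    z = rng.standard_normal((nb, q, 1))
    u = mean_u + np.linalg.solve(np.transpose(Lw, (0, 2, 1)), z)[..., 0]
    d = u @ bs.B.T
    if bs.m is not None:
        d = d + bs.m
    return gamma, d


def _chol_from_partials(z):
    """Cholesky factor of a correlation matrix from unconstrained canonical
    partial correlations (tanh link)."""
    r = np.tanh(np.asarray(z, dtype=float))
    n = r.size
    d = int(round((1 + np.sqrt(1 + 8 * n)) / 2))
    L = np.zeros((d, d))
    L[0, 0] = 1.0
    idx = 0
    for i in range(1, d):
        rem = 1.0
        for j in range(i):
            L[i, j] = r[idx] * np.sqrt(rem)
            rem -= L[i, j] ** 2
            idx += 1
        L[i, i] = np.sqrt(max(rem, 1e-12))
    return L


def _lkj_like_logprior(z, eta=2.0):
    """Log prior for the partial-correlation parameterization: each canonical
    partial correlation has density ∝ (1−r²)^(η−1), plus the tanh Jacobian."""
    r2 = np.tanh(np.asarray(z, dtype=float)) ** 2
    return float(np.sum(eta * np.log1p(-r2)))


def _halfnormal_logprior(log_s, scale):
    s = np.exp(log_s)
    return float(-0.5 * (s / scale) ** 2 + log_s)


# ---------------------------------------------------------------------------
# posterior container
# ---------------------------------------------------------------------------


@dataclass
class PosteriorSamples:
    """MCMC draws in long-wide form (chain, draw, one column per parameter)."""

    draws: pd.DataFrame
    diagnostics: pd.DataFrame
    spec: ModelSpec | None = None
    designs: Designs | None = None
    pregnancies: pd.DataFrame | None = None
    seed: int | None = None
    attrs: dict = field(default_factory=dict)

    @property
    def parameter_names(self) -> list[str]:
        return [c for c in self.draws.columns if c not in ("chain", "draw")]

    @property
    def population_names(self) -> list[str]:
        return [c for c in self.parameter_names if not c.startswith("dev:")]

    @property
    def n_chains(self) -> int:
        return int(self.draws["chain"].nunique())

    def scalar(self, name: str) -> np.ndarray:
        if name not in self.draws.columns:
            raise KeyError(f"no parameter named {name!r}")
        return self.draws[name].to_numpy(float)

    @property
    def max_rhat(self) -> float:
        return float(self.diagnostics["rhat"].max())

    def check_convergence(self, threshold: float = 1.05):
        bad = self.diagnostics[self.diagnostics["rhat"] > threshold]
        if len(bad):
            raise ConvergenceError(
                "posterior has not converged (R-hat > "
                f"{threshold}) for: {', '.join(bad.index[:8])}; "
                "pass allow_nonconverged=True to summarize anyway"
            )

    def summary(self, params=None, level: float = 0.95,
                allow_nonconverged: bool = False) -> pd.DataFrame:
        """Posterior summary table (estimate, SD, CrI, pd, interpretation)."""
        if not allow_nonconverged:
            self.check_convergence()
        params = list(params) if params is not None else self.population_names
        rows = []
        for name in params:
            s = summarize_draws(self.scalar(name), level)
            rows.append(
                {
                    "parameter": name,
                    "estimate": s.mean,
                    "sd": s.sd,
                    "lower": s.lower,
                    "upper": s.upper,
                    "pd": float(s.pd),
                    "direction": s.pd.sign,
                    "interpretation": s.interpretation,
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def pregnancy_shapes(self) -> dict:
        """Per-draw, per-pregnancy curve parameters (fixed part + deviations).

        Returns a dict mapping each shape parameter to an array of shape
        (n_draws, n_pregnancies), columns ordered as in the design index.
        """
        if self.designs is None or self.pregnancies is None or self.spec is None:
            raise ValueError("this posterior does not carry a growth-model design")
        out = {}
        preg = self.pregnancies
        for p in SHAPE_PARAMS:
            m = self.designs.matrices[p]
            cols = [f"{p}:{c}" for c in m.columns]
            vals = self.draws[cols].to_numpy(float) @ m.to_numpy().T
            for g in self.spec.random_groups(p):
                labels = preg[GROUP_COLUMNS[g]].astype(str).to_numpy()
                dev_cols = [f"dev:{g}:{p}:{lab}" for lab in labels]
                present = [c in self.draws.columns for c in dev_cols]
                if all(present):
                    vals = vals + self.draws[dev_cols].to_numpy(float)
            out[p] = vals
        return out


def _make_diagnostics(named_chains: dict, n_chains: int) -> pd.DataFrame:
    """Split-R-hat and bulk ESS per parameter via arviz."""
    rows = {}
    for name, arr in named_chains.items():
        a = np.asarray(arr)  # (chain, draw)
        if np.allclose(a.std(), 0.0):
            rows[name] = (1.0, float(a.size))
            continue
        da = az.convert_to_dataset(a)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat = float(np.asarray(az.rhat(da)["x"].values).item())
            ess = float(np.asarray(az.ess(da)["x"].values).item())
        rows[name] = (rhat if np.isfinite(rhat) else 1.0, ess)
    return pd.DataFrame(rows, index=["rhat", "ess"]).T


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrowthPriors:
    """Weakly informative defaults for the growth model, on natural scales.

    Gaussian (mean, sd) priors for location parameters, half-normal scales for
    SDs, and a partial-correlation Beta-type prior (eta) for the correlation
    matrix of pregnancy-level effects.
    """

    m0_intercept: tuple = (750.0, 100.0)
    m0_coef: tuple = (0.0, 50.0)
    k_intercept: tuple = (37.5, 15.0)
    k_coef: tuple = (0.0, 10.0)
    slope_intercept: tuple = (0.0, 10.0)
    slope_coef: tuple = (0.0, 10.0)
    sd_scale: float = 50.0
    sigma_scale: float = 50.0
    corr_eta: float = 2.0

    def coef_prior(self, param: str, column: str) -> tuple:
        if param == "m0":
            return self.m0_intercept if column == "intercept" else self.m0_coef
        if param == "k":
            return self.k_intercept if column == "intercept" else self.k_coef
        return self.slope_intercept if column == "intercept" else self.slope_coef


# ---------------------------------------------------------------------------
# the growth-model fitter
# ---------------------------------------------------------------------------

_LINEAR_PARAMS = ("m0", "b_pre", "b_post")


class _GrowthProblem:
    """Pre-computed data structures and the collapsed log-posterior."""

    def __init__(self, spec, weighings, pregnancies, priors):
        self.spec = spec
        self.priors = priors
        self.designs = build_design(spec, pregnancies)
        self.pregnancies = pregnancies.reset_index(drop=True)

        unknown = set(weighings["pregnancy_id"]) - set(pregnancies["pregnancy_id"])
        if unknown:
            raise ValueError(
                f"weighings reference unknown pregnancies: {sorted(unknown)[:5]}"
            )
        pid_order = list(self.pregnancies["pregnancy_id"])
        w = weighings.copy()
        w["_pos"] = w["pregnancy_id"].map({p: i for i, p in enumerate(pid_order)})
        w = w.sort_values(["_pos", "day"], kind="stable").reset_index(drop=True)
        self.weighings = w
        self.t = w["day"].to_numpy(float)
        if np.any(self.t < 0):
            raise ValueError("weighing days must be non-negative")
        self.y = w["mass_g"].to_numpy(float)
        self.obs_pos = w["_pos"].to_numpy(int)
        self.n_obs = self.y.size
        self.n_preg = len(pid_order)
        self.pid_order = pid_order
        counts = np.bincount(self.obs_pos, minlength=self.n_preg)
        if np.any(counts == 0):
            raise ValueError("every pregnancy needs at least one weighing")
        self.block_starts = np.concatenate([[0], np.cumsum(counts)[:-1]]).astype(int)

        # fixed-effect designs (pregnancy level -> observation level); the
        # sampler centres non-intercept columns so intercepts (and their
        # priors, and the logistic map on k) describe the covariate mean —
        # essential when a covariate enters raw, like gestation length.
        # Draws are translated back to the raw parameterization on expansion.
        self.cols = {p: list(self.designs.matrices[p].columns) for p in SHAPE_PARAMS}
        self.Xp = {}
        self.centers = {}
        for p in SHAPE_PARAMS:
            X = self.designs.matrices[p].to_numpy(float).copy()
            c = X.mean(axis=0)
            c[0] = 0.0  # intercept column stays
            X -= c
            self.Xp[p] = X
            self.centers[p] = c
        self.Xo = {p: self.Xp[p][self.obs_pos] for p in _LINEAR_PARAMS}
        self.Xk = self.Xp["k"]

        # random-effect structure
        self.preg_re = [p for p in SHAPE_PARAMS if "pregnancy" in spec.random_groups(p)]
        self.k_in_preg = "k" in self.preg_re
        self.block_lin = [p for p in _LINEAR_PARAMS if p in self.preg_re]
        self.correlated = spec.correlated_pregnancy_effects and len(self.preg_re) >= 2
        self.block_order = (["k"] if self.k_in_preg else []) + self.block_lin

        # non-pregnancy (crossed) random effects: linear ones join gamma,
        # k ones are explicit non-centred deviations
        self.crossed = []  # (param, group, levels, codes)
        self.k_crossed = []
        for p in SHAPE_PARAMS:
            for g in spec.random_groups(p):
                if g == "pregnancy":
                    continue
                labels = self.pregnancies[GROUP_COLUMNS[g]].astype(str)
                levels = sorted(labels.unique())
                codes = labels.map({l: i for i, l in enumerate(levels)}).to_numpy(int)
                entry = (p, g, levels, codes)
                (self.k_crossed if p == "k" else self.crossed).append(entry)

        # gamma layout: fixed linear coefs then crossed linear deviations
        self.gamma_names = []
        mu0, v0const = [], []
        for p in _LINEAR_PARAMS:
            for c in self.cols[p]:
                self.gamma_names.append(f"{p}:{c}")
                mu, sd = priors.coef_prior(p, c)
                mu0.append(mu)
                v0const.append(sd**2)
        self.n_fixed = len(self.gamma_names)
        for p, g, levels, codes in self.crossed:
            for lvl in levels:
                self.gamma_names.append(f"dev:{g}:{p}:{lvl}")
                mu0.append(0.0)
                v0const.append(np.nan)  # filled from the sampled SD
        self.mu0 = np.asarray(mu0)
        self.v0const = np.asarray(v0const)

        # psi layout
        self.psi_names = ["kappa"]
        self.psi_names += [f"k:{c}" for c in self.cols["k"] if c != "intercept"]
        self.psi_names.append("log_sigma")
        self.sd_keys = []
        for p in SHAPE_PARAMS:
            for g in spec.random_groups(p):
                self.sd_keys.append((g, p))
                self.psi_names.append(f"log_sd:{g}:{p}")
        self.n_cor = 0
        if self.correlated:
            d = len(self.block_order)
            self.n_cor = d * (d - 1) // 2
            self.psi_names += [f"z_cor:{i}" for i in range(self.n_cor)]
        self.raw_layout = []  # (kind, group, count)
        if self.k_in_preg:
            self.raw_layout.append(("pregnancy", self.n_preg))
            self.psi_names += [f"raw:pregnancy:k:{pid}" for pid in pid_order]
        for p, g, levels, codes in self.k_crossed:
            self.raw_layout.append((g, len(levels)))
            self.psi_names += [f"raw:{g}:k:{lvl}" for lvl in levels]
        self.ndim = len(self.psi_names)

        self._ix = {n: i for i, n in enumerate(self.psi_names)}
        self.k_coef_idx = [self._ix[f"k:{c}"] for c in self.cols["k"] if c != "intercept"]
        self.sd_idx = {key: self._ix[f"log_sd:{key[0]}:{key[1]}"] for key in self.sd_keys}
        self.cor_sl = (
            slice(self._ix["z_cor:0"], self._ix["z_cor:0"] + self.n_cor)
            if self.n_cor
            else slice(0, 0)
        )
        start = 1 + len(self.k_coef_idx) + 1 + len(self.sd_keys) + self.n_cor
        self.raw_slices = []
        for g, count in self.raw_layout:
            self.raw_slices.append((g, slice(start, start + count)))
            start += count

    # -- psi parsing helpers -------------------------------------------------

    def _unpack(self, psi):
        kappa = psi[0]
        e = 1.0 / (1.0 + np.exp(-kappa))
        k0 = self.spec.horizon * e
        beta_k = psi[self.k_coef_idx]
        sigma = np.exp(psi[self._ix["log_sigma"]])
        sds = {key: np.exp(psi[i]) for key, i in self.sd_idx.items()}
        z = psi[self.cor_sl]
        raws = {g: psi[sl] for g, sl in self.raw_slices}
        return k0, e, beta_k, sigma, sds, z, raws

    def _k_values(self, k0, beta_k, sds, raws):
        k = np.full(self.n_preg, k0)
        if self.k_coef_idx:
            k = k + self.Xk[:, 1:] @ beta_k
        if self.k_in_preg:
            k = k + sds[("pregnancy", "k")] * raws["pregnancy"]
        for p, g, levels, codes in self.k_crossed:
            k = k + sds[(g, "k")] * raws[g][codes]
        return k

    def _assemble(self, psi):
        k0, e, beta_k, sigma, sds, z, raws = self._unpack(psi)
        k_preg = self._k_values(k0, beta_k, sds, raws)
        k_obs = k_preg[self.obs_pos]
        s_pre = np.minimum(self.t, k_obs)
        s_post = np.maximum(0.0, self.t - k_obs)
        basis = {"m0": np.ones_like(self.t), "b_pre": s_pre, "b_post": s_post}

        cols = [self.Xo["m0"], self.Xo["b_pre"] * s_pre[:, None],
                self.Xo["b_post"] * s_post[:, None]]
        v0 = self.v0const.copy()
        pos = self.n_fixed
        for p, g, levels, codes in self.crossed:
            ind = np.zeros((self.n_obs, len(levels)))
            ind[np.arange(self.n_obs), codes[self.obs_pos]] = basis[p]
            cols.append(ind)
            v0[pos: pos + len(levels)] = max(sds[(g, p)] ** 2, 1e-12)
            pos += len(levels)
        A = np.hstack(cols)

        # pregnancy-level marginalized blocks (one shared covariance factor)
        if self.block_lin:
            d = len(self.block_order)
            Lc = _chol_from_partials(z) if self.correlated else np.eye(d)
            D = np.diag([sds[("pregnancy", p)] for p in self.block_order])
            Lfull = D @ Lc
            if self.k_in_preg:
                m_mult = Lfull[1:, 0]
                B = Lfull[1:, 1:]
                m = raws["pregnancy"][:, None] * m_mult[None, :]
            else:
                B = Lfull
                m = None
            Zb = np.column_stack([basis[p] for p in self.block_lin])
            bs = _BlockStructure(starts=self.block_starts, Zb=Zb, B=B, m=m,
                                 obs_block=self.obs_pos)
        else:
            bs = _NO_BLOCKS
        return A, v0, sigma, bs, k_preg, (k0, e, beta_k, sds, z, raws)

    def log_prob(self, psi):
        try:
            A, v0, sigma, bs, k_preg, parts = self._assemble(psi)
        except FloatingPointError:
            return -np.inf
        k0, e, beta_k, sds, z, raws = parts
        if not np.isfinite(sigma) or sigma <= 0 or e <= 0 or e >= 1:
            return -np.inf
        lp = 0.0
        mu_k, sd_k = self.priors.k_intercept
        lp += -0.5 * ((k0 - mu_k) / sd_k) ** 2
        lp += np.log(self.spec.horizon * e * (1 - e))  # Jacobian of the logistic map
        for b, idx in zip(beta_k, self.k_coef_idx):
            mu, sd = self.priors.k_coef
            lp += -0.5 * ((b - mu) / sd) ** 2
        lp += _halfnormal_logprior(np.log(sigma), self.priors.sigma_scale)
        for key, s in sds.items():
            lp += _halfnormal_logprior(np.log(s), self.priors.sd_scale)
        if self.n_cor:
            lp += _lkj_like_logprior(z, self.priors.corr_eta)
        for g, sl in self.raw_slices:
            r = raws[g]
            lp += float(-0.5 * r @ r)
        if not np.isfinite(lp):
            return -np.inf
        try:
            evid, _ = _collapsed_evidence(self.y, A, self.mu0, v0, sigma**2, bs)
        except np.linalg.LinAlgError:
            return -np.inf
        return lp + evid

    # -- initialization ------------------------------------------------------

    def initial_point(self, rng):
        psi = np.zeros(self.ndim)
        k_init = self.spec.horizon * rng.uniform(0.38, 0.52)
        psi[0] = np.log(k_init / (self.spec.horizon - k_init))
        psi[self.k_coef_idx] = 0.1 * rng.standard_normal(len(self.k_coef_idx))
        # rough residual scale from within-pregnancy first differences
        diffs = np.diff(self.y)
        same = self.obs_pos[1:] == self.obs_pos[:-1]
        s0 = np.std(diffs[same]) / np.sqrt(2) if same.any() else np.std(self.y) / 10
        psi[self._ix["log_sigma"]] = np.log(max(s0, 1.0)) + 0.2 * rng.standard_normal()
        sd_guess = {"m0": 30.0, "k": 3.0, "b_pre": 0.2, "b_post": 0.8}
        for (g, p), i in self.sd_idx.items():
            psi[i] = np.log(sd_guess[p]) + 0.3 * rng.standard_normal()
        if self.n_cor:
            psi[self.cor_sl] = 0.1 * rng.standard_normal(self.n_cor)
        for g, sl in self.raw_slices:
            psi[sl] = 0.3 * rng.standard_normal(sl.stop - sl.start)
        return psi

    # -- expansion of a kept psi draw into named parameters ------------------

    def expand_draw(self, psi, rng):
        A, v0, sigma, bs, k_preg, parts = self._assemble(psi)
        k0, e, beta_k, sds, z, raws = parts
        _, cache = _collapsed_evidence(self.y, A, self.mu0, v0, sigma**2, bs)
        gamma, devs = _conditional_draw(
            rng, self.y, A, self.mu0, v0, sigma**2, bs, cache
        )
        out = {}
        # translate intercepts back to the raw (uncentred) parameterization
        out["k:intercept"] = k0 - float(self.centers["k"][1:] @ beta_k)
        for b, name in zip(beta_k, [c for c in self.cols["k"] if c != "intercept"]):
            out[f"k:{name}"] = b
        for name, val in zip(self.gamma_names, gamma):
            out[name] = val
        for p in _LINEAR_PARAMS:
            betas = np.array([out[f"{p}:{c}"] for c in self.cols[p][1:]])
            out[f"{p}:intercept"] -= float(self.centers[p][1:] @ betas)
        out["sigma"] = sigma
        for (g, p), s in sds.items():
            out[f"sd:{g}:{p}"] = s
        if self.n_cor:
            Lc = _chol_from_partials(z)
            C = Lc @ Lc.T
            names = self.block_order
            for i in range(len(names)):
                for j in range(i):
                    out[f"cor:pregnancy:{names[j]},{names[i]}"] = C[i, j]
        if self.k_in_preg:
            dk = sds[("pregnancy", "k")] * raws["pregnancy"]
            for pid, v in zip(self.pid_order, dk):
                out[f"dev:pregnancy:k:{pid}"] = v
        for p, g, levels, codes in self.k_crossed:
            dk = sds[(g, "k")] * raws[g]
            for lvl, v in zip(levels, dk):
                out[f"dev:{g}:k:{lvl}"] = v
        if self.block_lin:
            for i, (pid, d) in enumerate(zip(self.pid_order, devs)):
                for jp, p in enumerate(self.block_lin):
                    out[f"dev:pregnancy:{p}:{pid}"] = d[jp] if d is not None else 0.0
        return out


def _run_ensemble(log_prob, init_points, n_steps, seed):
    n_walkers, ndim = init_points.shape
    sampler = emcee.EnsembleSampler(n_walkers, ndim, log_prob)
    state = emcee.State(init_points, random_state=np.random.RandomState(seed).get_state())
    sampler.run_mcmc(state, n_steps, progress=False, skip_initial_state_check=True)
    return sampler.get_chain()  # (steps, walkers, ndim)


def fit(
    spec: ModelSpec,
    weighings: pd.DataFrame,
    pregnancies: pd.DataFrame,
    priors: GrowthPriors | None = None,
    *,
    n_chains: int = 2,
    n_steps: int = 900,
    n_warmup: int | None = None,
    n_keep: int = 500,
    seed: int = 0,
    rhat_warn: float = 1.05,
) -> PosteriorSamples:
    """Sample the posterior of a piecewise growth model.

    Runs ``n_chains`` independent ensembles over the collapsed parameter
    space, discards ``n_warmup`` steps, retains ``n_keep`` draws per chain and
    expands each into the full parameter vector (linear coefficients and
    random deviations re-drawn from their conjugate conditional).

    A known degenerate regime: if every weighing falls before the inflection
    the post-inflection slope is informed only by its prior and the inflection
    day drifts toward the end of the horizon; R-hat diagnostics flag this.
    """
    if n_chains < 2:
        raise ValueError("need at least 2 chains for convergence diagnostics")
    priors = priors or GrowthPriors()
    problem = _GrowthProblem(spec, weighings, pregnancies, priors)
    n_warmup = n_steps // 3 if n_warmup is None else n_warmup
    n_walkers = max(2 * problem.ndim + 2, 16)
    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.generate_state(2 * n_chains)

    chain_frames = []
    psi_chains = {n: [] for n in problem.psi_names}
    for c in range(n_chains):
        rng = np.random.default_rng(chain_seeds[2 * c])
        init = np.vstack([problem.initial_point(rng) for _ in range(n_walkers)])
        chain = _run_ensemble(
            problem.log_prob, init, n_steps, int(chain_seeds[2 * c + 1] % (2**31))
        )
        kept = chain[n_warmup:]  # (steps, walkers, ndim)
        flat = kept.reshape(-1, problem.ndim)
        stride = max(len(flat) // n_keep, 1)
        sel = flat[::stride][:n_keep]
        for j, name in enumerate(problem.psi_names):
            psi_chains[name].append(kept[:, :, j].reshape(-1))
        rows = [problem.expand_draw(psi, rng) for psi in sel]
        frame = pd.DataFrame(rows)
        frame.insert(0, "draw", np.arange(len(frame)))
        frame.insert(0, "chain", c)
        chain_frames.append(frame)

    draws = pd.concat(chain_frames, ignore_index=True)
    diag_source = {
        n: np.vstack(v) for n, v in psi_chains.items() if not n.startswith("raw:")
    }
    diagnostics = _make_diagnostics(diag_source, n_chains)
    if (diagnostics["rhat"] > rhat_warn).any():
        bad = diagnostics[diagnostics["rhat"] > rhat_warn]
        warnings.warn(
            "possible non-convergence (R-hat > "
            f"{rhat_warn}):\n{bad.round(3).to_string()}",
            RuntimeWarning,
            stacklevel=2,
        )
    return PosteriorSamples(
        draws=draws,
        diagnostics=diagnostics,
        spec=spec,
        designs=problem.designs,
        pregnancies=problem.pregnancies,
        seed=seed,
        attrs={
            "n_steps": n_steps,
            "n_warmup": n_warmup,
            "n_walkers": n_walkers,
            "sampler": "emcee (collapsed)",
        },
    )


# ---------------------------------------------------------------------------
# generic Gaussian linear mixed model (collapsed over everything linear)
# ---------------------------------------------------------------------------


def fit_gaussian_lmm(
    y,
    X: pd.DataFrame,
    groups: dict | None = None,
    *,
    n_chains: int = 2,
    n_steps: int = 500,
    n_warmup: int | None = None,
    n_keep: int = 500,
    seed: int = 0,
    coef_prior_sd: float | None = None,
    intercept_prior: tuple | None = None,
    sigma_scale: float | None = None,
    sd_scale: float | None = None,
    rhat_warn: float = 1.05,
) -> PosteriorSamples:
    """Bayesian Gaussian linear mixed model y = Xβ + Σ_g Z_g u_g + ε.

    Only the variance components are sampled by MCMC; coefficients and random
    effects are conjugately re-drawn per retained draw.  The grouping with the
    most levels is marginalized blockwise for speed.  Priors default to weakly
    informative scales derived from sd(y).
    """
    y = np.asarray(y, dtype=float)
    X = X.copy()
    groups = {k: np.asarray(v).astype(str) for k, v in (groups or {}).items()}
    if len(y) != len(X):
        raise ValueError("y and X must have the same length")
    if len(y) < 2:
        raise ValueError("need at least two observations")
    sdy = max(float(np.std(y, ddof=1)), 1e-8)
    coef_prior_sd = coef_prior_sd if coef_prior_sd is not None else 10.0 * sdy
    intercept_prior = intercept_prior or (float(np.mean(y)), 10.0 * sdy)
    sigma_scale = sigma_scale if sigma_scale is not None else 5.0 * sdy
    sd_scale = sd_scale if sd_scale is not None else 2.0 * sdy

    group_names = list(groups)
    if len(set(map(len, groups.values())) | {len(y)}) > 1:
        raise ValueError("group label arrays must match the data length")
    for g in group_names:
        if len(np.unique(groups[g])) < 2:
            warnings.warn(
                f"grouping {g!r} has a single level; its variance is not identified",
                RuntimeWarning,
                stacklevel=2,
            )

    block_group = None
    if group_names:
        block_group = max(group_names, key=lambda g: len(np.unique(groups[g])))

    # order observations by the blocked group
    if block_group is not None:
        order = np.argsort(groups[block_group], kind="stable")
    else:
        order = np.arange(len(y))
    y_o = y[order]
    Xo = X.to_numpy(float)[order]
    block_starts = None
    block_levels = None
    obs_block = None
    if block_group is not None:
        labs = groups[block_group][order]
        block_levels, block_starts = np.unique(labs, return_index=True)
        block_starts = block_starts.astype(int)
        obs_block = np.searchsorted(block_levels, labs)

    gamma_names = [f"beta:{c}" for c in X.columns]
    mu0 = [intercept_prior[0] if c == "intercept" else 0.0 for c in X.columns]
    v0c = [
        intercept_prior[1] ** 2 if c == "intercept" else coef_prior_sd**2
        for c in X.columns
    ]
    crossed = [g for g in group_names if g != block_group]
    crossed_levels = {}
    A_cols = [Xo]
    for g in crossed:
        labs = groups[g][order]
        levels = sorted(np.unique(labs))
        crossed_levels[g] = levels
        codes = pd.Series(labs).map({l: i for i, l in enumerate(levels)}).to_numpy(int)
        ind = np.zeros((len(y), len(levels)))
        ind[np.arange(len(y)), codes] = 1.0
        A_cols.append(ind)
        gamma_names += [f"dev:{g}:{l}" for l in levels]
        mu0 += [0.0] * len(levels)
        v0c += [np.nan] * len(levels)
    A = np.hstack(A_cols)
    mu0 = np.asarray(mu0)
    v0c = np.asarray(v0c)

    psi_names = ["log_sigma"] + [f"log_sd:{g}" for g in group_names]
    ndim = len(psi_names)
    sd_pos = {g: 1 + i for i, g in enumerate(group_names)}

    fill_slices = []
    pos = Xo.shape[1]
    for g in crossed:
        n_l = len(crossed_levels[g])
        fill_slices.append((g, slice(pos, pos + n_l)))
        pos += n_l

    ones_col = np.ones((len(y), 1))

    def make_blocks(sds):
        if block_group is None:
            return _NO_BLOCKS
        return _BlockStructure(
            starts=block_starts, Zb=ones_col,
            B=np.array([[sds[block_group]]]), m=None, obs_block=obs_block,
        )

    def log_prob(psi):
        sigma = np.exp(psi[0])
        if not 1e-8 * sdy < sigma < 1e8 * sdy:
            return -np.inf
        sds = {g: np.exp(psi[sd_pos[g]]) for g in group_names}
        lp = _halfnormal_logprior(psi[0], sigma_scale)
        for g in group_names:
            lp += _halfnormal_logprior(psi[sd_pos[g]], sd_scale)
        v0 = v0c.copy()
        for g, sl in fill_slices:
            v0[sl] = max(sds[g] ** 2, 1e-12)
        try:
            evid, _ = _collapsed_evidence(y_o, A, mu0, v0, sigma**2, make_blocks(sds))
        except np.linalg.LinAlgError:
            return -np.inf
        return lp + evid

    n_warmup = n_steps // 3 if n_warmup is None else n_warmup
    n_walkers = max(2 * ndim + 2, 12)
    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.generate_state(2 * n_chains)
    frames = []
    psi_chains = {n: [] for n in psi_names}
    for c in range(n_chains):
        rng = np.random.default_rng(chain_seeds[2 * c])
        init = np.log(sdy / 2) + 0.4 * rng.standard_normal((n_walkers, ndim))
        chain = _run_ensemble(log_prob, init, n_steps, int(chain_seeds[2 * c + 1] % (2**31)))
        kept = chain[n_warmup:]
        flat = kept.reshape(-1, ndim)
        stride = max(len(flat) // n_keep, 1)
        sel = flat[::stride][:n_keep]
        for j, n in enumerate(psi_names):
            psi_chains[n].append(kept[:, :, j].reshape(-1))
        rows = []
        for psi in sel:
            sigma = np.exp(psi[0])
            sds = {g: np.exp(psi[sd_pos[g]]) for g in group_names}
            v0 = v0c.copy()
            for g, sl in fill_slices:
                v0[sl] = max(sds[g] ** 2, 1e-12)
            blocks = make_blocks(sds)
            _, cache = _collapsed_evidence(y_o, A, mu0, v0, sigma**2, blocks)
            gamma, devs = _conditional_draw(rng, y_o, A, mu0, v0, sigma**2, blocks, cache)
            row = dict(zip(gamma_names, gamma))
            row["sigma"] = sigma
            for g in group_names:
                row[f"sd:{g}"] = sds[g]
            if block_group is not None and devs is not None:
                for lvl, d in zip(block_levels, devs[:, 0]):
                    row[f"dev:{block_group}:{lvl}"] = float(d)
            rows.append(row)
        frame = pd.DataFrame(rows)
        frame.insert(0, "draw", np.arange(len(frame)))
        frame.insert(0, "chain", c)
        frames.append(frame)

    draws = pd.concat(frames, ignore_index=True)
    diagnostics = _make_diagnostics({n: np.vstack(v) for n, v in psi_chains.items()}, n_chains)
    if (diagnostics["rhat"] > rhat_warn).any():
        warnings.warn("possible non-convergence in variance components", RuntimeWarning,
                      stacklevel=2)
    return PosteriorSamples(draws=draws, diagnostics=diagnostics, seed=seed,
                            attrs={"model": "gaussian_lmm"})


# ---------------------------------------------------------------------------
# Bernoulli (logit) regression, optionally with random intercepts
# ---------------------------------------------------------------------------


def fit_logistic(
    y,
    X: pd.DataFrame,
    groups: dict | None = None,
    *,
    n_chains: int = 2,
    n_steps: int = 1200,
    n_warmup: int | None = None,
    n_keep: int = 500,
    seed: int = 0,
    coef_prior_sd: float = 5.0,
    sd_scale: float = 1.0,
    rhat_warn: float = 1.05,
    separation_threshold: float = 10.0,
) -> PosteriorSamples:
    """Bayesian logistic regression with optional random intercepts.

    The full parameter vector (coefficients, deviations, log group SDs) is
    explored by the ensemble sampler; suited to modest numbers of levels.
    Posterior mass beyond ``separation_threshold`` on the logit scale flags
    likely complete separation with a warning.
    """
    y = np.asarray(y, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("logistic response must be 0/1")
    Xm = X.to_numpy(float)
    n, p = Xm.shape
    groups = {k: np.asarray(v).astype(str) for k, v in (groups or {}).items()}
    group_names = list(groups)
    level_maps = {}
    codes = {}
    for g in group_names:
        levels = sorted(np.unique(groups[g]))
        level_maps[g] = levels
        codes[g] = pd.Series(groups[g]).map({l: i for i, l in enumerate(levels)}).to_numpy(int)

    names = [f"beta:{c}" for c in X.columns]
    for g in group_names:
        names += [f"dev:{g}:{l}" for l in level_maps[g]]
    names += [f"log_sd:{g}" for g in group_names]
    ndim = len(names)
    dev_slices = {}
    pos = p
    for g in group_names:
        dev_slices[g] = slice(pos, pos + len(level_maps[g]))
        pos += len(level_maps[g])
    sd_pos = {g: pos + i for i, g in enumerate(group_names)}

    def log_prob(theta):
        beta = theta[:p]
        eta = Xm @ beta
        lp = -0.5 * np.sum((beta / coef_prior_sd) ** 2)
        for g in group_names:
            dv = theta[dev_slices[g]]
            s = np.exp(theta[sd_pos[g]])
            eta = eta + dv[codes[g]]
            lp += -0.5 * np.sum((dv / max(s, 1e-8)) ** 2) - dv.size * np.log(max(s, 1e-8))
            lp += _halfnormal_logprior(theta[sd_pos[g]], sd_scale)
        # Bernoulli log-likelihood via log1p for stability
        ll = -np.sum(np.logaddexp(0.0, -eta) * y + np.logaddexp(0.0, eta) * (1 - y))
        return lp + ll

    n_warmup = n_steps // 3 if n_warmup is None else n_warmup
    n_walkers = max(2 * ndim + 2, 16)
    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.generate_state(2 * n_chains)
    frames = []
    chains_arr = []
    for c in range(n_chains):
        rng = np.random.default_rng(chain_seeds[2 * c])
        init = 0.1 * rng.standard_normal((n_walkers, ndim))
        for g in group_names:
            init[:, sd_pos[g]] = np.log(0.3) + 0.2 * rng.standard_normal(n_walkers)
        chain = _run_ensemble(log_prob, init, n_steps, int(chain_seeds[2 * c + 1] % (2**31)))
        kept = chain[n_warmup:]
        chains_arr.append(kept.reshape(-1, ndim))
        flat = kept.reshape(-1, ndim)
        stride = max(len(flat) // n_keep, 1)
        sel = flat[::stride][:n_keep]
        frame = pd.DataFrame(sel, columns=names)
        for g in group_names:
            frame[f"sd:{g}"] = np.exp(frame.pop(f"log_sd:{g}"))
        frame.insert(0, "draw", np.arange(len(frame)))
        frame.insert(0, "chain", c)
        frames.append(frame)
    draws = pd.concat(frames, ignore_index=True)
    diag_src = {
        n: np.vstack([arr[:, i] for arr in chains_arr]).reshape(n_chains, -1)
        for i, n in enumerate(names)
        if not n.startswith("dev:")
    }
    diagnostics = _make_diagnostics(diag_src, n_chains)
    for cname in X.columns:
        b = draws[f"beta:{cname}"]
        if np.abs(b).mean() > separation_threshold:
            warnings.warn(
                f"coefficient {cname!r} drifts beyond ±{separation_threshold} on the "
                "logit scale; likely complete separation",
                RuntimeWarning,
                stacklevel=2,
            )
    if (diagnostics["rhat"] > rhat_warn).any():
        warnings.warn("possible non-convergence in logistic model", RuntimeWarning,
                      stacklevel=2)
    return PosteriorSamples(draws=draws, diagnostics=diagnostics, seed=seed,
                            attrs={"model": "bernoulli_logit"})
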