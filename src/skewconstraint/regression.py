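"""Skew-normal distributional regression.

Each parameter of the centered skew normal is modeled as a linear function
of covariates:

* the mean:        mu_i    = X_mu  beta_mu
* the SD (log):    sigma_i = exp(X_sigma beta_sigma)
* the shape:       alpha_i = X_alpha beta_alpha (+ random intercepts)

Random intercepts are supported on the shape only — the shape is where
between-individual constraint differences live in this framework — and are
estimated by penalized maximum likelihood: group deviations u_g carry a
normal N(0, tau^2) penalty and (u, log tau) are optimized jointly with the
fixed effects. Intervals are Wald intervals from the observed information
at the optimum.

Setting ``alpha_formula=None`` in :class:`ModelSpec` fixes the shape at
zero, i.e. fits a plain (hetero- or homoscedastic) normal model; this is
the natural null for model comparison.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
import scipy.optimize
import scipy.special
import scipy.stats
from statsmodels.tools import numdiff

from ._exceptions import DataError
from .constraint import ConstraintCurve, constraint_from_params
from .distribution import (
    MAX_SKEWNESS,
    SkewNormalParams,
    alpha_from_skewness,
    log_density,
)
from .formula import DesignInfo, ParsedFormula, build_design, parse_formula

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "FitResult",
    "ComparisonResult",
    "neg_log_likelihood",
    "fit",
    "predict_params",
    "group_constraint_curves",
    "compare_models",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)
_SQRT_2_OVER_PI = math.sqrt(2.0 / math.pi)
_BIG = 1e10  # optimizer-safe stand-in for a non-finite objective
_MIN_LOG_TAU = math.log(1e-4)


@dataclass(frozen=True)
class ModelSpec:
    """Definition of a skew-normal distributional regression.

    ``alpha_formula=None`` requests a normal model (shape fixed at 0).
    Random intercept terms ``(1|g)`` / ``(1|g1/g2)`` are accepted in
    ``alpha_formula`` only.
    """

    response: str
    mu_formula: str = "~1"
    sigma_formula: str = "~1"
    alpha_formula: str | None = "~1"

    def parsed(self) -> tuple[ParsedFormula, ParsedFormula, ParsedFormula | None]:
        mu = parse_formula(self.mu_formula)
        sigma = parse_formula(self.sigma_formula)
        alpha = parse_formula(self.alpha_formula) if self.alpha_formula is not None else None
        for f, where in ((mu, "mu"), (sigma, "sigma")):
            if f.groups:
                raise DataError(
                    f"random intercepts are only supported on alpha, found one in "
                    f"the {where} formula {f.text!r}"
                )
        return mu, sigma, alpha


@dataclass
class _Designs:
    """Realized design matrices for one data frame under one spec."""

    y: np.ndarray
    mu: DesignInfo
    sigma: DesignInfo
    alpha: DesignInfo | None

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def n_fixed(self) -> int:
        p = self.mu.n_fixed + self.sigma.n_fixed
        if self.alpha is not None:
            p += self.alpha.n_fixed
        return p

    @property
    def group_sizes(self) -> list[int]:
        if self.alpha is None:
            return []
        return [len(self.alpha.group_levels[g]) for g in self.alpha.group_names]

    @property
    def n_params(self) -> int:
        # fixed effects + per grouping factor: deviations + log tau
        return self.n_fixed + sum(m + 1 for m in self.group_sizes)


def _make_designs(
    data: pd.DataFrame,
    spec: ModelSpec,
    *,
    template: "FitResult | None" = None,
    allow_new_group_levels: bool = False,
) -> _Designs:
    if spec.response not in data.columns:
        raise DataError(f"response column {spec.response!r} not in data")
    y = data[spec.response].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise DataError(f"non-finite values in response {spec.response!r}")
    mu_f, sigma_f, alpha_f = spec.parsed()
    lv = template.levels if template is not None else None
    glv = template.group_level_index if template is not None else None
    mu_d = build_design(data, mu_f, levels=lv)
    sigma_d = build_design(data, sigma_f, levels=lv)
    alpha_d = (
        build_design(
            data,
            alpha_f,
            levels=lv,
            group_levels=glv,
            allow_new_group_levels=allow_new_group_levels,
        )
        if alpha_f is not None
        else None
    )
    if template is None:  # rank check only applies to estimation designs
        for d, where in ((mu_d, "mu"), (sigma_d, "sigma"), (alpha_d, "alpha")):
            if d is None:
                continue
            if d.X.shape[1] > 1:
                rank = np.linalg.matrix_rank(d.X)
                if rank < d.X.shape[1]:
                    raise DataError(
                        f"singular {where} design: columns {d.columns} are collinear"
                    )
    return _Designs(y=y, mu=mu_d, sigma=sigma_d, alpha=alpha_d)


def _unpack(theta: np.ndarray, d: _Designs):
    p_mu = d.mu.n_fixed
    p_s = d.sigma.n_fixed
    p_a = d.alpha.n_fixed if d.alpha is not None else 0
    b_mu = theta[:p_mu]
    b_s = theta[p_mu : p_mu + p_s]
    b_a = theta[p_mu + p_s : p_mu + p_s + p_a]
    pos = p_mu + p_s + p_a
    us, log_taus = [], []
    for m in d.group_sizes:
        us.append(theta[pos : pos + m])
        log_taus.append(theta[pos + m])
        pos += m + 1
    return b_mu, b_s, b_a, us, log_taus


def _linear_predictors(theta: np.ndarray, d: _Designs):
    b_mu, b_s, b_a, us, _ = _unpack(theta, d)
    mu = d.mu.X @ b_mu
    log_sigma = d.sigma.X @ b_s
    if d.alpha is not None:
        alpha = d.alpha.X @ b_a
        for u, codes in zip(us, d.alpha.group_codes):
            valid = codes >= 0
            alpha = alpha + np.where(valid, u[np.clip(codes, 0, None)], 0.0)
    else:
        alpha = np.zeros_like(mu)
    return mu, log_sigma, alpha


def _centered_loglik_terms(y, mu, log_sigma, alpha):
    """Vectorized log density of centered skew normal per observation."""
    from scipy.special import log_ndtr

    sigma = np.exp(log_sigma)
    delta = alpha / np.hypot(1.0, alpha)
    mz = delta * _SQRT_2_OVER_PI
    b = np.sqrt(1.0 - mz * mz)
    omega = sigma / b
    xi = mu - omega * mz
    z = (y - xi) / omega
    return math.log(2.0) - np.log(omega) - _LOG_SQRT_2PI - 0.5 * z * z + log_ndtr(alpha * z)


def _data_loglik(theta: np.ndarray, d: _Designs) -> float:
    mu, log_sigma, alpha = _linear_predictors(theta, d)
    terms = _centered_loglik_terms(d.y, mu, log_sigma, alpha)
    return float(np.sum(terms))


def _loglik_gradient_terms(y, mu, log_sigma, alpha):
    """Per-observation d(loglik)/d(mu_i, log_sigma_i, alpha_i).

    The mu and log-sigma derivatives are analytic; the alpha derivative is
    a vectorized central difference (alpha enters the centered form through
    delta, omega and xi simultaneously, and one numeric column keeps the
    cost at a handful of vectorized likelihood sweeps).
    """
    sigma = np.exp(log_sigma)
    delta = alpha / np.hypot(1.0, alpha)
    mz = delta * _SQRT_2_OVER_PI
    b = np.sqrt(1.0 - mz * mz)
    omega = sigma / b
    xi = mu - omega * mz
    z = (y - xi) / omega
    az = alpha * z
    # phi(az)/Phi(az), stable in the deep tail
    r = np.exp(
        -0.5 * az * az - _LOG_SQRT_2PI - scipy.special.log_ndtr(az)
    )
    dll_dz = -z + alpha * r
    d_mu = -dll_dz / omega  # dz/dmu = -1/omega
    d_ls = -1.0 + dll_dz * (mz - z)
    h = 1e-5 * (1.0 + np.abs(alpha))
    lp = _centered_loglik_terms(y, mu, log_sigma, alpha + h)
    lm = _centered_loglik_terms(y, mu, log_sigma, alpha - h)
    d_alpha = (lp - lm) / (2.0 * h)
    return d_mu, d_ls, d_alpha


def _penalty(theta: np.ndarray, d: _Designs) -> float:
    """Negative log of the N(0, tau^2) random-effect distribution."""
    _, _, _, us, log_taus = _unpack(theta, d)
    pen = 0.0
    for u, lt in zip(us, log_taus):
        lt = max(lt, _MIN_LOG_TAU)
        tau2 = math.exp(2.0 * lt)
        pen += 0.5 * float(u @ u) / tau2 + u.size * (lt + _LOG_SQRT_2PI)
    return pen


def _objective(theta: np.ndarray, d: _Designs) -> float:
    if not np.all(np.isfinite(theta)):
        return _BIG
    with np.errstate(over="ignore", invalid="ignore"):
        ll = _data_loglik(theta, d)
        pen = _penalty(theta, d)
    val = -ll + pen
    if not np.isfinite(val):
        logger.debug("non-finite objective at theta=%s", theta)
        return _BIG
    return val


def neg_log_likelihood(
    params: np.ndarray, data: pd.DataFrame, spec: ModelSpec
) -> float:
    """Penalized negative log likelihood for a packed parameter vector.

    Packing order: mu fixed effects, log-sigma fixed effects, alpha fixed
    effects, then per grouping factor its deviations followed by log tau.
    """
    d = _make_designs(data, spec)
    params = np.asarray(params, dtype=float)
    if params.size != d.n_params:
        raise DataError(
            f"expected {d.n_params} packed parameters, got {params.size}"
        )
    return _objective(params, d)


@dataclass
class FitResult:
    """Estimates and Wald intervals from one fitted model."""

    spec: ModelSpec
    estimates: dict[str, float]
    intervals: dict[str, tuple[float, float]]
    loglik: float
    n_obs: int
    converged: bool
    level: float = 0.95
    seed: int | None = None
    param_names: list[str] = field(default_factory=list)
    theta: np.ndarray = field(default_factory=lambda: np.empty(0))
    levels: dict[str, list[str]] = field(default_factory=dict)
    group_level_index: dict[str, list[str]] = field(default_factory=dict)
    n_fixed: int = 0

    def __getitem__(self, name: str) -> float:
        return self.estimates[name]


def _param_names(d: _Designs) -> list[str]:
    names = []
    for c in d.mu.columns:
        names.append("intercept" if c == "intercept" else c)
    for c in d.sigma.columns:
        names.append("sigma_intercept" if c == "intercept" else f"sigma_{c}")
    if d.alpha is not None:
        for c in d.alpha.columns:
            names.append("alpha_intercept" if c == "intercept" else f"alpha_{c}")
        for gname, m in zip(d.alpha.group_names, d.group_sizes):
            for lev in d.alpha.group_levels[gname]:
                names.append(f"u_alpha[{gname}:{lev}]")
            names.append(f"log_tau_{gname}")
    return names


def _cell_skew_start(d: _Designs) -> np.ndarray:
    """Start values for the alpha coefficients from residual skewness.

    When the alpha design has few distinct rows (factor-style designs),
    each cell's residual skewness is inverted to a shape value and the
    coefficients solved by least squares; otherwise the pooled skewness
    seeds the intercept alone. Skewness is clipped inside the attainable
    skew-normal range before inversion.
    """
    assert d.alpha is not None
    resid = d.y - d.y.mean()
    Xa = d.alpha.X
    start = np.zeros(Xa.shape[1])
    clip = 0.995 * MAX_SKEWNESS

    uniq, inv = np.unique(Xa, axis=0, return_inverse=True)
    if uniq.shape[0] <= 32 and uniq.shape[0] >= Xa.shape[1]:
        targets = np.empty(uniq.shape[0])
        ok = True
        for j in range(uniq.shape[0]):
            cell = resid[inv == j]
            if cell.size < 8 or cell.std() == 0:
                ok = False
                break
            g = scipy.stats.skew(cell - cell.mean(), bias=True)
            targets[j] = alpha_from_skewness(float(np.clip(g, -clip, clip)))
        if ok:
            sol, *_ = np.linalg.lstsq(uniq, targets, rcond=None)
            return sol
    g = scipy.stats.skew(resid, bias=True) if resid.std() > 0 else 0.0
    start[0] = alpha_from_skewness(float(np.clip(g, -clip, clip)))
    return start


def _start_values(d: _Designs) -> np.ndarray:
    theta = np.zeros(d.n_params)
    p_mu, p_s = d.mu.n_fixed, d.sigma.n_fixed
    b_mu, *_ = np.linalg.lstsq(d.mu.X, d.y, rcond=None)
    theta[:p_mu] = b_mu
    resid_sd = float(np.std(d.y - d.mu.X @ b_mu))
    theta[p_mu] = math.log(max(resid_sd, 1e-8))  # log-sigma intercept
    if d.alpha is not None:
        p_a = d.alpha.n_fixed
        theta[p_mu + p_s : p_mu + p_s + p_a] = _cell_skew_start(d)
        pos = p_mu + p_s + p_a
        for m in d.group_sizes:
            theta[pos + m] = math.log(0.5)  # log tau start
            pos += m + 1
    return theta


# --- inner problem: fixed effects + group deviations at fixed tau ---------
#
# Jointly maximizing over (u, log tau) is degenerate (u -> 0, tau -> 0 sends
# the penalized objective to -inf), so the variance parameters are updated
# by an EM-style step instead: the inner optimization solves for the fixed
# effects and the group deviations at fixed tau, and tau^2 is then set to
# the mean of (u_g^2 + conditional variance of u_g), the conditional
# variance coming from the observed curvature of the likelihood in u_g.


def _split_inner(tb: np.ndarray, d: _Designs):
    us = []
    pos = d.n_fixed
    for m in d.group_sizes:
        us.append(tb[pos : pos + m])
        pos += m
    return tb[: d.n_fixed], us


def _inner_objective(tb: np.ndarray, d: _Designs, taus: list[float]) -> float:
    if not np.all(np.isfinite(tb)):
        return _BIG
    theta = _inner_to_full(tb, d, taus)
    with np.errstate(over="ignore", invalid="ignore"):
        ll = _data_loglik(theta, d)
    _, us = _split_inner(tb, d)
    pen = sum(0.5 * float(u @ u) / t**2 for u, t in zip(us, taus))
    val = -ll + pen
    return val if np.isfinite(val) else _BIG


def _inner_grad(tb: np.ndarray, d: _Designs, taus: list[float]) -> np.ndarray:
    theta = _inner_to_full(tb, d, taus)
    with np.errstate(over="ignore", invalid="ignore"):
        mu, log_sigma, alpha = _linear_predictors(theta, d)
        d_mu, d_ls, d_alpha = _loglik_gradient_terms(d.y, mu, log_sigma, alpha)
    if not (
        np.all(np.isfinite(d_mu))
        and np.all(np.isfinite(d_ls))
        and np.all(np.isfinite(d_alpha))
    ):
        # fall back to a zero gradient; the objective guard handles this region
        return np.zeros_like(tb)
    g = np.empty_like(tb)
    p_mu, p_s = d.mu.n_fixed, d.sigma.n_fixed
    g[:p_mu] = -(d.mu.X.T @ d_mu)
    g[p_mu : p_mu + p_s] = -(d.sigma.X.T @ d_ls)
    pos = p_mu + p_s
    if d.alpha is not None:
        p_a = d.alpha.n_fixed
        g[pos : pos + p_a] = -(d.alpha.X.T @ d_alpha)
        pos += p_a
        _, us = _split_inner(tb, d)
        for u, tau, codes, m in zip(us, taus, d.alpha.group_codes, d.group_sizes):
            gu = -np.bincount(
                np.clip(codes, 0, None), weights=d_alpha, minlength=m
            )
            g[pos : pos + m] = gu + u / tau**2
            pos += m
    return g


def _inner_to_full(tb: np.ndarray, d: _Designs, taus: list[float]) -> np.ndarray:
    """Insert the (fixed) log-tau entries to form the packed vector."""
    theta = np.empty(d.n_params)
    theta[: d.n_fixed] = tb[: d.n_fixed]
    pos_t, pos_b = d.n_fixed, d.n_fixed
    for m, tau in zip(d.group_sizes, taus):
        theta[pos_t : pos_t + m] = tb[pos_b : pos_b + m]
        theta[pos_t + m] = math.log(tau)
        pos_t += m + 1
        pos_b += m
    return theta


def _minimize_inner(tb0: np.ndarray, d: _Designs, taus: list[float]):
    return scipy.optimize.minimize(
        _inner_objective,
        tb0,
        args=(d, taus),
        jac=_inner_grad,
        method="L-BFGS-B",
        options={"maxiter": 2000, "maxfun": 20000},
    )


def _profile_objective(
    v: float, j: int, tb_hat: np.ndarray, d: _Designs, taus: list[float]
) -> float:
    """Minimized inner objective with parameter j held fixed at v."""
    free0 = np.delete(tb_hat, j)

    def obj(tf):
        return _inner_objective(np.insert(tf, j, v), d, taus)

    def grad(tf):
        return np.delete(_inner_grad(np.insert(tf, j, v), d, taus), j)

    res = scipy.optimize.minimize(
        obj, free0, jac=grad, method="L-BFGS-B", options={"maxiter": 500}
    )
    return float(res.fun)


def _profile_bound(
    j: int,
    tb_hat: np.ndarray,
    d: _Designs,
    taus: list[float],
    fmin: float,
    level: float,
    direction: int,
    step0: float,
) -> float:
    """One endpoint of a profile-likelihood interval for parameter j.

    Walks outward (doubling steps) until the profile deviance exceeds the
    chi-square(1) cutoff, then solves for the crossing by bisection. If
    the likelihood stays flat out to a wide cap (possible for the shape in
    near-boundary fits), the cap is returned.
    """
    target = fmin + 0.5 * scipy.stats.chi2.ppf(level, 1)
    est = tb_hat[j]
    step = max(step0, 0.25)
    prev = est
    for k in range(12):
        v = est + direction * step * 2.0**k
        if _profile_objective(v, j, tb_hat, d, taus) > target:
            lo_v, hi_v = (prev, v) if direction > 0 else (v, prev)
            f = lambda x: _profile_objective(x, j, tb_hat, d, taus) - target
            try:
                return float(
                    scipy.optimize.brentq(
                        f, lo_v, hi_v, xtol=1e-3 * (1.0 + abs(est)), maxiter=60
                    )
                )
            except ValueError:  # numerically flat; return the bracket edge
                return float(v)
        prev = v
    return float(prev)


def _conditional_variances(tb: np.ndarray, d: _Designs, taus: list[float]):
    """Var(u_g | data) ~ 1/(I_g + 1/tau^2) from the curvature in u_g."""
    theta = _inner_to_full(tb, d, taus)
    mu, log_sigma, alpha = _linear_predictors(theta, d)
    h = 1e-3
    l0 = _centered_loglik_terms(d.y, mu, log_sigma, alpha)
    lp = _centered_loglik_terms(d.y, mu, log_sigma, alpha + h)
    lm = _centered_loglik_terms(d.y, mu, log_sigma, alpha - h)
    d2 = (lp - 2.0 * l0 + lm) / h**2  # d2 loglik / d alpha_i^2, per row
    out = []
    assert d.alpha is not None
    for tau, codes, m in zip(taus, d.alpha.group_codes, d.group_sizes):
        info = -np.bincount(np.clip(codes, 0, None), weights=d2, minlength=m)
        info = np.clip(info, 1e-8, None)
        out.append(1.0 / (info + 1.0 / tau**2))
    return out


def fit(
    data: pd.DataFrame,
    spec: ModelSpec,
    level: float = 0.95,
    seed: int = 0,
    n_starts: int = 3,
    compute_intervals: bool = True,
) -> FitResult:
    """Fit the distributional regression by (penalized) maximum likelihood.

    Method-of-moments starting values seed a quasi-Newton optimizer;
    ``n_starts - 1`` jittered restarts (plus a sign-flipped-shape start,
    guarding the known near-symmetric bimodality of skew-normal
    likelihoods) are tried and the best optimum kept. ``seed`` only
    controls the jitter, so the default fit is deterministic.

    Intervals are Wald intervals from the observed information for the
    mean and log-scale blocks, and profile-likelihood intervals for the
    shape coefficients: the observed information is singular at shape 0
    (the shape score is collinear with the location score there), which
    makes Wald intervals on the shape unreliable precisely where the
    no-constraint hypothesis lives. ``compute_intervals=False`` skips all
    interval computation (used internally for cross-validation refits).
    """
    if not (0 < level < 1):
        raise DataError(f"level must be in (0, 1), got {level!r}")
    d = _make_designs(data, spec)
    if d.n_obs < 10 * d.n_fixed:
        warnings.warn(
            f"only {d.n_obs} observations for {d.n_fixed} fixed parameters; "
            "estimates may be unstable",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    theta0 = _start_values(d)
    n_groups = len(d.group_sizes)
    taus = [0.5] * n_groups
    tb0 = np.concatenate(
        [theta0[: d.n_fixed]]
        + [np.zeros(m) for m in d.group_sizes]
    )

    starts = [tb0]
    if d.alpha is not None and np.any(tb0 != 0):
        flipped = tb0.copy()
        p0 = d.mu.n_fixed + d.sigma.n_fixed
        p1 = p0 + d.alpha.n_fixed
        flipped[p0:p1] = -flipped[p0:p1]
        starts.append(flipped)
    for _ in range(max(0, n_starts - len(starts))):
        jitter = rng.normal(scale=0.3 * (1.0 + np.abs(tb0)))
        starts.append(tb0 + jitter)

    best = None
    for s in starts:
        res = _minimize_inner(s, d, taus)
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None

    # EM-style updates of the random-effect SDs at the current optimum
    if n_groups:
        for _ in range(25):
            tb = np.asarray(best.x, dtype=float)
            _, us = _split_inner(tb, d)
            cond_vars = _conditional_variances(tb, d, taus)
            new_taus = [
                max(math.sqrt(float(np.mean(u**2 + v))), 1e-4)
                for u, v in zip(us, cond_vars)
            ]
            shift = max(
                abs(math.log(a) - math.log(b)) for a, b in zip(new_taus, taus)
            )
            taus = new_taus
            best = _minimize_inner(tb, d, taus)
            if shift < 1e-3:
                break

    tb = np.asarray(best.x, dtype=float)
    theta = _inner_to_full(tb, d, taus)
    converged = bool(best.success) and best.fun < _BIG / 2

    names = _param_names(d)
    estimates = dict(zip(names, theta.tolist()))
    loglik = _data_loglik(theta, d) if best.fun < _BIG / 2 else float("nan")

    intervals: dict[str, tuple[float, float]] = {}
    if converged and compute_intervals:
        zcrit = scipy.stats.norm.ppf(0.5 + level / 2.0)
        with np.errstate(all="ignore"):
            H = numdiff.approx_hess2(tb, _inner_objective, args=(d, taus))
            cov = np.linalg.pinv(H)
            var = np.clip(np.diag(cov), 0.0, None)
        se_inner = np.sqrt(var)
        # map inner (beta, u) SEs onto the packed-name order; log-tau
        # entries get degenerate intervals (EM point updates, no Wald SE)
        se = np.zeros(d.n_params)
        se[: d.n_fixed] = se_inner[: d.n_fixed]
        pos_t, pos_b = d.n_fixed, d.n_fixed
        for m in d.group_sizes:
            se[pos_t : pos_t + m] = se_inner[pos_b : pos_b + m]
            se[pos_t + m] = 0.0
            pos_t += m + 1
            pos_b += m
        for name, est, s_ in zip(names, theta, se):
            if np.isfinite(s_) and s_ > 0:
                intervals[name] = (float(est - zcrit * s_), float(est + zcrit * s_))
            else:
                intervals[name] = (float(est), float(est))
        if d.alpha is not None:
            p0 = d.mu.n_fixed + d.sigma.n_fixed
            for ja in range(d.alpha.n_fixed):
                j = p0 + ja
                step0 = se_inner[j] if np.isfinite(se_inner[j]) else 0.25
                lo = _profile_bound(j, tb, d, taus, best.fun, level, -1, step0)
                hi = _profile_bound(j, tb, d, taus, best.fun, level, +1, step0)
                intervals[names[j]] = (
                    min(lo, float(tb[j])),
                    max(hi, float(tb[j])),
                )
    elif not converged:
        logger.warning("optimizer did not converge; intervals suppressed")

    if d.alpha is not None:
        for gname in d.alpha.group_names:
            lt = estimates[f"log_tau_{gname}"]
            estimates[f"tau_{gname}"] = math.exp(max(lt, _MIN_LOG_TAU))

    all_levels: dict[str, list[str]] = {}
    for dd in (d.mu, d.sigma, d.alpha):
        if dd is not None:
            all_levels.update(dd.levels)
    return FitResult(
        spec=spec,
        estimates=estimates,
        intervals=intervals,
        loglik=float(loglik),
        n_obs=d.n_obs,
        converged=converged,
        level=level,
        seed=seed,
        param_names=names,
        theta=theta,
        levels=all_levels,
        group_level_index=dict(d.alpha.group_levels) if d.alpha is not None else {},
        n_fixed=d.n_fixed,
    )


def predict_params(
    fit_result: FitResult,
    newdata: pd.DataFrame,
    include_groups: bool = False,
) -> list[SkewNormalParams]:
    """Per-row centered (mean, SD, shape) implied by the fit for new data.

    With ``include_groups=False`` the population-level shape is used
    (group deviations set to zero) and unseen group levels are permitted;
    with ``include_groups=True`` group deviations are added and an unseen
    level is an error.
    """
    d = _make_designs(
        _with_dummy_response(newdata, fit_result.spec),
        fit_result.spec,
        template=fit_result,
        allow_new_group_levels=not include_groups,
    )
    theta = fit_result.theta.copy()
    if not include_groups and d.alpha is not None and d.group_sizes:
        b_mu, b_s, b_a, us, lts = _unpack(theta, d)
        for u in us:
            u[:] = 0.0
    mu, log_sigma, alpha = _linear_predictors(theta, d)
    return [
        SkewNormalParams(float(m), float(math.exp(ls)), float(a), "centered")
        for m, ls, a in zip(mu, log_sigma, alpha)
    ]


def _with_dummy_response(newdata: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    if spec.response in newdata.columns:
        return newdata
    out = newdata.copy()
    out[spec.response] = 0.0
    return out


def group_constraint_curves(
    fit_result: FitResult,
    newdata: pd.DataFrame,
    include_groups: bool = True,
    grid_points: int = 512,
    grid_halfwidth_sds: float = 4.0,
) -> list[ConstraintCurve | None]:
    """One constraint curve per row of ``newdata``.

    Rows whose predicted shape is exactly zero have no defined constraint
    curve; those entries are ``None`` and a warning is emitted, while the
    remaining rows are still returned.
    """
    params = predict_params(fit_result, newdata, include_groups=include_groups)
    curves: list[ConstraintCurve | None] = []
    for i, p in enumerate(params):
        if p.shape == 0.0:
            warnings.warn(
                f"row {i}: predicted shape is 0, constraint curve undefined",
                stacklevel=2,
            )
            curves.append(None)
            continue
        curve = constraint_from_params(
            p, grid_points=grid_points, grid_halfwidth_sds=grid_halfwidth_sds
        )
        curve.label = {c: newdata.iloc[i][c] for c in newdata.columns}
        curves.append(curve)
    return curves


@dataclass(frozen=True)
class ComparisonResult:
    """Out-of-sample comparison of two fitted models (first minus second)."""

    elpd_diff: float
    se_diff: float
    method: str


def compare_models(
    fit1: FitResult,
    fit2: FitResult,
    data: pd.DataFrame,
    method: str = "kfold_cv",
    k: int = 10,
    seed: int = 0,
) -> ComparisonResult:
    """Compare two model specs on the same data.

    ``kfold_cv`` (default) refits both specs on k-1 folds and sums
    held-out log predictive density; the difference (first model minus
    second) estimates the elpd difference, with a fold-wise standard
    error. ``information_criterion`` uses the AIC-style bias correction
    loglik - n_params instead (se reported as 0).
    """
    if fit1.spec.response != fit2.spec.response:
        raise DataError("models must share the same response column")
    if fit1.n_obs != len(data) or fit2.n_obs != len(data):
        raise DataError("both fits must have been obtained on the supplied data")
    if method == "information_criterion":
        d1 = _make_designs(data, fit1.spec)
        d2 = _make_designs(data, fit2.spec)
        e1 = fit1.loglik - d1.n_params
        e2 = fit2.loglik - d2.n_params
        return ComparisonResult(float(e1 - e2), 0.0, method)
    if method != "kfold_cv":
        raise DataError(f"unknown comparison method {method!r}")
    if k < 2:
        raise DataError(f"k must be >= 2, got {k}")

    rng = np.random.default_rng(seed)
    n = len(data)
    idx = rng.permutation(n)
    folds = np.array_split(idx, k)
    fold_diffs = []
    for test_idx in folds:
        mask = np.zeros(n, dtype=bool)
        mask[test_idx] = True
        train = data.loc[~mask].reset_index(drop=True)
        test = data.loc[mask].reset_index(drop=True)
        diffs = []
        for spec in (fit1.spec, fit2.spec):
            f = fit(train, spec, seed=seed, n_starts=2, compute_intervals=False)
            params = predict_params(f, test, include_groups=False)
            y = test[spec.response].to_numpy(dtype=float)
            lp = sum(
                float(log_density(yi, pi)) for yi, pi in zip(y, params)
            )
            diffs.append(lp)
        fold_diffs.append(diffs[0] - diffs[1])
    fold_diffs = np.asarray(fold_diffs)
    elpd_diff = float(fold_diffs.sum())
    se = float(np.sqrt(k * fold_diffs.var(ddof=1))) if k > 1 else 0.0
    return ComparisonResult(elpd_diff, se, "kfold_cv")
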