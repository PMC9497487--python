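"""Estimation: 2SLS initialization, simultaneous LIML fit, and (K, J) selection.

The limited-information maximum likelihood estimator maximizes the mean
bivariate-normal log-likelihood over all coefficients, threshold locations and
error parameters simultaneously.  There is no closed form, so a quasi-Newton
(BFGS) ascent with the analytic score is used, started from a two-stage least
squares fit with thresholds placed on interior quantiles.  Constrained
parameters are optimized on an unconstrained scale (rho through tanh, variances
through log); thresholds are optimized on the raw scale, where the objective is
continuous and piecewise smooth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .likelihood import loglik, loglik_and_grad_free
from .model import Dataset, ParamSpace, Theta, ThresholdCounts, build_stage_design

__all__ = [
    "FitOptions",
    "FitResult",
    "tsls_init",
    "grid_search_init",
    "fit_liml",
    "select_thresholds",
    "InitializationError",
]


class InitializationError(ValueError):
    """Raised when the 2SLS initializer cannot produce a full-rank design."""


@dataclass
class FitOptions:
    """Tuning knobs for the LIML optimizer.

    ``threshold_bounds`` are the quantile levels that bracket admissible
    threshold locations (interior placement avoids boundary effects where a
    hinge column is almost all zeros).
    """

    max_iter: int = 500
    grad_tol: float = 1e-8
    optimizer: str = "BFGS"
    seed: int | None = None
    restarts: int = 0
    threshold_bounds: tuple[float, float] = (0.05, 0.95)

    def __post_init__(self):
        lo, hi = self.threshold_bounds
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("threshold_bounds must be ordered and inside (0, 1)")
        if self.grad_tol <= 0:
            raise ValueError("grad_tol must be positive")
        if self.max_iter <= 0:
            raise ValueError("max_iter must be positive")


@dataclass
class FitResult:
    """Outcome of a LIML fit."""

    theta_hat: Theta
    space: ParamSpace
    loglik_at_opt: float  # mean per-observation l_n at the optimum
    converged: bool
    n_iter: int
    init: Theta
    loglik_at_init: float
    first_stage_F: float
    grad_norm: float
    n_obs: int
    message: str = ""

    @property
    def n_params(self) -> int:
        return self.space.size

    @property
    def model_loglik(self) -> float:
        """Total log-likelihood n * l_n."""
        return self.n_obs * self.loglik_at_opt

    def aic(self) -> float:
        return -2.0 * self.model_loglik + 2.0 * self.n_params

    def bic(self) -> float:
        return -2.0 * self.model_loglik + self.n_params * np.log(self.n_obs)


def _quantile_thresholds(sample: np.ndarray, m: int, bounds: tuple[float, float]) -> np.ndarray:
    """m points at quantile levels lo + i*(hi-lo)/(m+1), i=1..m (m=1 -> midpoint)."""
    if m == 0:
        return np.empty(0)
    lo, hi = bounds
    levels = lo + (np.arange(1, m + 1) / (m + 1)) * (hi - lo)
    return np.quantile(sample, levels)


def _ols(design: np.ndarray, response: np.ndarray) -> np.ndarray:
    coef, _, rank, _ = np.linalg.lstsq(design, response, rcond=None)
    if rank < design.shape[1]:
        raise InitializationError(
            "rank-deficient stage design (a threshold may lie outside the data range)"
        )
    return coef


def tsls_init(
    data: Dataset,
    counts: ThresholdCounts,
    bounds: tuple[float, float] = (0.05, 0.95),
    c: np.ndarray | None = None,
    t: np.ndarray | None = None,
) -> Theta:
    """Two-stage least squares starting values.

    Stage 1 regresses x on [1, phi(z, c), z] with c evenly spaced (in quantile
    space) between the 5% and 95% sample quantiles of z; stage 2 regresses y on
    [1, phi(xhat, t), xhat] with t placed the same way on the fitted xhat.
    Error parameters come from the two stages' residuals, with u formed from
    the observed x (the structural residual).  Explicit ``c``/``t`` override
    the quantile placement (e.g. thresholds known a priori).
    """
    c = _quantile_thresholds(data.z, counts.K, bounds) if c is None else np.asarray(c, dtype=float)
    d1 = build_stage_design(data.z, c)
    alpha = _ols(d1, data.x)
    xhat = d1 @ alpha

    t = _quantile_thresholds(xhat, counts.J, bounds) if t is None else np.asarray(t, dtype=float)
    d2_hat = build_stage_design(xhat, t)
    beta = _ols(d2_hat, data.y)

    v = data.x - xhat
    u = data.y - build_stage_design(data.x, t) @ beta
    sigma_v = float(np.std(v))
    sigma_u = float(np.std(u))
    if sigma_u <= 0 or sigma_v <= 0:
        raise InitializationError("degenerate residuals in 2SLS initialization")
    rho = float(np.clip(np.corrcoef(u, v)[0, 1], -0.99, 0.99))
    if not np.isfinite(rho):
        rho = 0.0
    return Theta(alpha=alpha, beta=beta, c=c, t=t, rho=rho, sigma_u=sigma_u, sigma_v=sigma_v)


def grid_search_init(
    data: Dataset,
    counts: ThresholdCounts,
    bounds: tuple[float, float] = (0.05, 0.95),
    grid_points: int = 19,
) -> Theta:
    """2SLS initializer with thresholds chosen by grid search (K, J <= 1).

    Scans a quantile grid for (c, t), fitting both stages at each candidate and
    keeping the pair minimizing the stage-2 sum of squared errors of y.
    """
    if counts.K > 1 or counts.J > 1:
        raise ValueError("grid search initializer supports K, J <= 1")
    lo, hi = bounds
    levels = np.linspace(lo, hi, grid_points)
    c_grid = [np.empty(0)] if counts.K == 0 else [np.array([q]) for q in np.quantile(data.z, levels)]

    best = None
    best_sse = np.inf
    for c in c_grid:
        d1 = build_stage_design(data.z, c)
        alpha = _ols(d1, data.x)
        xhat = d1 @ alpha
        t_grid = [np.empty(0)] if counts.J == 0 else [np.array([q]) for q in np.quantile(xhat, levels)]
        for t in t_grid:
            d2 = build_stage_design(xhat, t)
            beta = _ols(d2, data.y)
            sse = float(np.sum((data.y - d2 @ beta) ** 2))
            if sse < best_sse:
                best_sse = sse
                best = (c, t, alpha, beta, xhat)
    c, t, alpha, beta, xhat = best
    v = data.x - xhat
    u = data.y - build_stage_design(data.x, t) @ beta
    rho = float(np.clip(np.corrcoef(u, v)[0, 1], -0.99, 0.99)) if u.std() > 0 and v.std() > 0 else 0.0
    return Theta(
        alpha=alpha, beta=beta, c=c, t=t, rho=rho,
        sigma_u=float(np.std(u)) or 1.0, sigma_v=float(np.std(v)) or 1.0,
    )


def _profile_candidate(
    vec: np.ndarray,
    space: ParamSpace,
    data: Dataset,
    bounds: tuple[float, float],
    n_grid: int = 25,
):
    """Best threshold relocation found by a coordinate profile scan.

    The likelihood is multimodal in each threshold (every data point is a
    kink), so a gradient ascent can stall between modes.  For each threshold
    coordinate in turn, candidate locations on a quantile grid are scored by
    the likelihood after refreshing both stages' coefficients and the error
    parameters by least squares conditional on the thresholds — a cheap
    surrogate for the profile likelihood.  Scores are compared against the
    same surrogate evaluated at the current thresholds (absolute likelihoods
    would be unfair: the surrogate ignores the error correlation).  Returns
    the best strictly-improving candidate Theta, or None; the caller verifies
    any proposal with a full ascent.
    """
    from .likelihood import loglik as _loglik

    theta = space.unpack(vec)
    levels = np.linspace(bounds[0], bounds[1], n_grid)

    def rebuild(c, t):
        d1 = build_stage_design(data.z, c)
        alpha = np.linalg.lstsq(d1, data.x, rcond=None)[0]
        d2 = build_stage_design(data.x, t)
        beta = np.linalg.lstsq(d2, data.y, rcond=None)[0]
        v = data.x - d1 @ alpha
        u = data.y - d2 @ beta
        su, sv = float(np.std(u)), float(np.std(v))
        if su <= 0 or sv <= 0:
            return None
        rho = float(np.clip(np.corrcoef(u, v)[0, 1], -0.99, 0.99))
        if space.common_sigma:
            su = sv = float(np.sqrt(0.5 * (su**2 + sv**2)))
        return Theta(alpha=alpha, beta=beta, c=c, t=t, rho=rho, sigma_u=su, sigma_v=sv)

    baseline = rebuild(theta.c, theta.t)
    if baseline is None:  # pragma: no cover
        return None
    best_ll, best_theta = _loglik(baseline, data) + 1e-8, None
    for which, sample, thr in (("c", data.z, theta.c), ("t", data.x, theta.t)):
        grid = np.quantile(sample, levels)
        for k in range(thr.size):
            for cand in grid:
                new_thr = thr.copy()
                new_thr[k] = cand
                if new_thr.size > 1 and not np.all(np.diff(np.sort(new_thr)) > 1e-8):
                    continue
                new_thr = np.sort(new_thr)
                c, t = (new_thr, theta.t) if which == "c" else (theta.c, new_thr)
                try:
                    cand_theta = rebuild(c, t)
                except np.linalg.LinAlgError:  # pragma: no cover
                    continue
                if cand_theta is None:
                    continue
                ll = _loglik(cand_theta, data)
                if ll > best_ll + 1e-8:
                    best_ll, best_theta = ll, cand_theta
    return best_theta


def _first_stage_F(data: Dataset, c: np.ndarray) -> float:
    """Overall F of the stage-1 regression (weak-instrument diagnostic)."""
    d1 = build_stage_design(data.z, np.sort(c))
    coef, _, rank, _ = np.linalg.lstsq(d1, data.x, rcond=None)
    resid = data.x - d1 @ coef
    rss = float(resid @ resid)
    tss = float(np.sum((data.x - data.x.mean()) ** 2))
    p = d1.shape[1]
    dof = data.n - p
    if dof <= 0 or rss <= 0:
        return np.inf
    return ((tss - rss) / (p - 1)) / (rss / dof)


def _canonicalize(vec: np.ndarray, space: ParamSpace, data: Dataset, bounds) -> np.ndarray:
    """Sort threshold/coefficient pairs ascending and project escaped thresholds.

    The model is invariant to permuting (alpha_k, c_k) pairs, so sorting fixes
    the label-switching ambiguity.  Thresholds outside the data's quantile
    bounds are projected back (with a warning): beyond them a hinge column is
    numerically unidentified.
    """
    vec = vec.copy()
    K, J = space.counts.K, space.counts.J
    for slc, coef_slc, sample in (
        (space.slice_c, space.slice_alpha, data.z),
        (space.slice_t, space.slice_beta, data.x),
    ):
        m = slc.stop - slc.start
        if m == 0:
            continue
        thr = vec[slc]
        coefs = vec[coef_slc]
        order = np.argsort(thr)
        thr = thr[order]
        hinge = coefs[1:-1][order]  # permute hinge coefficients with their kinks
        qlo, qhi = np.quantile(sample, bounds)
        if np.any(thr < qlo) or np.any(thr > qhi):
            warnings.warn(
                "threshold estimate escaped the interior quantile range; projected back",
                RuntimeWarning,
                stacklevel=2,
            )
            thr = np.clip(thr, qlo, qhi)
        rng = sample.max() - sample.min()
        if m > 1 and np.any(np.diff(thr) < 1e-6 * rng):
            warnings.warn(
                "two threshold estimates nearly coincide; model is close to non-identified",
                RuntimeWarning,
                stacklevel=2,
            )
        vec[slc] = thr
        coefs = coefs.copy()
        coefs[1:-1] = hinge
        vec[coef_slc] = coefs
    del K, J
    return vec


def fit_liml(
    data: Dataset,
    counts: ThresholdCounts,
    options: FitOptions | None = None,
    *,
    common_sigma: bool = False,
    init: Theta | str = "quantile",
) -> FitResult:
    """Maximize the LIML criterion l_n over all parameters simultaneously.

    ``init`` is either a Theta to start from, ``"quantile"`` (2SLS with
    quantile-placed thresholds, the default) or ``"grid"`` (2SLS with
    grid-searched thresholds, K, J <= 1).  With ``common_sigma=True`` a single
    error variance sigma2 = sigma_u^2 = sigma_v^2 is estimated.
    """
    options = options or FitOptions()
    space = ParamSpace(counts, common_sigma=common_sigma)
    if data.n < space.size:
        raise ValueError(f"need at least {space.size} observations, got {data.n}")

    if isinstance(init, Theta):
        theta0 = init
    elif init == "quantile":
        theta0 = tsls_init(data, counts, options.threshold_bounds)
    elif init == "grid":
        theta0 = grid_search_init(data, counts, options.threshold_bounds)
    else:
        raise ValueError(f"unknown init {init!r}")

    if common_sigma:
        pooled = float(np.sqrt(0.5 * (theta0.sigma_u**2 + theta0.sigma_v**2)))
        theta0 = Theta(
            alpha=theta0.alpha, beta=theta0.beta, c=theta0.c, t=theta0.t,
            rho=theta0.rho, sigma_u=pooled, sigma_v=pooled,
        )
    ll_init = loglik(theta0, data)

    def objective(free):
        ll, grad = loglik_and_grad_free(free, data, space)
        return -ll, -grad

    def ascend(free_start):
        """BFGS ascent with kink handling; returns (result, at_kink, iters)."""
        res = minimize(
            objective, free_start, jac=True, method=options.optimizer,
            options={"gtol": options.grad_tol, "maxiter": options.max_iter},
        )
        iters = int(res.nit)
        at_kink = False
        for _ in range(10):
            if res.success:
                break
            # A line-search failure usually means the maximizer sits on a kink
            # of the piecewise-smooth objective, where the gradient cannot
            # vanish (only one-sided derivatives exist).  Restart with a fresh
            # quasi-Newton state; improvements decay geometrically at a kink,
            # and once both the gain and the step are negligible the point is
            # stationary in the subdifferential sense and accepted.
            res2 = minimize(
                objective, res.x, jac=True, method=options.optimizer,
                options={"gtol": options.grad_tol, "maxiter": options.max_iter},
            )
            iters += int(res2.nit)
            stalled = (
                -res2.fun <= -res.fun + 1e-8
                and np.max(np.abs(res2.x - res.x)) < 1e-4
            )
            if -res2.fun >= -res.fun:
                res = res2
            if stalled:
                at_kink = True
                break
        return res, at_kink, iters

    free0 = space.to_free(space.pack(theta0))
    res, at_kink, n_iter = ascend(free0)

    # Escape local modes in the threshold coordinates: a coordinate profile
    # scan proposes relocations; each accepted proposal is polished by a fresh
    # ascent, until no proposal improves the likelihood.
    if space.counts.K + space.counts.J > 0:
        for _ in range(3):
            cand = _profile_candidate(
                space.from_free(res.x), space, data, options.threshold_bounds
            )
            if cand is None:
                break
            res_c, kink_c, it_c = ascend(space.to_free(space.pack(cand)))
            n_iter += it_c
            if -res_c.fun > -res.fun:
                res, at_kink = res_c, kink_c
            else:
                break

    rng_master = np.random.default_rng(options.seed)
    for _ in range(options.restarts):
        jitter = rng_master.normal(scale=0.05, size=free0.size)
        res_r, kink_r, it_r = ascend(free0 + jitter)
        n_iter += it_r
        if -res_r.fun > -res.fun:
            res, at_kink = res_r, kink_r

    vec = _canonicalize(space.from_free(res.x), space, data, options.threshold_bounds)
    theta_hat = space.unpack(vec)
    ll_opt = loglik(theta_hat, data)
    if ll_opt < ll_init - 1e-9:
        # ascent safeguard: never return a point worse than the start
        warnings.warn("optimizer failed to improve on the 2SLS start", RuntimeWarning)
        theta_hat, ll_opt = theta0, ll_init

    grad_norm = float(np.max(np.abs(res.jac)))
    converged = bool(res.success or grad_norm < 1e-4 or at_kink)
    return FitResult(
        theta_hat=theta_hat,
        space=space,
        loglik_at_opt=ll_opt,
        converged=converged,
        n_iter=n_iter,
        init=theta0,
        loglik_at_init=ll_init,
        first_stage_F=_first_stage_F(data, theta_hat.c),
        grad_norm=grad_norm,
        n_obs=data.n,
        message=str(res.message),
    )


def select_thresholds(
    data: Dataset,
    Kmax: int,
    Jmax: int,
    criterion: str = "bic",
    options: FitOptions | None = None,
    *,
    common_sigma: bool = False,
) -> tuple[ThresholdCounts, pd.DataFrame]:
    """Fit every admissible (K, J) with 0 <= J <= min(K, Jmax), K <= Kmax.

    Returns the pair minimizing the requested information criterion together
    with the full criterion table (one row per candidate; failed fits keep a
    row with NaN criteria and are excluded from the argmin).
    """
    criterion = criterion.lower()
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    if Kmax < Jmax or Jmax < 0:
        raise ValueError("need Kmax >= Jmax >= 0")

    rows = []
    for K in range(Kmax + 1):
        for J in range(min(K, Jmax) + 1):
            counts = ThresholdCounts(K=K, J=J)
            try:
                fit = fit_liml(data, counts, options, common_sigma=common_sigma)
                rows.append(
                    {"K": K, "J": J, "loglik": fit.model_loglik, "aic": fit.aic(),
                     "bic": fit.bic(), "converged": fit.converged}
                )
            except (InitializationError, ValueError, np.linalg.LinAlgError) as exc:  # pragma: no cover
                warnings.warn(f"fit failed for (K={K}, J={J}): {exc}", RuntimeWarning)
                rows.append({"K": K, "J": J, "loglik": np.nan, "aic": np.nan,
                             "bic": np.nan, "converged": False})
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=[criterion])
    if valid.empty:
        raise RuntimeError("all candidate fits failed")
    best = valid.loc[valid[criterion].idxmin()]
    return ThresholdCounts(K=int(best["K"]), J=int(best["J"])), table
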