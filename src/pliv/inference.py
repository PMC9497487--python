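"""Variance estimation and Wald summaries for LIML fits.

Two covariance estimates of theta_hat are offered.  Under a correctly
specified model the asymptotic variance is the inverse Fisher information,
estimated by M^{-1}/n with M the average outer product of per-observation
scores.  Under misspecification the robust (sandwich) form V^{-1} M V^{-1}/n
applies, with V the second derivative of the mean log-likelihood.

V needs care because the hinge terms make the empirical objective only
piecewise smooth in the thresholds: differentiating the indicator I(z > c_k)
a second time yields, in the large-sample limit, a density term -f_Z(c_k)
rather than anything computable by naive differencing across a kink.  V is
therefore assembled as (1) central finite differences of the analytic score,
which capture every term that is continuous in the thresholds, plus (2)
kernel-estimated density corrections on the c/c and t/t diagonal entries,
where the Dirac-delta contributions live.  Densities f_Z, f_X are estimated by
a Gaussian KDE with Silverman's rule-of-thumb bandwidth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimation import FitResult
from .likelihood import residuals, score_in_space
from .model import Dataset, ParamSpace, Theta

__all__ = [
    "VarianceEstimate",
    "outer_product_M",
    "kde_density",
    "hessian_V",
    "vcov",
    "summarize",
]


@dataclass
class VarianceEstimate:
    """Covariance of theta_hat with its ingredients.

    ``M`` is the average score outer product, ``V`` the Hessian-type matrix
    (None in model-based mode, where it is not needed), ``cov`` the chosen
    covariance of theta_hat (already scaled by 1/n) and ``se`` its diagonal
    square roots, in the canonical parameter order of ``names``.
    """

    M: np.ndarray
    V: np.ndarray | None
    cov: np.ndarray
    se: np.ndarray
    mode: str
    names: list[str]


def outer_product_M(scores: np.ndarray) -> np.ndarray:
    """Average outer product of per-observation scores, (1/n) sum s_i s_i^T."""
    scores = np.asarray(scores, dtype=float)
    return scores.T @ scores / scores.shape[0]


def _silverman_bandwidth(sample: np.ndarray) -> float:
    # scipy's silverman factor for d=1: (3n/4)^(-1/5), scaled by the sample SD
    n = sample.size
    sd = float(np.std(sample, ddof=1))
    return (3.0 * n / 4.0) ** (-0.2) * sd


def kde_density(sample: np.ndarray, point: float) -> float:
    """Gaussian-kernel density estimate at ``point`` (Silverman bandwidth)."""
    sample = np.asarray(sample, dtype=float).ravel()
    if sample.size < 10:
        raise ValueError("need at least 10 observations for a density estimate")
    if np.std(sample) == 0:
        raise ValueError("degenerate (zero-variance) sample")
    kde = stats.gaussian_kde(sample, bw_method="silverman")
    return float(kde(point)[0])


def _safe_inverse(mat: np.ndarray, label: str) -> np.ndarray:
    cond = np.linalg.cond(mat)
    if not np.isfinite(cond) or cond > 1e12:
        warnings.warn(
            f"{label} is near-singular (condition number {cond:.2e}); "
            "using Moore-Penrose pseudo-inverse",
            RuntimeWarning,
            stacklevel=3,
        )
        return np.linalg.pinv(mat)
    return np.linalg.inv(mat)


def _mean_score_frozen(
    vec: np.ndarray,
    space: ParamSpace,
    data: Dataset,
    mask_c: list[np.ndarray],
    mask_t: list[np.ndarray],
) -> np.ndarray:
    """Mean analytic score with the hinge indicators frozen at the base point.

    Freezing I(z > c_k), I(x > t_j) isolates the part of the objective that is
    smooth in the thresholds: differencing it never steps a data point across
    a kink, which at large n would otherwise contaminate the derivative with
    O(1/(n h)) jump terms.
    """
    alpha = vec[space.slice_alpha]
    beta = vec[space.slice_beta]
    c = vec[space.slice_c]
    t = vec[space.slice_t]
    rho = float(vec[space.idx_rho])
    if space.common_sigma:
        su = sv = float(np.sqrt(vec[space.idx_rho + 1]))
    else:
        su = float(vec[space.idx_rho + 1])
        sv = float(vec[space.idx_rho + 2])

    d1 = np.column_stack(
        [np.ones(data.n)] + [(data.z - ck) * mk for ck, mk in zip(c, mask_c)] + [data.z]
    )
    d2 = np.column_stack(
        [np.ones(data.n)] + [(data.x - tj) * mj for tj, mj in zip(t, mask_t)] + [data.x]
    )
    v = data.x - d1 @ alpha
    u = data.y - d2 @ beta

    a = 1.0 / (1.0 - rho * rho)
    gu = -a * (u / su**2 - rho * v / (su * sv))
    gv = -a * (v / sv**2 - rho * u / (su * sv))
    s_alpha = -gv[:, None] * d1
    s_beta = -gu[:, None] * d2
    s_c = np.column_stack([gv * alpha[k + 1] * mask_c[k] for k in range(len(c))]) if len(c) else np.empty((data.n, 0))
    s_t = np.column_stack([gu * beta[j + 1] * mask_t[j] for j in range(len(t))]) if len(t) else np.empty((data.n, 0))
    q = (u / su) ** 2 - 2.0 * rho * (u / su) * (v / sv) + (v / sv) ** 2
    s_rho = rho * a - rho * a * a * q + a * u * v / (su * sv)
    s_su = -1.0 / su + a * (u**2 / su**3 - rho * u * v / (su**2 * sv))
    s_sv = -1.0 / sv + a * (v**2 / sv**3 - rho * u * v / (sv**2 * su))
    smat = np.column_stack([s_alpha, s_beta, s_c, s_t, s_rho, s_su, s_sv])
    if space.common_sigma:
        s_sigma2 = (smat[:, -2] + smat[:, -1]) / (2.0 * su)
        smat = np.column_stack([smat[:, :-2], s_sigma2])
    return smat.mean(axis=0)


def hessian_V(theta_hat: Theta, data: Dataset, space: ParamSpace | None = None) -> np.ndarray:
    """Hessian-type matrix V of the mean log-likelihood at theta_hat.

    Central finite differences of the analytic score, with the hinge
    indicators held fixed at the base point, give the part of the Hessian
    that is continuous in every coordinate; kernel density corrections then
    add the indicator-derived (distributional-limit) terms on the threshold
    diagonal.  With no thresholds (K = J = 0) the correction vanishes and V
    is exactly the numerical Hessian of l_n.
    """
    space = space or ParamSpace(theta_hat.counts)
    vec = space.pack(theta_hat)
    p = space.size
    mask_c = [(data.z > ck).astype(float) for ck in theta_hat.c]
    mask_t = [(data.x > tj).astype(float) for tj in theta_hat.t]

    V = np.empty((p, p))
    for j in range(p):
        h = 1e-5 * max(1.0, abs(vec[j]))
        if j == space.idx_rho:
            h = min(h, 0.4 * (1.0 - abs(vec[j])))
        e = np.zeros(p)
        e[j] = h
        V[:, j] = (
            _mean_score_frozen(vec + e, space, data, mask_c, mask_t)
            - _mean_score_frozen(vec - e, space, data, mask_c, mask_t)
        ) / (2.0 * h)
    V = 0.5 * (V + V.T)

    # Dirac-delta terms: d^2 v_i / dc_k^2 = -alpha_k * delta(z_i - c_k), so the
    # (c_k, c_k) entry gains -alpha_k * E[dl/dv * delta(z - c_k)], estimated by
    # a kernel-weighted average (its own normalization supplies f_hat).
    u, v = residuals(theta_hat, data)
    rho, su, sv = theta_hat.rho, theta_hat.sigma_u, theta_hat.sigma_v
    a = 1.0 / (1.0 - rho * rho)
    gu = -a * (u / su**2 - rho * v / (su * sv))
    gv = -a * (v / sv**2 - rho * u / (su * sv))

    for k in range(space.counts.K):
        idx = space.slice_c.start + k
        bw = _silverman_bandwidth(data.z)
        w = stats.norm.pdf((data.z - theta_hat.c[k]) / bw) / bw
        V[idx, idx] += -theta_hat.alpha[k + 1] * float(np.mean(gv * w))
    for j in range(space.counts.J):
        idx = space.slice_t.start + j
        bw = _silverman_bandwidth(data.x)
        w = stats.norm.pdf((data.x - theta_hat.t[j]) / bw) / bw
        V[idx, idx] += -theta_hat.beta[j + 1] * float(np.mean(gu * w))
    return V


def _covariance_from_parts(M: np.ndarray, V: np.ndarray | None, n: int, mode: str) -> np.ndarray:
    if mode == "model_based":
        cov = _safe_inverse(M, "M") / n
    elif mode == "sandwich":
        V_inv = _safe_inverse(V, "V")
        cov = V_inv @ M @ V_inv / n
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return 0.5 * (cov + cov.T)


def vcov(fit: FitResult, data: Dataset, mode: str = "model_based") -> VarianceEstimate:
    """Covariance of theta_hat: ``model_based`` (M^{-1}/n) or ``sandwich``."""
    if not fit.converged:
        warnings.warn("variance estimate requested for a non-converged fit", RuntimeWarning)
    scores = score_in_space(fit.theta_hat, data, fit.space)
    M = outer_product_M(scores)
    V = hessian_V(fit.theta_hat, data, fit.space) if mode == "sandwich" else None
    cov = _covariance_from_parts(M, V, data.n, mode)
    diag = np.diag(cov)
    if np.any(diag < 0):
        raise ValueError("covariance has negative diagonal entries")
    return VarianceEstimate(
        M=M, V=V, cov=cov, se=np.sqrt(diag), mode=mode, names=fit.space.names
    )


def summarize(fit: FitResult, vc: VarianceEstimate, level: float = 0.95) -> pd.DataFrame:
    """Wald summary table: estimate, se, z, CI and two-sided normal p.

    p-values for threshold locations are reported as missing — testing a
    threshold against zero has no meaning (zero is just another location).
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    est = fit.space.pack(fit.theta_hat)
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        zval = est / vc.se
    pval = 2.0 * stats.norm.sf(np.abs(zval))
    names = fit.space.names
    is_threshold = [name[0] in ("c", "t") and name[1:].isdigit() for name in names]
    pval = np.where(is_threshold, np.nan, pval)
    return pd.DataFrame(
        {
            "parameter": names,
            "estimate": est,
            "se": vc.se,
            "z": zval,
            "ci_low": est - zcrit * vc.se,
            "ci_high": est + zcrit * vc.se,
            "p": pval,
        }
    )
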