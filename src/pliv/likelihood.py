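"""Bivariate-normal limited-information log-likelihood and its analytic score.

The two structural errors (u_i, v_i) are modelled as mean-zero bivariate normal
with standard deviations sigma_u, sigma_v and correlation rho.  Per observation

    l_i = -log(2*pi) - log(sigma_u*sigma_v) - (1/2)*log(1 - rho^2)
          - Q_i / (2*(1 - rho^2)),
    Q_i = u_i^2/sigma_u^2 - 2*rho*u_i*v_i/(sigma_u*sigma_v) + v_i^2/sigma_v^2,

and the criterion maximized is the mean l_n(theta) = (1/n) * sum_i l_i.  The
additive constant -log(2*pi) is kept so that absolute values are comparable
across software and directly usable in AIC/BIC.

The analytic score differentiates through the hinge terms with the strict
subgradient convention d(phi(z, c))/dc = -I(z > c): an observation exactly at a
threshold (a probability-zero event for continuous Z, X) contributes zero.
"""

from __future__ import annotations

import numpy as np

from .model import Dataset, ParamSpace, Theta, relu_threshold

__all__ = ["residuals", "loglik", "score", "score_in_space", "loglik_and_grad_free"]

_LOG_2PI = float(np.log(2.0 * np.pi))


def _stage_columns(v: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    # like model.build_stage_design but tolerant of unsorted thresholds, for
    # use inside optimizer line searches where kinks may transiently cross
    cols = [np.ones_like(v)]
    for tau in thresholds:
        cols.append(relu_threshold(v, tau))
    cols.append(v)
    return np.column_stack(cols)


def _core(alpha, beta, c, t, rho, su, sv, data: Dataset, want_score: bool):
    """Log-likelihood mean and (optionally) the per-observation score matrix."""
    d1 = _stage_columns(data.z, c)
    d2 = _stage_columns(data.x, t)
    v = data.x - d1 @ alpha
    u = data.y - d2 @ beta

    one_m_r2 = 1.0 - rho * rho
    a = 1.0 / one_m_r2
    q = (u / su) ** 2 - 2.0 * rho * (u / su) * (v / sv) + (v / sv) ** 2
    li = -_LOG_2PI - np.log(su * sv) - 0.5 * np.log(one_m_r2) - q * (0.5 * a)
    ll = float(np.mean(li))
    if not want_score:
        return ll, None

    gu = -a * (u / su**2 - rho * v / (su * sv))  # dl/du
    gv = -a * (v / sv**2 - rho * u / (su * sv))  # dl/dv

    s_alpha = -gv[:, None] * d1
    s_beta = -gu[:, None] * d2
    K, J = len(c), len(t)
    s_c = np.empty((data.n, K))
    for k in range(K):
        # dv/dc_k = +alpha_k * I(z > c_k)  (strict; zero exactly at the kink)
        s_c[:, k] = gv * alpha[k + 1] * (data.z > c[k])
    s_t = np.empty((data.n, J))
    for j in range(J):
        s_t[:, j] = gu * beta[j + 1] * (data.x > t[j])

    s_rho = rho * a - rho * a * a * q + a * u * v / (su * sv)
    s_su = -1.0 / su + a * (u**2 / su**3 - rho * u * v / (su**2 * sv))
    s_sv = -1.0 / sv + a * (v**2 / sv**3 - rho * u * v / (sv**2 * su))

    smat = np.column_stack([s_alpha, s_beta, s_c, s_t, s_rho, s_su, s_sv])
    return ll, smat


def _check_domain(theta: Theta) -> None:
    if not abs(theta.rho) < 1:
        raise ValueError(f"|rho| must be < 1, got {theta.rho}")
    if theta.sigma_u <= 0 or theta.sigma_v <= 0:
        raise ValueError("sigma_u and sigma_v must be positive")


def residuals(theta: Theta, data: Dataset) -> tuple[np.ndarray, np.ndarray]:
    """Structural residuals (u, v); u uses the observed x, not the fitted x."""
    from .model import predict_stage1, predict_stage2

    v = data.x - predict_stage1(theta, data.z)
    u = data.y - predict_stage2(theta, data.x)
    return u, v


def loglik(theta: Theta, data: Dataset) -> float:
    """Mean per-observation log-likelihood l_n(theta) (constant included).

    The reported model log-likelihood is ``n * loglik(theta, data)``.
    """
    _check_domain(theta)
    ll, _ = _core(
        theta.alpha, theta.beta, theta.c, theta.t, theta.rho, theta.sigma_u, theta.sigma_v, data, False
    )
    return ll


def score(theta: Theta, data: Dataset) -> np.ndarray:
    """Per-observation score matrix, n x |theta|*.

    Columns follow the canonical order (alpha, beta, c, t, rho, sigma_u,
    sigma_v); entries are d l_i / d theta.  The column means equal the gradient
    of l_n and vanish (up to optimizer tolerance) at a maximizer.
    """
    _check_domain(theta)
    _, smat = _core(
        theta.alpha, theta.beta, theta.c, theta.t, theta.rho, theta.sigma_u, theta.sigma_v, data, True
    )
    return smat


def _reduce_common_sigma(smat: np.ndarray, sigma: float) -> np.ndarray:
    # d l/d sigma2 = (d l/d sigma_u + d l/d sigma_v) / (2*sigma)
    s_sigma2 = (smat[:, -2] + smat[:, -1]) / (2.0 * sigma)
    return np.column_stack([smat[:, :-2], s_sigma2])


def score_in_space(theta: Theta, data: Dataset, space: ParamSpace) -> np.ndarray:
    """Score matrix in the coordinates of ``space``.

    With ``common_sigma`` the last column is the derivative w.r.t. the common
    variance sigma2 = sigma_u^2 = sigma_v^2.
    """
    smat = score(theta, data)
    if not space.common_sigma:
        return smat
    return _reduce_common_sigma(smat, theta.sigma_u)


def loglik_and_grad_free(free: np.ndarray, data: Dataset, space: ParamSpace) -> tuple[float, np.ndarray]:
    """l_n and its gradient in the unconstrained coordinates of ``space``.

    Used by the optimizer; tolerates transiently unsorted thresholds during
    line searches (the model is invariant to reordering the hinge terms).
    """
    vec = space.from_free(free)
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
    ll, smat = _core(alpha, beta, c, t, rho, su, sv, data, True)
    if space.common_sigma:
        smat = _reduce_common_sigma(smat, su)
    grad_nat = smat.mean(axis=0)
    return ll, space.grad_to_free(vec, grad_nat)
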