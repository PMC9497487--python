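"""Core model components for piecewise linear instrumental variable (PLIV) models.

A PLIV model links an instrument Z, an endogenous explanatory variable X and an
outcome Y through two continuous piecewise-linear (kinked) equations::

    x_i = a0 + a1*phi(z_i, c_1) + ... + aK*phi(z_i, c_K) + a_{K+1}*z_i + v_i
    y_i = b0 + b1*phi(x_i, t_1) + ... + bJ*phi(x_i, t_J) + b_{J+1}*x_i + u_i

where ``phi(x, t) = (x - t) * I(x > t)`` is the continuous threshold (hinge /
ReLU) function, (u, v) are correlated bivariate-normal errors capturing
unmeasured confounding, c and t are free threshold (kink) parameters and K >= J
is required for identifiability.  With K = J = 0 the model is the classical
linear instrumental variable model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "relu_threshold",
    "build_stage_design",
    "piecewise_slope",
    "predict_stage1",
    "predict_stage2",
    "ThresholdCounts",
    "Theta",
    "Dataset",
    "ParamSpace",
]


def relu_threshold(x, t):
    """Continuous threshold function ``phi(x, t) = (x - t) * I(x > t)``.

    The indicator is strict, so ``phi(t, t) == 0``; the function is continuous
    in both arguments and nonnegative.  Accepts scalars or arrays in ``x``.
    """
    x = np.asarray(x, dtype=float)
    out = np.where(x > t, x - t, 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def build_stage_design(v, thresholds) -> np.ndarray:
    """Design matrix ``[1, phi(v, tau_1), ..., phi(v, tau_m), v]`` for one stage.

    Column order matches the coefficient order (intercept, threshold terms in
    threshold order, linear term).  ``thresholds`` must be strictly increasing.
    """
    v = np.asarray(v, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size > 1 and not np.all(np.diff(thresholds) > 0):
        raise ValueError("thresholds must be strictly increasing")
    cols = [np.ones_like(v)]
    for tau in thresholds:
        cols.append(relu_threshold(v, tau))
    cols.append(v)
    return np.column_stack(cols)


def piecewise_slope(beta, thresholds, x0: float) -> float:
    """Local slope of the kinked mean function at ``x0``.

    For the stage-2 equation the derivative on the segment ``t_j < x <= t_{j+1}``
    is ``b_{J+1} + sum_{j': t_j' < x0} b_j'`` — the linear coefficient plus every
    threshold coefficient whose kink lies below ``x0``.  The slope is undefined
    exactly at a kink and an error is raised there rather than picking a side.
    """
    beta = np.asarray(beta, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    if beta.size != thresholds.size + 2:
        raise ValueError("beta must have length len(thresholds) + 2")
    if np.any(x0 == thresholds):
        raise ValueError(f"slope undefined at kink point x0={x0}")
    return float(beta[-1] + beta[1:-1][thresholds < x0].sum())


@dataclass(frozen=True)
class ThresholdCounts:
    """Number of thresholds in the instrument (K) and the explanatory variable (J).

    K >= J is required for identifiability (at least as many instruments as
    endogenous regressors); K = J = 0 is the classical linear IV model.
    """

    K: int
    J: int

    def __post_init__(self):
        if self.K < 0 or self.J < 0:
            raise ValueError("threshold counts must be nonnegative")
        if self.K < self.J:
            raise ValueError(
                f"identifiability requires K >= J, got K={self.K}, J={self.J}"
            )


@dataclass
class Theta:
    """Full parameter vector theta = (alpha, beta, c, t, rho, sigma_u, sigma_v).

    ``alpha`` has length K+2 (intercept, K threshold coefficients, linear term),
    ``beta`` length J+2; ``c`` and ``t`` are the strictly increasing threshold
    locations in Z and X.  ``rho`` is the error correlation (|rho| < 1) and
    ``sigma_u``, ``sigma_v`` the positive error standard deviations.
    """

    alpha: np.ndarray
    beta: np.ndarray
    c: np.ndarray = field(default_factory=lambda: np.empty(0))
    t: np.ndarray = field(default_factory=lambda: np.empty(0))
    rho: float = 0.0
    sigma_u: float = 1.0
    sigma_v: float = 1.0

    def __post_init__(self):
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.c = np.atleast_1d(np.asarray(self.c, dtype=float)) if np.size(self.c) else np.empty(0)
        self.t = np.atleast_1d(np.asarray(self.t, dtype=float)) if np.size(self.t) else np.empty(0)
        self.validate()

    @property
    def counts(self) -> ThresholdCounts:
        return ThresholdCounts(K=self.c.size, J=self.t.size)

    @property
    def n_params(self) -> int:
        """Element count |theta|* = (K+2) + (J+2) + K + J + 3."""
        K, J = self.c.size, self.t.size
        return (K + 2) + (J + 2) + K + J + 3

    def validate(self) -> None:
        K, J = self.c.size, self.t.size
        if self.alpha.size != K + 2:
            raise ValueError(f"alpha must have length K+2={K + 2}, got {self.alpha.size}")
        if self.beta.size != J + 2:
            raise ValueError(f"beta must have length J+2={J + 2}, got {self.beta.size}")
        if K > 1 and not np.all(np.diff(self.c) > 0):
            raise ValueError("c must be strictly increasing")
        if J > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")
        if not abs(self.rho) < 1:
            raise ValueError(f"|rho| must be < 1, got {self.rho}")
        if self.sigma_u <= 0 or self.sigma_v <= 0:
            raise ValueError("sigma_u and sigma_v must be positive")
        ThresholdCounts(K=K, J=J)


def predict_stage1(theta: Theta, z) -> np.ndarray:
    """Conditional mean of X given Z (stage-1 equation with zero error)."""
    return build_stage_design(z, theta.c) @ theta.alpha


def predict_stage2(theta: Theta, x) -> np.ndarray:
    """Conditional mean of Y given X (stage-2 equation with zero error)."""
    return build_stage_design(x, theta.t) @ theta.beta


@dataclass
class Dataset:
    """Aligned observation vectors (y, x, z) with transform bookkeeping.

    ``transform_log_*`` record whether a log transform was applied on ingestion;
    ``n_dropped`` counts rows removed for missing values.
    """

    y: np.ndarray
    x: np.ndarray
    z: np.ndarray
    transform_log_y: bool = False
    transform_log_x: bool = False
    transform_log_z: bool = False
    n_dropped: int = 0

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.x = np.asarray(self.x, dtype=float).ravel()
        self.z = np.asarray(self.z, dtype=float).ravel()
        if not (self.y.size == self.x.size == self.z.size):
            raise ValueError("y, x, z must share the same length")
        if self.y.size == 0:
            raise ValueError("empty dataset")
        if not (np.all(np.isfinite(self.y)) and np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.z))):
            raise ValueError("dataset contains non-finite values after ingestion")

    @property
    def n(self) -> int:
        return self.y.size


class ParamSpace:
    """Flat-vector parameterization of Theta for optimization and inference.

    Canonical order: alpha (K+2), beta (J+2), c (K), t (J), then either
    (rho, sigma_u, sigma_v) or, with ``common_sigma=True``, (rho, sigma2) where
    sigma2 is the common error variance sigma_u^2 = sigma_v^2 (the tables'
    single sigma^2 row).
    """

    def __init__(self, counts: ThresholdCounts, common_sigma: bool = False):
        self.counts = counts
        self.common_sigma = bool(common_sigma)
        K, J = counts.K, counts.J
        self.slice_alpha = slice(0, K + 2)
        self.slice_beta = slice(K + 2, K + J + 4)
        self.slice_c = slice(K + J + 4, 2 * K + J + 4)
        self.slice_t = slice(2 * K + J + 4, 2 * K + 2 * J + 4)
        self.idx_rho = 2 * K + 2 * J + 4
        self.size = self.idx_rho + (2 if self.common_sigma else 3)

    @property
    def names(self) -> list[str]:
        K, J = self.counts.K, self.counts.J
        names = [f"alpha{i}" for i in range(K + 2)]
        names += [f"beta{i}" for i in range(J + 2)]
        names += [f"c{k + 1}" for k in range(K)]
        names += [f"t{j + 1}" for j in range(J)]
        names.append("rho")
        names += ["sigma2"] if self.common_sigma else ["sigma_u", "sigma_v"]
        return names

    def pack(self, theta: Theta) -> np.ndarray:
        vec = np.empty(self.size)
        vec[self.slice_alpha] = theta.alpha
        vec[self.slice_beta] = theta.beta
        vec[self.slice_c] = theta.c
        vec[self.slice_t] = theta.t
        vec[self.idx_rho] = theta.rho
        if self.common_sigma:
            vec[self.idx_rho + 1] = 0.5 * (theta.sigma_u**2 + theta.sigma_v**2)
        else:
            vec[self.idx_rho + 1] = theta.sigma_u
            vec[self.idx_rho + 2] = theta.sigma_v
        return vec

    def unpack(self, vec: np.ndarray) -> Theta:
        vec = np.asarray(vec, dtype=float)
        if vec.size != self.size:
            raise ValueError(f"expected vector of length {self.size}, got {vec.size}")
        rho = float(vec[self.idx_rho])
        if self.common_sigma:
            sigma = float(np.sqrt(vec[self.idx_rho + 1]))
            su = sv = sigma
        else:
            su = float(vec[self.idx_rho + 1])
            sv = float(vec[self.idx_rho + 2])
        return Theta(
            alpha=vec[self.slice_alpha].copy(),
            beta=vec[self.slice_beta].copy(),
            c=vec[self.slice_c].copy(),
            t=vec[self.slice_t].copy(),
            rho=rho,
            sigma_u=su,
            sigma_v=sv,
        )

    # -- unconstrained (free) coordinates for quasi-Newton ascent ------------
    # rho = tanh(eta), variances through log; thresholds stay on the raw scale.

    def to_free(self, vec: np.ndarray) -> np.ndarray:
        free = np.array(vec, dtype=float, copy=True)
        free[self.idx_rho] = np.arctanh(vec[self.idx_rho])
        free[self.idx_rho + 1 :] = np.log(vec[self.idx_rho + 1 :])
        return free

    def from_free(self, free: np.ndarray) -> np.ndarray:
        vec = np.array(free, dtype=float, copy=True)
        vec[self.idx_rho] = np.tanh(free[self.idx_rho])
        vec[self.idx_rho + 1 :] = np.exp(free[self.idx_rho + 1 :])
        return vec

    def grad_to_free(self, vec: np.ndarray, grad: np.ndarray) -> np.ndarray:
        """Chain rule: gradient w.r.t. natural params -> w.r.t. free params."""
        g = np.array(grad, dtype=float, copy=True)
        g[self.idx_rho] = grad[self.idx_rho] * (1.0 - vec[self.idx_rho] ** 2)
        g[self.idx_rho + 1 :] = grad[self.idx_rho + 1 :] * vec[self.idx_rho + 1 :]
        return g
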