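"""Zero-inflated negative binomial (ZINB) regression with a stage covariate.

The model for a per-pupa bacterial count :math:`y_i` at stage
:math:`s_i \\in \\{0, 1\\}` (P0 -> 0, pharate adult -> 1) is a two-part
mixture.  A logistic "structural zero" component,

.. math:: \\mathrm{logit}\\,\\pi_i = \\gamma_0 + \\gamma_1 s_i,

treats zero as the event of interest (an individual that cleared or never
carried bacteria), while counts otherwise follow an NB2 negative binomial
with stage-dependent mean,

.. math:: \\log \\mu_i = \\beta_0 + \\beta_1 s_i,
          \\qquad \\mathrm{Var}(y) = \\mu + \\mu^2/\\theta .

Positive :math:`\\beta_1` means higher counts in pharate adults than at
pupariation; the dispersion :math:`\\theta` is shared across stages.  The
fit maximises the exact mixture log-likelihood over
:math:`(\\beta, \\gamma, \\log\\theta)` by quasi-Newton iteration with an
analytic gradient.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import optimize, special

GAMMA_BOUND = 15.0  # |gamma| clamp under perfect separation of the zero indicator
THETA_BOUND = 10.0  # |log theta| clamp when dispersion is barely identified


class DegenerateDataError(ValueError):
    """Input cannot identify the model (a stage absent, or no zeros/positives)."""


@dataclasses.dataclass(frozen=True)
class ZinbParams:
    """ZINB parameters: count coefficients ``beta`` (log-mean scale), zero
    coefficients ``gamma`` (logit scale), and ``log_theta``."""

    beta: np.ndarray  # (intercept, stage)
    gamma: np.ndarray  # (intercept, stage)
    log_theta: float

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta, dtype=float)
        gamma = np.asarray(self.gamma, dtype=float)
        if beta.shape != (2,) or gamma.shape != (2,):
            raise ValueError("beta and gamma must each have shape (2,)")
        if not (np.isfinite(beta).all() and np.isfinite(gamma).all()
                and np.isfinite(self.log_theta)):
            raise ValueError("ZINB parameters must be finite")
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "gamma", gamma)

    @property
    def theta(self) -> float:
        return float(np.exp(self.log_theta))

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.beta, self.gamma, [self.log_theta]])

    @classmethod
    def from_vector(cls, x: np.ndarray) -> "ZinbParams":
        x = np.asarray(x, dtype=float)
        return cls(beta=x[:2], gamma=x[2:4], log_theta=float(x[4]))


@dataclasses.dataclass(frozen=True)
class ZinbFit:
    params: ZinbParams
    loglik: float
    converged: bool
    n_obs: int
    gradient_norm: float
    iterations: int
    boundary: bool = False  # gamma clamped due to perfect separation
    standard_errors: np.ndarray | None = None


def nb_log_pmf(y, mu, theta):
    """Log pmf of the NB2 negative binomial (mean ``mu``, dispersion ``theta``).

    ``log[ Gamma(y+theta) / (Gamma(theta) y!) * (theta/(theta+mu))^theta
    * (mu/(theta+mu))^y ]``, evaluated through log-gamma for stability.
    Vectorised over any broadcastable combination of arguments.
    """
    y = np.asarray(y)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("y must contain non-negative integers")
    y = y.astype(float)
    mu = np.asarray(mu, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(mu <= 0) or np.any(theta <= 0):
        raise ValueError("mu and theta must be positive")
    return (
        special.gammaln(y + theta)
        - special.gammaln(theta)
        - special.gammaln(y + 1.0)
        + theta * np.log(theta / (theta + mu))
        + y * np.log(mu / (theta + mu))
    )


def _design(data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Counts and 0/1 stage coding (P0 -> 0, pharate -> 1) from a CFU table."""
    if "cfu_per_pupa" in data.columns:
        y = np.asarray(data["cfu_per_pupa"], dtype=float)
    else:
        y = np.asarray(data["colonies"], dtype=float)
    stage = np.asarray(data["stage"].astype(str) == "pharate", dtype=float)
    return y, stage


def zinb_log_likelihood(params: ZinbParams, data: pd.DataFrame) -> float:
    """Exact ZINB log-likelihood of a CFU dataset under ``params``.

    The zero branch ``log(pi + (1-pi) * NB(0))`` is computed with
    log-sum-exp stabilisation; invariant to row order.
    """
    y, stage = _design(data)
    ll, _ = _loglik_and_grad(params.to_vector(), y, stage)
    return float(ll)


def _loglik_and_grad(x: np.ndarray, y: np.ndarray, stage: np.ndarray):
    b0, b1, g0, g1, logtheta = x
    theta = np.exp(logtheta)
    eta_mu = b0 + b1 * stage
    eta_z = g0 + g1 * stage
    mu = np.exp(eta_mu)

    softplus = np.logaddexp(0.0, eta_z)  # log(1 + e^eta_z)
    sig = special.expit(eta_z)
    log_ratio = np.log(theta) - np.log(theta + mu)  # log(theta/(theta+mu))

    zero = y == 0
    pos = ~zero

    ll = np.empty_like(y)
    # gradient pieces: d ll / d eta_z, d ll / d log mu, d ll / d log theta
    d_eta_z = np.empty_like(y)
    d_log_mu = np.empty_like(y)
    d_log_theta = np.empty_like(y)

    # y > 0: log(1-pi) + NB log pmf
    if pos.any():
        yp, mup, lrp = y[pos], mu[pos], log_ratio[pos]
        nb = (
            special.gammaln(yp + theta)
            - special.gammaln(theta)
            - special.gammaln(yp + 1.0)
            + theta * lrp
            + yp * (np.log(mup) - np.log(theta + mup))
        )
        ll[pos] = -softplus[pos] + nb
        d_eta_z[pos] = -sig[pos]
        d_log_mu[pos] = yp - (yp + theta) * mup / (theta + mup)
        dtheta = (
            special.digamma(yp + theta)
            - special.digamma(theta)
            + lrp
            + (mup - yp) / (theta + mup)
        )
        d_log_theta[pos] = theta * dtheta

    # y = 0: log(pi + (1-pi) p0) = logaddexp(eta_z, l0) - softplus(eta_z)
    if zero.any():
        mu0, lr0 = mu[zero], log_ratio[zero]
        l0 = theta * lr0
        A = np.logaddexp(eta_z[zero], l0)
        ll[zero] = A - softplus[zero]
        w_z = special.expit(eta_z[zero] - l0)  # weight of the structural-zero branch
        w_nb = 1.0 - w_z
        d_eta_z[zero] = w_z - sig[zero]
        d_log_mu[zero] = w_nb * (-theta * mu0 / (theta + mu0))
        d_log_theta[zero] = w_nb * theta * (lr0 + mu0 / (theta + mu0))

    grad = np.array(
        [
            d_log_mu.sum(),
            (d_log_mu * stage).sum(),
            d_eta_z.sum(),
            (d_eta_z * stage).sum(),
            d_log_theta.sum(),
        ]
    )
    return ll.sum(), grad


def _starting_values(y: np.ndarray, stage: np.ndarray) -> np.ndarray:
    """Poisson log-linear fit for beta, empirical zero-fraction logits for
    gamma (clamped), log theta = 0."""
    mean0 = y[stage == 0].mean()
    mean1 = y[stage == 1].mean()
    b0 = np.log(max(mean0, 0.5))
    b1 = np.log(max(mean1, 0.5)) - b0
    z0 = (y[stage == 0] == 0).mean()
    z1 = (y[stage == 1] == 0).mean()

    def _logit(p: float) -> float:
        p = min(max(p, 1e-3), 1.0 - 1e-3)
        return float(np.log(p / (1.0 - p)))

    g0 = _logit(z0)
    g1 = _logit(z1) - g0
    return np.array([b0, b1, g0, g1, 0.0])


def fit_zinb(
    data: pd.DataFrame,
    tolerance: float = 1e-6,
    max_iterations: int = 500,
    compute_se: bool = False,
) -> ZinbFit:
    """Maximum-likelihood ZINB fit of counts on stage.

    Starts from a Poisson log-linear fit (count part) and the empirical
    logit of per-stage zero fractions (zero part), then maximises the exact
    mixture likelihood by L-BFGS-B with an analytic gradient.  Convergence
    requires max-abs gradient <= ``tolerance``.  Under perfect separation of
    the zero indicator within a stage the zero coefficients are clamped at
    ``|gamma| = 15`` and the fit is flagged ``boundary`` (still converged).
    A stalled optimiser returns ``converged=False`` rather than raising.

    Raises
    ------
    DegenerateDataError
        If a stage level is absent, all counts are zero, or no count is zero
        in either stage *and* the data cannot identify both components.
    """
    y, stage = _design(data)
    if np.any(y != np.floor(y)) or np.any(y < 0):
        raise ValueError("counts must be non-negative integers")
    if len(np.unique(stage)) < 2:
        raise DegenerateDataError("both stages (P0 and pharate) must be present")
    if (y == 0).all():
        raise DegenerateDataError("all counts are zero: count component unidentified")
    if not (y == 0).any():
        raise DegenerateDataError("no zero counts: zero component unidentified")
    for s in (0.0, 1.0):
        if not (y[stage == s] > 0).any():
            raise DegenerateDataError(
                "a stage has no positive counts: stage mean unidentified"
            )

    x0 = _starting_values(y, stage)
    ll0, _ = _loglik_and_grad(x0, y, stage)

    x0[4] = float(np.clip(x0[4], -THETA_BOUND, THETA_BOUND))
    bounds = (
        [(None, None)] * 2
        + [(-GAMMA_BOUND, GAMMA_BOUND)] * 2
        + [(-THETA_BOUND, THETA_BOUND)]
    )

    def negloglik(x):
        ll, grad = _loglik_and_grad(x, y, stage)
        return -ll, -grad

    res = optimize.minimize(
        negloglik,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iterations, "ftol": 1e-14, "gtol": 1e-9},
    )
    x, iterations = res.x, int(res.nit)
    x, gnorm, newton_iters, at_bound, stalled = _newton_polish(x, y, stage, tolerance)
    iterations += newton_iters

    ll, _ = _loglik_and_grad(x, y, stage)
    # converged outright, or stalled at machine precision with a small gradient
    # (relative log-likelihood change below 1e-10 and gradient below sqrt(tol))
    ok = gnorm <= tolerance or (stalled and gnorm <= np.sqrt(tolerance))
    converged = bool(ok and ll >= ll0 - 1e-8)
    params = ZinbParams.from_vector(x)

    se = None
    if compute_se:
        se = _observed_information_se(x, y, stage)

    return ZinbFit(
        params=params,
        loglik=float(ll),
        converged=converged,
        n_obs=len(y),
        gradient_norm=gnorm,
        iterations=iterations,
        boundary=bool(at_bound),
        standard_errors=se,
    )


def _numerical_hessian(x: np.ndarray, y: np.ndarray, stage: np.ndarray) -> np.ndarray:
    k = len(x)
    H = np.zeros((k, k))
    for j in range(k):
        h = 1e-5 * (1.0 + abs(x[j]))
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        _, gp = _loglik_and_grad(xp, y, stage)
        _, gm = _loglik_and_grad(xm, y, stage)
        H[j] = (gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


def _newton_polish(
    x: np.ndarray,
    y: np.ndarray,
    stage: np.ndarray,
    tolerance: float,
    max_steps: int = 25,
) -> tuple[np.ndarray, float, int, bool]:
    """Damped Newton refinement to drive the max-abs gradient below tolerance.

    Gamma and log-theta coordinates are projected onto their clamp boxes;
    clamped coordinates whose gradient pushes outward are excluded from the
    convergence norm (KKT-style).
    """
    box = np.array([np.inf, np.inf, GAMMA_BOUND, GAMMA_BOUND, THETA_BOUND])

    def clamped(v: np.ndarray) -> np.ndarray:
        return np.clip(v, -box, box)

    def free_grad_norm(v: np.ndarray, g: np.ndarray) -> float:
        g = g.copy()
        for j in (2, 3, 4):
            if abs(v[j]) >= box[j] - 1e-8 and v[j] * g[j] > 0:
                g[j] = 0.0
        return float(np.max(np.abs(g)))

    x = clamped(x)
    ll, grad = _loglik_and_grad(x, y, stage)
    steps = 0
    stalled = False
    while free_grad_norm(x, grad) > tolerance and steps < max_steps:
        H = _numerical_hessian(x, y, stage)
        try:
            direction = np.linalg.solve(H, -grad)
        except np.linalg.LinAlgError:
            stalled = True
            break
        if not np.isfinite(direction).all():
            stalled = True
            break
        # ascent check: fall back to gradient direction if Newton points downhill
        if grad @ direction <= 0:
            direction = grad / (1.0 + np.max(np.abs(grad)))
        t = 1.0
        improved = False
        for _ in range(30):
            x_new = clamped(x + t * direction)
            ll_new, grad_new = _loglik_and_grad(x_new, y, stage)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                gain = ll_new - ll
                x, ll, grad = x_new, ll_new, grad_new
                improved = True
                # relative log-likelihood change at numerical precision
                if abs(gain) <= 1e-10 * (1.0 + abs(ll)):
                    stalled = True
                break
            t *= 0.5
        steps += 1
        if not improved:
            stalled = True
            break
        if stalled:
            break
    at_bound = bool(np.any(np.abs(x[2:]) >= box[2:] - 1e-8))
    return x, free_grad_norm(x, grad), steps, at_bound, stalled


def _observed_information_se(x: np.ndarray, y: np.ndarray, stage: np.ndarray):
    """Diagnostic standard errors from the inverse observed information
    (central-difference Hessian of the log-likelihood)."""
    H = _numerical_hessian(x, y, stage)
    try:
        cov = np.linalg.inv(-H)
        d = np.diag(cov)
        return np.sqrt(np.where(d > 0, d, np.nan))
    except np.linalg.LinAlgError:
        return np.full(len(x), np.nan)
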