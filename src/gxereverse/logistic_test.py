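"""Standard logistic-regression Wald test for GxE interaction.

Fits logit Pr(D=1|G,X,Z) = a0 + m(Z) + ax*X + ag*G + agx*G*X by
iteratively reweighted least squares (IRLS / Newton-Raphson with
step-halving) and tests H0: agx = 0 with the 1-df Wald statistic
tau^2 = agx_hat^2 / Var(agx_hat).

When the exposure is measured with classical additive error, the naive
interaction estimate from the error-prone exposure is attenuated by the
reliability rho = Var(X)/Var(X*); regression calibration divides it
back out (valid when the disease is rare and X|G,Z is normal, or when
Var(X|X*,G,Z) is small).  The Wald *test* on the naive coefficient
remains valid either way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, special

from .datatypes import (
    ConvergenceError,
    DegenerateVarianceError,
    InfeasibleErrorVarianceError,
    SeparationError,
)
from .design import DesignMatrix
from .reverse_test import TestResult, _wald_1df

__all__ = ["LogisticFit", "CalibrationResult", "fit_logistic", "wald_gx", "calibrate_attenuation"]

MAX_ABS_COEF = 30.0  # beyond this the fit is treated as separated


@dataclass
class LogisticFit:
    coef: np.ndarray
    cov: np.ndarray
    n_iter: int
    converged: bool
    loglik: float
    gx_index: int | None = None


@dataclass
class CalibrationResult:
    """Regression-calibration correction of the interaction coefficient."""

    rho_hat: float
    alpha_gx_corrected: float
    alpha_gx_naive: float


def _bernoulli_loglik(d: np.ndarray, eta: np.ndarray) -> float:
    # log L = sum d*eta - log(1+exp(eta)), stable via logaddexp
    return float(d @ eta - np.logaddexp(0.0, eta).sum())


def fit_logistic(
    design: DesignMatrix,
    d: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> LogisticFit:
    """Maximum-likelihood logistic fit by IRLS with step-halving.

    Convergence requires the relative log-likelihood change to fall
    below ``tol`` and the score to be numerically zero.  Quasi-complete
    separation (diverging coefficients or fitted probabilities pinned at
    0/1 on the wrong side) raises :class:`SeparationError` rather than
    returning a silently unstable fit.
    """
    X = design.values
    d = np.asarray(d, dtype=float)
    n, p = X.shape
    if d.shape[0] != n:
        raise ValueError("outcome length does not match design")
    uniq = np.unique(d)
    if not np.isin(uniq, (0.0, 1.0)).all():
        raise ValueError("outcome must be coded 0/1")
    if uniq.size < 2:
        raise SeparationError("outcome is constant; logistic model is degenerate")

    beta = np.zeros(p)
    pbar = d.mean()
    beta[0] = np.log(pbar / (1.0 - pbar))  # intercept-only start
    eta = X @ beta
    ll = _bernoulli_loglik(d, eta)
    trace = [ll]

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = special.expit(eta)
        w = mu * (1.0 - mu)
        score = X.T @ (d - mu)
        hess = X.T @ (X * w[:, None])
        try:
            step = linalg.solve(hess, score, assume_a="pos")
        except linalg.LinAlgError:
            raise SeparationError(
                "Fisher information is singular (separation or collinearity)"
            ) from None

        # step-halving: the log-likelihood must not decrease
        scale = 1.0
        for _ in range(30):
            beta_new = beta + scale * step
            eta_new = X @ beta_new
            ll_new = _bernoulli_loglik(d, eta_new)
            if ll_new >= ll - 1e-12 * (abs(ll) + 1.0):
                break
            scale *= 0.5
        beta, eta = beta_new, eta_new
        trace.append(ll_new)

        if np.abs(beta).max() > MAX_ABS_COEF:
            raise SeparationError(
                f"coefficient magnitude exceeded {MAX_ABS_COEF}; "
                "quasi-complete separation suspected"
            )
        rel_change = abs(ll_new - ll) / (abs(ll) + 1.0)
        ll = ll_new
        if rel_change < tol:
            mu = special.expit(eta)
            score = X.T @ (d - mu)
            # converged only once the score is numerically zero as well;
            # otherwise let Newton polish it (quadratic convergence makes
            # this at most one or two extra iterations)
            if np.abs(score).max() < 1e-6 * np.sqrt(n):
                converged = True
                break

    if not converged:
        raise ConvergenceError(
            f"IRLS did not converge within {it} iterations", trace=trace
        )

    mu = special.expit(eta)
    w = mu * (1.0 - mu)
    hess = X.T @ (X * w[:, None])
    cov = linalg.solve(hess, np.eye(p), assume_a="pos")
    return LogisticFit(
        coef=beta,
        cov=cov,
        n_iter=it,
        converged=converged,
        loglik=ll,
        gx_index=design.gx_index,
    )


def wald_gx(fit: LogisticFit, design: DesignMatrix) -> TestResult:
    """1-df Wald test of H0: agx = 0 in the logistic model."""
    j = design.gx_index
    if j is None:
        raise ValueError("design has no GX column; was it built with model_role='logistic'?")
    return _wald_1df(float(fit.coef[j]), float(fit.cov[j, j]), "model")


def calibrate_attenuation(
    fit_star: LogisticFit,
    x_star: np.ndarray,
    sigma_delta2: float,
) -> CalibrationResult:
    """Regression-calibration correction agx_hat ~= agx*_hat / rho_hat.

    ``rho_hat = (Var(X*) - sigma_delta2)/Var(X*) = Var(X)/(Var(X)+sigma_delta2)``
    estimates the reliability of the error-prone exposure; the naive
    interaction coefficient is divided by it.
    """
    if fit_star.gx_index is None:
        raise ValueError("fit does not carry a GX column index")
    if sigma_delta2 < 0:
        raise ValueError("measurement-error variance must be nonnegative")
    var_star = float(np.var(np.asarray(x_star, dtype=float), ddof=1))
    if sigma_delta2 >= var_star:
        raise InfeasibleErrorVarianceError(
            f"assumed error variance {sigma_delta2} is not smaller than "
            f"Var(X*) = {var_star:.4g}"
        )
    rho_hat = (var_star - sigma_delta2) / var_star
    naive = float(fit_star.coef[fit_star.gx_index])
    return CalibrationResult(
        rho_hat=rho_hat,
        alpha_gx_corrected=naive / rho_hat,
        alpha_gx_naive=naive,
    )
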