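"""The reverse (exposure-on-disease) test for gene-environment interaction.

The reverse test regresses the continuous exposure X on disease status
D, genotype G, their product GD and confounders:

    X = b0 + h(Z) + bg*G + bd*D + bgd*G*D + eps,   eps ~ N(0, sigma^2)

Under conditional normality with constant variance this linear model and
the prospective logistic disease model hold simultaneously, with
alpha_gx = bgd / sigma^2; testing H0: bgd = 0 with the one-degree-of-
freedom Wald statistic tau^2 = bgd_hat^2 / Var(bgd_hat) is therefore a
test of no interaction on the odds-ratio scale (ROR = exp(bgd/sigma^2)
= 1).  Because OLS has a closed form, the test is several-fold cheaper
than the iterative logistic fit, which is what makes it attractive for
genome-wide scans.

When the residual variance depends on covariates the model-based
variance is invalid and a heteroskedasticity-consistent (sandwich)
variance should be used; the Wald test of bgd = 0 then remains a valid
test of no interaction in the difference-of-mean-differences sense
(DMD = bgd), even though exp(bgd/sigma^2) no longer equals the ROR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize, stats

from .datatypes import (
    CollinearityError,
    DegenerateInputError,
    DegenerateVarianceError,
)
from .design import DesignMatrix

__all__ = [
    "OLSFit",
    "TestResult",
    "RORResult",
    "DiagnosticReport",
    "fit_ols",
    "wald_gd",
    "estimate_ror",
    "set_test",
    "yeo_johnson",
    "diagnostics",
]


@dataclass
class TestResult:
    """A Wald chi-square test (tau^2 statistic)."""

    stat: float
    df: int
    p_value: float
    variance_used: str  # "model" or "sandwich"


@dataclass
class OLSFit:
    coef: np.ndarray
    cov_model: np.ndarray
    cov_sandwich: np.ndarray
    sigma2_hat: float
    residuals: np.ndarray
    df_resid: int
    gd_index: int | None = None
    sandwich_flavor: str = "HC0"


@dataclass
class RORResult:
    """Ratio of odds ratios implied by the reverse fit.

    ``ror_hat = exp(bgd_hat / sigma2_hat)``; ``dmd_hat`` is the
    difference of mean differences, identically the fitted GD
    coefficient.
    """

    ror_hat: float
    log_ror_se: float
    ci_lower: float
    ci_upper: float
    dmd_hat: float
    level: float = 0.95


@dataclass
class DiagnosticReport:
    normality_p: float
    heteroskedasticity_p: float
    skewness: float


def _solve_normal_equations(X: np.ndarray, y: np.ndarray, names: list[str] | None = None):
    """Cholesky solve of X'X b = X'y; diagnose the offending column on failure."""
    xtx = X.T @ X
    xty = X.T @ y
    try:
        c, low = linalg.cho_factor(xtx, check_finite=False)
        # rounding can let an exactly singular matrix through: a pivot far
        # below the column scale means some column is a linear combination
        pivots2 = np.diag(c) ** 2
        if np.any(pivots2 <= 1e-12 * np.diag(xtx)):
            raise linalg.LinAlgError
    except linalg.LinAlgError:
        col = _find_collinear_column(X, names)
        raise CollinearityError(
            f"design matrix is rank deficient (column {col!r})", column=col
        ) from None
    coef = linalg.cho_solve((c, low), xty, check_finite=False)
    xtx_inv = linalg.cho_solve((c, low), np.eye(X.shape[1]), check_finite=False)
    return coef, xtx_inv


def _find_collinear_column(X: np.ndarray, names: list[str] | None) -> str:
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    bad = int(np.argmin(diag / (diag.max() + 1e-300)))
    return names[bad] if names else f"#{bad}"


def fit_ols(design: DesignMatrix, y: np.ndarray, sandwich_flavor: str = "HC0") -> OLSFit:
    """Ordinary least squares fit of the reverse linear model.

    Returns both the model-based covariance ``sigma2*(X'X)^-1`` and a
    heteroskedasticity-consistent sandwich covariance (HC0 by default;
    HC1 and HC3 available via ``sandwich_flavor``).
    """
    X = design.values
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("response length does not match design")
    coef, xtx_inv = _solve_normal_equations(X, y, design.columns)
    resid = y - X @ coef
    df_resid = n - p
    rss = float(resid @ resid)
    sigma2 = rss / df_resid if df_resid > 0 else 0.0
    cov_model = sigma2 * xtx_inv

    e2 = resid**2
    if sandwich_flavor == "HC1":
        e2 = e2 * (n / df_resid)
    elif sandwich_flavor == "HC3":
        h = np.einsum("ij,jk,ik->i", X, xtx_inv, X)
        e2 = e2 / (1.0 - h) ** 2
    elif sandwich_flavor != "HC0":
        raise ValueError(f"unknown sandwich flavor {sandwich_flavor!r}")
    meat = X.T @ (X * e2[:, None])
    cov_sandwich = xtx_inv @ meat @ xtx_inv

    return OLSFit(
        coef=coef,
        cov_model=cov_model,
        cov_sandwich=cov_sandwich,
        sigma2_hat=sigma2,
        residuals=resid,
        df_resid=df_resid,
        gd_index=design.gd_index,
        sandwich_flavor=sandwich_flavor,
    )


def _wald_1df(beta: float, var: float, variance_used: str) -> TestResult:
    if var <= 0 or not np.isfinite(var):
        raise DegenerateVarianceError(
            f"estimated variance of the interaction coefficient is {var}; "
            "Wald statistic undefined"
        )
    stat = beta * beta / var
    return TestResult(stat=float(stat), df=1, p_value=float(stats.chi2.sf(stat, 1)), variance_used=variance_used)


def wald_gd(fit: OLSFit, design: DesignMatrix, variance: str = "model") -> TestResult:
    """1-df Wald test of H0: bgd = 0 (no GxE interaction)."""
    j = design.gd_index
    if j is None:
        raise ValueError("design has no GD column; was it built with model_role='reverse'?")
    cov = fit.cov_model if variance == "model" else fit.cov_sandwich
    if variance not in ("model", "sandwich"):
        raise ValueError("variance must be 'model' or 'sandwich'")
    return _wald_1df(float(fit.coef[j]), float(cov[j, j]), variance)


def estimate_ror(fit: OLSFit, level: float = 0.95) -> RORResult:
    """Point estimate and delta-method CI for the ratio of odds ratios.

    log ROR_hat = bgd_hat / sigma2_hat.  Treating bgd_hat and sigma2_hat
    as independent (exact under normal theory), with
    Var(sigma2_hat) = 2 sigma^4 / df_resid,

        SE(log ROR)^2 = Var(bgd_hat)/sigma^4 + 2 bgd_hat^2 / (sigma^4 df_resid).
    """
    if fit.gd_index is None:
        raise ValueError("fit does not carry a GD column index")
    if fit.sigma2_hat <= 0:
        raise DegenerateVarianceError("sigma2_hat is zero; ROR undefined")
    bgd = float(fit.coef[fit.gd_index])
    s2 = fit.sigma2_hat
    var_b = float(fit.cov_model[fit.gd_index, fit.gd_index])
    log_ror = bgd / s2
    se = np.sqrt(var_b / s2**2 + 2.0 * bgd**2 / (s2**2 * fit.df_resid))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return RORResult(
        ror_hat=float(np.exp(log_ror)),
        log_ror_se=float(se),
        ci_lower=float(np.exp(log_ror - z * se)),
        ci_upper=float(np.exp(log_ror + z * se)),
        dmd_hat=bgd,
        level=level,
    )


def set_test(
    fit: OLSFit,
    design: DesignMatrix,
    gd_indices,
    variance: str = "model",
) -> TestResult:
    """Multi-marker interaction test on a block of G_k * D columns.

    Wald statistic b' V^-1 b over the selected coefficient block, with
    |indices| degrees of freedom; reduces to :func:`wald_gd` for a
    single index.
    """
    idx = np.atleast_1d(np.asarray(gd_indices, dtype=int))
    if idx.size == 0:
        raise ValueError("need at least one interaction index")
    if idx.min() < 0 or idx.max() >= design.p:
        raise ValueError("interaction index out of range")
    cov = fit.cov_model if variance == "model" else fit.cov_sandwich
    b = fit.coef[idx]
    V = cov[np.ix_(idx, idx)]
    try:
        stat = float(b @ linalg.solve(V, b, assume_a="pos"))
    except linalg.LinAlgError:
        raise DegenerateVarianceError("singular covariance block in set test") from None
    df = idx.size
    return TestResult(stat=stat, df=df, p_value=float(stats.chi2.sf(stat, df)), variance_used=variance)


def _yj_transform(x: np.ndarray, gamma: float) -> np.ndarray:
    if abs(gamma) < 1e-12:
        return np.log1p(x)
    return (np.power(x + 1.0, gamma) - 1.0) / gamma


def yeo_johnson(x: np.ndarray, gamma: float | str = "estimate"):
    """Power transform T(x) = ((x+1)^gamma - 1)/gamma for nonnegative x.

    For gamma = 0 the transform is log(x+1) (the continuous limit).  With
    ``gamma='estimate'`` the exponent maximising the normal profile
    log-likelihood is found by bounded scalar search over [-2, 2].

    Returns ``(transformed, gamma)``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("this transform branch requires nonnegative values")
    if gamma == "estimate":
        logs = np.log1p(x)

        def neg_profile_ll(gm):
            t = _yj_transform(x, gm)
            var = t.var()
            if var <= 0:
                return np.inf
            return 0.5 * x.size * np.log(var) - (gm - 1.0) * logs.sum()

        res = optimize.minimize_scalar(neg_profile_ll, bounds=(-2.0, 2.0), method="bounded")
        gamma = float(res.x)
    else:
        gamma = float(gamma)
    return _yj_transform(x, gamma), gamma


def diagnostics(fit: OLSFit, design: DesignMatrix) -> DiagnosticReport:
    """Residual checks of the two assumptions behind the ROR interpretation.

    Jarque-Bera on the residuals probes conditional normality; the White
    test (auxiliary regression of squared residuals on the design, its
    squares and cross-products) probes constant variance.  Residual
    skewness is reported to guide transformation choices.
    """
    resid = fit.residuals
    n = resid.shape[0]
    p = design.p
    # White's auxiliary regression needs more rows than cross-product terms
    n_aux = p * (p + 1) // 2
    if n <= n_aux + 1:
        raise DegenerateInputError(
            f"n={n} too small for the White auxiliary regression ({n_aux} terms)"
        )
    jb_stat, jb_p = stats.jarque_bera(resid)
    white_p = _white_test_p(resid, design.values)
    return DiagnosticReport(
        normality_p=float(jb_p),
        heteroskedasticity_p=float(white_p),
        skewness=float(stats.skew(resid)),
    )


def _white_test_p(resid: np.ndarray, X: np.ndarray) -> float:
    """White LM test, tolerant of rank-deficient auxiliary designs.

    GxE designs routinely contain binary columns whose squares duplicate
    themselves, so the squares-and-cross-products auxiliary matrix is
    rank deficient by construction; duplicated directions are dropped
    and the chi-square df is the post-reduction rank minus one.
    """
    n, p = X.shape
    prods = [X[:, i] * X[:, j] for i in range(1, p) for j in range(i, p)]
    aux = np.column_stack([X] + prods) if prods else np.asarray(X)
    _, r = np.linalg.qr(aux)
    diag = np.abs(np.diag(r))
    keep = diag > 1e-8 * diag.max()
    aux = aux[:, keep]
    df = int(aux.shape[1]) - 1
    if df < 1:
        raise DegenerateInputError("auxiliary regression has no non-constant terms")
    e2 = resid**2
    coef, *_ = np.linalg.lstsq(aux, e2, rcond=None)
    fitted = aux @ coef
    ss_tot = float(((e2 - e2.mean()) ** 2).sum())
    if ss_tot <= 0:
        return 1.0
    r2 = 1.0 - float(((e2 - fitted) ** 2).sum()) / ss_tot
    return float(stats.chi2.sf(n * r2, df))
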