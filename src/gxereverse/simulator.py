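"""Compatible-model simulator for GxE interaction experiments.

Data are generated so that the prospective logistic disease model and
the reverse linear exposure model hold *simultaneously*:

    logit Pr(D=1|G,X,Z) = a0 + a1*Z1 + a2*Z1^2 + a3*Z2 + ag*G + ax*X + agx*G*X
    X = b0 + b1*Z1 + b2*Z1^2 + b3*Z2 + bg*G + bd*D + bgd*G*D + eps,  eps ~ N(0,1)

with the bridge identities ax = bd/sigma^2 and agx = bgd/sigma^2.  The
generation order is Z -> G -> D|G,Z -> X|D,G,Z; the D|G,Z law is the
unique logit (see :func:`compatible_disease_logit`) that, combined with
the normal X|D,G,Z model, yields exactly the logistic model above by
Bayes' rule.

Confounder/genotype marginals (not dictated by the joint model): Z1 is
standard normal, Z2 is Bernoulli(0.5), G is Bernoulli(0.3) for the
binary coding or Binomial(2, maf) for ordinal dosages, all mutually
independent.  Classical additive measurement error X* = X + delta can
be injected at a chosen reliability rho = Var(X)/Var(X*), and two
misspecification families break the compatibility on purpose (a simple
logistic D|G,Z law, or a rectified-Gaussian linear-model error).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .datatypes import GxEDataset

__all__ = [
    "ScenarioSpec",
    "ModelParams",
    "resolve_params",
    "compatible_disease_logit",
    "simulate_cohort",
    "sample_case_control",
    "add_measurement_error",
    "measurement_error_variance",
    "simulate_misspecified",
    "MISSPEC_VARIANTS",
]

MISSPEC_VARIANTS = (
    "none",
    "scenario_I_linear",
    "scenario_I_logistic",
    "scenario_II_linear",
    "scenario_II_logistic",
)


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation scenario, parameterised the way the result tables are.

    Effects are stated as odds ratios per unit increase (``or_g`` for the
    gene main effect at X=0, ``or_x`` for the exposure main effect at
    G=0, ``ror`` for the interaction) at baseline prevalence ``p0`` =
    Pr(D=1 | G=X=Z1=Z2=0).  ``corr_xz2`` and ``corr_xg`` are conditional
    (given everything else at reference) exposure-confounder and
    exposure-gene correlations; ``rho`` in (0,1] is the measurement-
    error reliability Var(X)/Var(X*), 1 meaning no error.
    """

    p0: float = 0.05
    or_g: float = 1.1
    or_x: float = 1.1
    ror: float = 1.0
    corr_xz2: float = 0.01
    corr_xg: float = 0.01
    rho: float = 1.0
    confounder_or: float = 1.2
    cohort_n: int = 100_000
    n_cases: int = 1000
    n_controls: int = 1000
    misspec: str = "none"
    genotype_coding: str = "ordinal"  # 0/1/2 dosage; "binary" for carrier coding
    p_g: float = 0.3  # minor allele frequency (ordinal) / carrier frequency (binary)

    def __post_init__(self):
        if not 0 < self.p0 < 1:
            raise ValueError("p0 must lie in (0,1)")
        for name in ("or_g", "or_x", "ror", "confounder_or"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("corr_xz2", "corr_xg"):
            if not abs(getattr(self, name)) < 1:
                raise ValueError(f"|{name}| must be < 1")
        if not 0 < self.rho <= 1:
            raise ValueError("rho must lie in (0,1]")
        if self.misspec not in MISSPEC_VARIANTS:
            raise ValueError(f"unknown misspecification variant {self.misspec!r}")
        if self.genotype_coding not in ("binary", "ordinal"):
            raise ValueError("genotype_coding must be 'binary' or 'ordinal'")
        if not 0 < self.p_g < 1:
            raise ValueError("p_g must lie in (0,1)")

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "ScenarioSpec":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                payload = json.loads(text)
            else:
                with open(text) as fh:
                    payload = json.load(fh)
        return cls(**payload)

    @property
    def var_g(self) -> float:
        if self.genotype_coding == "binary":
            return self.p_g * (1.0 - self.p_g)
        return 2.0 * self.p_g * (1.0 - self.p_g)

    @property
    def var_z2(self) -> float:
        return 0.25  # Bernoulli(0.5)


@dataclass
class ModelParams:
    """Coefficients of the joint logistic/linear generating model."""

    alpha0: float
    alpha1: float
    alpha2: float
    alpha3: float
    alpha_g: float
    alpha_x: float
    alpha_gx: float
    beta0: float
    beta1: float
    beta2: float
    beta3: float
    beta_g: float
    beta_d: float
    beta_gd: float
    sigma2: float = 1.0
    sigma_delta2: float | None = None  # filled when measurement error is injected


def resolve_params(spec: ScenarioSpec) -> ModelParams:
    """Translate table-style scenario knobs into model coefficients.

    The exposure-side slopes come from the stated conditional
    correlations with the conditional variance of X fixed at 1:
    b3 = corr_xz2 * sqrt(1/Var(Z2)), bg = corr_xg * sqrt(1/Var(G)).
    Compatibility pins bd = ax and bgd = agx (sigma^2 = 1).
    """
    alpha_x = np.log(spec.or_x)
    alpha_gx = np.log(spec.ror)
    return ModelParams(
        alpha0=float(logit(spec.p0)),
        alpha1=float(np.log(spec.confounder_or)),
        alpha2=float(np.log(spec.confounder_or)),
        alpha3=float(np.log(spec.confounder_or)),
        alpha_g=float(np.log(spec.or_g)),
        alpha_x=float(alpha_x),
        alpha_gx=float(alpha_gx),
        beta0=0.0,
        beta1=0.03,
        beta2=0.03,
        beta3=float(spec.corr_xz2 * np.sqrt(1.0 / spec.var_z2)),
        beta_g=float(spec.corr_xg * np.sqrt(1.0 / spec.var_g)),
        beta_d=float(alpha_x),
        beta_gd=float(alpha_gx),
        sigma2=1.0,
        sigma_delta2=None,
    )


def _m_of_z(z1, z2, p: ModelParams):
    return p.alpha1 * z1 + p.alpha2 * z1 * z1 + p.alpha3 * z2


def _h_of_z(z1, z2, p: ModelParams):
    return p.beta1 * z1 + p.beta2 * z1 * z1 + p.beta3 * z2


def compatible_disease_logit(g, z1, z2, params: ModelParams) -> np.ndarray:
    """logit Pr(D=1|G,Z) that makes both models hold simultaneously.

    With Delta(G) = bd + bgd*G (the case-control mean shift of X),

        c(G,Z) = a0 + m(Z) + ag*G
                 + Delta(G) * (b0 + h(Z) + bg*G) / sigma^2
                 + Delta(G)^2 / (2 sigma^2)

    Applying Bayes' rule to the normal X|D,G,Z law with this prior logit
    reproduces exactly the prospective logistic model with
    ax = bd/sigma^2, agx = bgd/sigma^2.
    """
    p = params
    g = np.asarray(g, dtype=float)
    delta = p.beta_d + p.beta_gd * g
    mu0 = p.beta0 + _h_of_z(z1, z2, p) + p.beta_g * g
    return (
        p.alpha0
        + _m_of_z(z1, z2, p)
        + p.alpha_g * g
        + delta * mu0 / p.sigma2
        + delta * delta / (2.0 * p.sigma2)
    )


def _draw_covariates(spec: ScenarioSpec, n: int, rng: np.random.Generator):
    z1 = rng.standard_normal(n)
    z2 = (rng.random(n) < 0.5).astype(float)
    if spec.genotype_coding == "binary":
        g = (rng.random(n) < spec.p_g).astype(float)
    else:
        g = rng.binomial(2, spec.p_g, size=n).astype(float)
    return z1, z2, g


def _linear_mean(g, d, z1, z2, p: ModelParams):
    return p.beta0 + _h_of_z(z1, z2, p) + p.beta_g * g + (p.beta_d + p.beta_gd * g) * d


def measurement_error_variance(x: np.ndarray, rho: float) -> float:
    """sigma_delta^2 sized so that Var(X)/Var(X*) = rho for this x."""
    if not 0 < rho <= 1:
        raise ValueError("rho must lie in (0,1]")
    return float(np.var(np.asarray(x, dtype=float)) * (1.0 - rho) / rho)


def add_measurement_error(x: np.ndarray, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Classical additive error X* = X + delta, delta ~ N(0, sigma_delta^2).

    The error variance is sized from the empirical Var(x) so that the
    reliability Var(X)/Var(X*) equals ``rho``; rho = 1 returns x itself.
    """
    x = np.asarray(x, dtype=float)
    s2 = measurement_error_variance(x, rho)
    if s2 == 0.0:
        return x.copy()
    return x + rng.normal(0.0, np.sqrt(s2), size=x.shape[0])


def _rectified_standard_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """max(N(0,1), 0), centred and scaled to mean 0 / variance 1."""
    w = np.maximum(rng.standard_normal(n), 0.0)
    mean = 1.0 / np.sqrt(2.0 * np.pi)
    sd = np.sqrt(0.5 - 1.0 / (2.0 * np.pi))
    return (w - mean) / sd


def _assemble(spec: ScenarioSpec, params: ModelParams, x, d, g, z1, z2, rng) -> GxEDataset:
    x_star = None
    if spec.rho < 1.0:
        s2 = measurement_error_variance(x, spec.rho)
        params.sigma_delta2 = s2
        x_star = x + rng.normal(0.0, np.sqrt(s2), size=x.shape[0])
    return GxEDataset(
        x=x,
        d=d.astype(np.int8),
        g=g,
        covariates=pd.DataFrame({"z1": z1, "z2": z2}),
        x_star=x_star,
    )


def simulate_cohort(
    spec: ScenarioSpec,
    params: ModelParams | None = None,
    n: int | None = None,
    rng: np.random.Generator | None = None,
) -> GxEDataset:
    """Simulate a cohort under the compatible joint model.

    Order: Z1, Z2 -> G -> D | G,Z via :func:`compatible_disease_logit`
    -> X | D,G,Z from the linear model with N(0, sigma^2) error.  When
    ``spec.rho < 1`` an error-prone ``x_star`` is attached.  Fully
    reproducible given the supplied generator.
    """
    if rng is None:
        raise ValueError("a seeded numpy Generator must be supplied")
    if params is None:
        params = resolve_params(spec)
    if spec.misspec != "none":
        return simulate_misspecified(spec, spec.misspec, rng, params=params, n=n)
    n = spec.cohort_n if n is None else int(n)
    z1, z2, g = _draw_covariates(spec, n, rng)
    d = (rng.random(n) < expit(compatible_disease_logit(g, z1, z2, params))).astype(float)
    x = _linear_mean(g, d, z1, z2, params) + np.sqrt(params.sigma2) * rng.standard_normal(n)
    return _assemble(spec, params, x, d, g, z1, z2, rng)


def simulate_misspecified(
    spec: ScenarioSpec,
    variant: str,
    rng: np.random.Generator,
    params: ModelParams | None = None,
    n: int | None = None,
) -> GxEDataset:
    """Generate data where the two models cannot both be correct.

    Scenario I swaps the carefully-matched D|G,Z law for a simple
    logistic one; Scenario II swaps the Gaussian linear-model error for
    a standardized rectified Gaussian (right-skewed).  The ``_linear``
    variants keep the linear exposure model correct (D generated first),
    the ``_logistic`` variants keep the logistic disease model correct
    (X generated first, marginally over D, then D | X,G,Z).
    """
    if variant not in MISSPEC_VARIANTS or variant == "none":
        raise ValueError(f"unknown misspecification variant {variant!r}")
    if params is None:
        params = resolve_params(spec)
    p = params
    n = spec.cohort_n if n is None else int(n)
    z1, z2, g = _draw_covariates(spec, n, rng)

    if variant.endswith("_linear"):
        if variant == "scenario_I_linear":
            eta = p.alpha0 + _m_of_z(z1, z2, p) + p.alpha_g * g
            noise = rng.standard_normal(n)
        else:  # scenario_II_linear: compatible D law, rectified linear error
            eta = compatible_disease_logit(g, z1, z2, p)
            noise = _rectified_standard_noise(n, rng)
        d = (rng.random(n) < expit(eta)).astype(float)
        x = _linear_mean(g, d, z1, z2, p) + np.sqrt(p.sigma2) * noise
    else:  # *_logistic: marginal X, then D from the prospective logistic model
        if variant == "scenario_II_logistic":
            noise = _rectified_standard_noise(n, rng)
        else:
            noise = rng.standard_normal(n)
        x = p.beta0 + _h_of_z(z1, z2, p) + p.beta_g * g + np.sqrt(p.sigma2) * noise
        eta = (
            p.alpha0
            + _m_of_z(z1, z2, p)
            + p.alpha_g * g
            + p.alpha_x * x
            + p.alpha_gx * g * x
        )
        d = (rng.random(n) < expit(eta)).astype(float)

    return _assemble(spec, p, x, d, g, z1, z2, rng)


def sample_case_control(
    cohort: GxEDataset,
    n_cases: int,
    n_controls: int,
    rng: np.random.Generator,
) -> GxEDataset:
    """Frequency-matched case-control subsample (uniform within class)."""
    d = np.asarray(cohort.d)
    case_idx = np.flatnonzero(d == 1)
    ctrl_idx = np.flatnonzero(d == 0)
    if case_idx.size < n_cases or ctrl_idx.size < n_controls:
        raise ValueError(
            f"cohort has {case_idx.size} cases / {ctrl_idx.size} controls; "
            f"requested {n_cases}+{n_controls} — simulate a larger cohort"
        )
    take = np.concatenate(
        [
            rng.choice(case_idx, size=n_cases, replace=False),
            rng.choice(ctrl_idx, size=n_controls, replace=False),
        ]
    )
    return cohort.subset(take)
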