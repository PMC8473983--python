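"""Monte-Carlo harness: empirical size, power and chi-square ratios.

Each replicate mirrors the reference experimental design: simulate a
cohort, draw a 1:1 case-control sample, build both designs with a cubic
B-spline (3 interior knots) on the continuous confounder Z1, fit the
reverse linear model and the logistic model on the same data, and
record both 1-df Wald statistics.  Aggregates are the empirical
rejection rate at each nominal level (type I error under ROR = 1, power
otherwise) and the ratio of mean chi-square statistics
mean(tau_rev^2)/mean(tau_log^2) — a paired relative-efficiency measure;
a ratio above 1 means the reverse test is the more powerful one.

Replicate-level randomness is driven by SeedSequence spawning, so one
integer seed reproduces a whole experiment regardless of chunking, and
replicate failures (separation, collinearity, non-convergence) are
excluded and counted rather than aborting the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    CollinearityError,
    ConvergenceError,
    DegenerateVarianceError,
    SeparationError,
)
from .design import ConfounderSpec, DesignSpec, SplineConfig, build_design
from .logistic_test import fit_logistic, wald_gx
from .reverse_test import fit_ols, wald_gd
from .simulator import ModelParams, ScenarioSpec, resolve_params, sample_case_control, simulate_cohort

__all__ = ["ExperimentResult", "run_experiment", "chi2_ratio_table", "default_design_spec"]

logger = logging.getLogger(__name__)

_REPLICATE_ERRORS = (
    SeparationError,
    CollinearityError,
    ConvergenceError,
    DegenerateVarianceError,
    np.linalg.LinAlgError,
    ValueError,
)


def default_design_spec() -> DesignSpec:
    """Z1 through a cubic B-spline with 3 interior knots, Z2 linear."""
    return DesignSpec(
        confounders=(
            ConfounderSpec("z1", is_continuous=True, spline=SplineConfig(3, "bspline_cubic", "quantile")),
            ConfounderSpec("z2", is_continuous=False),
        )
    )


@dataclass
class ExperimentResult:
    scenario: ScenarioSpec
    n_reps: int
    n_failed: int
    levels: tuple[float, ...]
    stats_reverse: np.ndarray
    stats_logistic: np.ndarray
    p_reverse: np.ndarray
    p_logistic: np.ndarray

    @property
    def n_ok(self) -> int:
        return self.stats_reverse.shape[0]

    @property
    def status(self) -> str:
        return "warning" if self.n_failed > 0.01 * self.n_reps else "ok"

    def rejection_rate(self, test: str, level: float = 0.05) -> float:
        p = self.p_reverse if test == "reverse" else self.p_logistic
        return float(np.mean(p < level))

    @staticmethod
    def mc_band(p: float, n: int) -> tuple[float, float]:
        """Binomial 95% Monte-Carlo band p +- 1.96*sqrt(p(1-p)/B)."""
        half = 1.96 * np.sqrt(p * (1.0 - p) / n)
        return p - half, p + half

    @property
    def mean_chi2_reverse(self) -> float:
        return float(self.stats_reverse.mean())

    @property
    def mean_chi2_logistic(self) -> float:
        return float(self.stats_logistic.mean())

    @property
    def chi2_ratio(self) -> float:
        return self.mean_chi2_reverse / self.mean_chi2_logistic

    def summary_row(self) -> dict:
        s = self.scenario
        row = {
            "p0": s.p0,
            "or_g": s.or_g,
            "or_x": s.or_x,
            "ror": s.ror,
            "corr_xz2": s.corr_xz2,
            "corr_xg": s.corr_xg,
            "rho": s.rho,
            "misspec": s.misspec,
            "n_reps": self.n_reps,
            "n_failed": self.n_failed,
            "mean_chi2_reverse": self.mean_chi2_reverse,
            "mean_chi2_logistic": self.mean_chi2_logistic,
            "chi2_ratio": self.chi2_ratio,
            "status": self.status,
        }
        for lv in self.levels:
            row[f"reject_reverse_{lv:g}"] = self.rejection_rate("reverse", lv)
            row[f"reject_logistic_{lv:g}"] = self.rejection_rate("logistic", lv)
        return row


def _simulate_case_control_fast(spec, params, rng):
    """Cohort + 1:1 case-control draw, generating X only for the sample.

    Distributionally identical to ``simulate_cohort`` followed by
    ``sample_case_control``: X is conditionally iid given (D, G, Z) and
    the case-control selection depends on D alone, so the exposure (and
    its measurement error) need only be realised for the selected
    subjects.  The cohort-level marginal Var(X) used to size the
    measurement error is Var(mu) + sigma^2 over the cohort's linear
    predictors.  Only valid for the compatible model (misspec='none').
    """
    from scipy.special import expit

    from .simulator import compatible_disease_logit

    p = params
    n = spec.cohort_n
    z1 = rng.standard_normal(n)
    z2 = (rng.random(n) < 0.5).astype(float)
    if spec.genotype_coding == "binary":
        g = (rng.random(n) < spec.p_g).astype(float)
    else:
        g = rng.binomial(2, spec.p_g, size=n).astype(float)
    dvec = rng.random(n) < expit(compatible_disease_logit(g, z1, z2, p))

    case_idx = np.flatnonzero(dvec)
    ctrl_idx = np.flatnonzero(~dvec)
    if case_idx.size < spec.n_cases or ctrl_idx.size < spec.n_controls:
        raise ValueError(
            f"cohort has {case_idx.size} cases / {ctrl_idx.size} controls; "
            f"requested {spec.n_cases}+{spec.n_controls}"
        )
    idx = np.concatenate(
        [
            rng.choice(case_idx, size=spec.n_cases, replace=False),
            rng.choice(ctrl_idx, size=spec.n_controls, replace=False),
        ]
    )

    g_s, z1_s, z2_s = g[idx], z1[idx], z2[idx]
    d_s = dvec[idx].astype(float)
    mu_s = (
        p.beta0
        + p.beta1 * z1_s
        + p.beta2 * z1_s * z1_s
        + p.beta3 * z2_s
        + p.beta_g * g_s
        + (p.beta_d + p.beta_gd * g_s) * d_s
    )
    m = idx.shape[0]
    x_s = mu_s + np.sqrt(p.sigma2) * rng.standard_normal(m)
    x_star = None
    if spec.rho < 1.0:
        mu_full = (
            p.beta0
            + p.beta1 * z1
            + p.beta2 * z1 * z1
            + p.beta3 * z2
            + p.beta_g * g
            + (p.beta_d + p.beta_gd * g) * dvec
        )
        var_x = float(mu_full.var() + p.sigma2)
        s2 = var_x * (1.0 - spec.rho) / spec.rho
        x_star = x_s + rng.normal(0.0, np.sqrt(s2), size=m)

    from .datatypes import GxEDataset

    return GxEDataset(
        x=x_s,
        d=d_s.astype(np.int8),
        g=g_s,
        covariates=pd.DataFrame({"z1": z1_s, "z2": z2_s}),
        x_star=x_star,
    )


def _one_replicate(spec, params, rev_spec, log_spec, rng, variance):
    if spec.misspec == "none":
        cc = _simulate_case_control_fast(spec, params, rng)
    else:
        cohort = simulate_cohort(spec, params=params, rng=rng)
        cc = sample_case_control(cohort, spec.n_cases, spec.n_controls, rng)
    y = cc.analysis_exposure

    rev_design = build_design(cc, rev_spec, "reverse")
    rev_fit = fit_ols(rev_design, y)
    rev = wald_gd(rev_fit, rev_design, variance=variance)

    log_design = build_design(cc, log_spec, "logistic")
    log_fit = fit_logistic(log_design, cc.d)
    logi = wald_gx(log_fit, log_design)
    return rev, logi


def run_experiment(
    spec: ScenarioSpec,
    n_reps: int,
    levels=(0.05,),
    seed: int | np.random.SeedSequence = 0,
    variance: str = "model",
    progress_every: int = 500,
) -> ExperimentResult:
    """Run ``n_reps`` paired replicates of the two tests under ``spec``."""
    if n_reps < 100:
        raise ValueError("n_reps must be at least 100")
    params = resolve_params(spec)
    rev_spec = default_design_spec()
    log_spec = default_design_spec()

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_reps)

    stats_rev, stats_log, p_rev, p_log = [], [], [], []
    n_failed = 0
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        try:
            rev, logi = _one_replicate(spec, params, rev_spec, log_spec, rng, variance)
        except _REPLICATE_ERRORS as exc:  # noqa: PERF203 - rare path
            n_failed += 1
            logger.debug("replicate %d failed: %s", i, exc)
            continue
        stats_rev.append(rev.stat)
        stats_log.append(logi.stat)
        p_rev.append(rev.p_value)
        p_log.append(logi.p_value)
        if progress_every and (i + 1) % progress_every == 0:
            logger.info("replicate %d/%d done", i + 1, n_reps)

    if n_failed > 0.01 * n_reps:
        logger.warning("%d/%d replicates failed (> 1%%)", n_failed, n_reps)
    return ExperimentResult(
        scenario=spec,
        n_reps=n_reps,
        n_failed=n_failed,
        levels=tuple(levels),
        stats_reverse=np.asarray(stats_rev),
        stats_logistic=np.asarray(stats_log),
        p_reverse=np.asarray(p_rev),
        p_logistic=np.asarray(p_log),
    )


def chi2_ratio_table(
    specs,
    n_reps: int,
    seed: int = 0,
    levels=(0.05,),
) -> pd.DataFrame:
    """One :func:`run_experiment` per scenario, summarised as a table.

    Deterministic for a fixed (seed, grid): each cell gets its own
    spawned seed stream, so the table is reproducible cell-by-cell.
    """
    specs = list(specs)
    if not specs:
        raise ValueError("scenario grid is empty")
    root = np.random.SeedSequence(seed)
    streams = root.spawn(len(specs))
    rows = []
    for spec, stream in zip(specs, streams):
        res = run_experiment(spec, n_reps, levels=levels, seed=stream)
        rows.append(res.summary_row())
    return pd.DataFrame(rows)
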