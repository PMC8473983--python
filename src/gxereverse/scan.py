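"""Genome-wide per-variant GxE scan.

For every variant passing MAF / call-rate filters, the scan fits the
reverse and/or logistic interaction model with the requested confounder
adjustment and reports the interaction coefficient, the 1-df Wald
statistic and its p-value.  The confounder block of the design (spline
bases, Z*D / Z*X products) does not depend on the variant, so it is
built once and only the genotype-dependent columns are rewritten per
variant — the engineering that makes the closed-form reverse test pay
off at genome scale.

Calibration of a scan is summarised by the genomic inflation factor
lambda (median observed chi-square over the chi-square(1) median); a
well-calibrated null scan has lambda close to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GxEDataset
from .design import DesignMatrix, DesignSpec, assemble_design, build_spline_basis, spline_knots
from .logistic_test import fit_logistic, wald_gx
from .reverse_test import fit_ols, wald_gd

__all__ = [
    "VariantRecord",
    "read_vcf",
    "read_dosage_matrix",
    "filter_variants",
    "run_scan",
    "genomic_inflation",
    "qq_points",
    "GENOME_WIDE_P",
    "SUGGESTIVE_P",
]

GENOME_WIDE_P = 5e-8
SUGGESTIVE_P = 1e-5

CHI2_1_MEDIAN = stats.chi2.ppf(0.5, 1)  # 0.4549...


@dataclass
class VariantRecord:
    """One variant with per-subject dosages (VCF coordinate conventions).

    ``dosage`` holds 0..2 allele dosages (fractional allowed for imputed
    data) with NaN for missing calls; ``maf`` is computed on the minor
    allele of this sample set and ``call_rate`` is the non-missing
    fraction.
    """

    chrom: str
    pos: int
    id: str
    ref: str
    alt: str
    dosage: np.ndarray
    maf: float = float("nan")
    call_rate: float = float("nan")

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        if np.isnan(self.maf) or np.isnan(self.call_rate):
            ok = np.isfinite(self.dosage)
            self.call_rate = float(ok.mean()) if self.dosage.size else 0.0
            if ok.any():
                af = float(self.dosage[ok].mean() / 2.0)
                self.maf = min(af, 1.0 - af)
            else:
                self.maf = 0.0


def read_vcf(path) -> list[VariantRecord]:
    """Read variants from a VCF (optionally bgzipped) via cyvcf2.

    Dosages come from the DS FORMAT field when present, otherwise from
    hard genotype calls (count of ALT alleles, missing -> NaN).
    """
    from cyvcf2 import VCF

    records = []
    vcf = VCF(str(path))
    try:
        for v in vcf:
            ds = None
            try:
                arr = v.format("DS")
                if arr is not None:
                    ds = np.asarray(arr, dtype=float).reshape(-1)
            except KeyError:
                ds = None
            if ds is None:
                codes = np.asarray(v.gt_types)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
                ds = np.choose(codes, [0.0, 1.0, np.nan, 2.0])
            records.append(
                VariantRecord(
                    chrom=str(v.CHROM),
                    pos=int(v.POS),
                    id=v.ID or f"{v.CHROM}:{v.POS}",
                    ref=v.REF,
                    alt=v.ALT[0] if v.ALT else ".",
                    dosage=ds,
                )
            )
    finally:
        vcf.close()
    return records


def read_dosage_matrix(path, sep: str = "\t") -> list[VariantRecord]:
    """Read a subjects x variants dosage TSV (header = variant ids)."""
    frame = pd.read_csv(path, sep=sep)
    return [
        VariantRecord(chrom=".", pos=0, id=str(col), ref=".", alt=".", dosage=frame[col].to_numpy(float))
        for col in frame.columns
    ]


def filter_variants(records, maf_min: float = 0.01, call_rate_min: float = 0.95):
    """Keep variants with maf > maf_min and call_rate > call_rate_min (strict)."""
    return [r for r in records if r.maf > maf_min and r.call_rate > call_rate_min]


def _precompute_blocks(dataset: GxEDataset, spec: DesignSpec):
    """Confounder bases with knots frozen on the full subject set."""
    bases, raw = [], []
    for c in spec.confounders:
        z = dataset.covariates[c.name].to_numpy(float)
        raw.append((c.name, z))
        if c.is_continuous and c.spline is not None:
            knots = spline_knots(z, c.spline)
            bases.append((c.name, build_spline_basis(z, c.spline, knots=knots)))
        else:
            bases.append((c.name, z[:, None]))
    return bases, raw


def run_scan(
    variants,
    dataset: GxEDataset,
    spec: DesignSpec,
    tests: str = "both",
    variance: str = "model",
    missing: str = "complete_case",
    maf_min: float | None = None,
    call_rate_min: float | None = None,
) -> pd.DataFrame:
    """Per-variant interaction tests over a panel.

    ``missing='complete_case'`` drops subjects missing that variant's
    dosage (n_used records how many remain); ``missing='mean'`` imputes
    the variant mean instead.  Per-variant failures become NA rows with
    a reason code; the scan never aborts.  Output columns follow the
    TSV contract: chrom, pos, id, ref, alt, maf, call_rate, test,
    beta_gd, stat, p, n_used, flag.
    """
    if tests not in ("reverse", "logistic", "both"):
        raise ValueError("tests must be 'reverse', 'logistic' or 'both'")
    if missing not in ("complete_case", "mean"):
        raise ValueError("missing must be 'complete_case' or 'mean'")
    if maf_min is not None or call_rate_min is not None:
        variants = filter_variants(
            variants,
            maf_min=0.01 if maf_min is None else maf_min,
            call_rate_min=0.95 if call_rate_min is None else call_rate_min,
        )

    wanted = ("reverse", "logistic") if tests == "both" else (tests,)
    bases, raw = _precompute_blocks(dataset, spec)
    d = np.asarray(dataset.d, dtype=float)
    y = dataset.analysis_exposure
    n = dataset.n

    rows = []
    for rec in variants:
        g = rec.dosage
        if g.shape[0] != n:
            raise ValueError(f"variant {rec.id}: dosage length {g.shape[0]} != n subjects {n}")
        ok = np.isfinite(g)
        if missing == "mean" and not ok.all():
            g = np.where(ok, g, g[ok].mean())
            ok = np.ones(n, dtype=bool)
        full = ok.all()

        for test in wanted:
            row = {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "id": rec.id,
                "ref": rec.ref,
                "alt": rec.alt,
                "maf": rec.maf,
                "call_rate": rec.call_rate,
                "test": test,
                "beta_gd": np.nan,
                "stat": np.nan,
                "p": np.nan,
                "n_used": int(ok.sum()),
                "flag": "",
            }
            try:
                if full:
                    b_use, r_use, g_use, d_use, y_use = bases, raw, g, d, y
                else:
                    b_use = [(name, mat[ok]) for name, mat in bases]
                    r_use = [(name, z[ok]) for name, z in raw]
                    g_use, d_use, y_use = g[ok], d[ok], y[ok]
                if test == "reverse":
                    dm = assemble_design(
                        model_role="reverse", spec=spec, bases=b_use, raw=r_use,
                        g=g_use, d=d_use, x=None, n=g_use.shape[0],
                    )
                    fit = fit_ols(dm, y_use)
                    res = wald_gd(fit, dm, variance=variance)
                    row["beta_gd"] = float(fit.coef[dm.gd_index])
                else:
                    dm = assemble_design(
                        model_role="logistic", spec=spec, bases=b_use, raw=r_use,
                        g=g_use, d=d_use, x=y_use, n=g_use.shape[0],
                    )
                    fit = fit_logistic(dm, d_use)
                    res = wald_gx(fit, dm)
                    row["beta_gd"] = float(fit.coef[dm.gx_index])
                row["stat"] = res.stat
                row["p"] = res.p_value
                if res.p_value < GENOME_WIDE_P:
                    row["flag"] = "genome_wide"
                elif res.p_value < SUGGESTIVE_P:
                    row["flag"] = "suggestive"
            except Exception as exc:  # per-variant failure -> NA row
                row["flag"] = f"failed:{type(exc).__name__}"
            rows.append(row)
    return pd.DataFrame(rows)


def genomic_inflation(p_values) -> float:
    """lambda = median(qchisq(1 - p, 1)) / qchisq(0.5, 1)."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size < 100:
        raise ValueError(f"need at least 100 p-values to estimate lambda, got {p.size}")
    chi2_obs = stats.chi2.isf(p, 1)
    return float(np.median(chi2_obs) / CHI2_1_MEDIAN)


def qq_points(p_values) -> pd.DataFrame:
    """Numeric QQ-plot export: expected vs observed -log10 p, sorted."""
    p = np.sort(np.asarray(p_values, dtype=float))
    p = p[np.isfinite(p)]
    m = p.size
    expected = (np.arange(1, m + 1) - 0.5) / m
    return pd.DataFrame(
        {"expected_neglog10": -np.log10(expected), "observed_neglog10": -np.log10(p)}
    )
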