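"""Shared containers and error types for the GxE testing toolkit.

The subject-level container :class:`GxEDataset` holds the continuous
exposure ``x`` (optionally an error-prone measurement ``x_star``), the
binary outcome ``d``, the genotype ``g`` (0/1 carrier coding or 0..2
dosage) and a named table of confounders.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GxEDataset",
    "DegenerateInputError",
    "CollinearityError",
    "SeparationError",
    "ConvergenceError",
    "DegenerateVarianceError",
    "InfeasibleErrorVarianceError",
]


class DegenerateInputError(ValueError):
    """Input has too little variation to support the requested operation."""


class CollinearityError(np.linalg.LinAlgError):
    """Design matrix is rank deficient; carries the offending column name."""

    def __init__(self, message: str, column: str | None = None):
        super().__init__(message)
        self.column = column


class SeparationError(RuntimeError):
    """(Quasi-)complete separation detected in a logistic fit."""


class ConvergenceError(RuntimeError):
    """Iterative fit failed to converge; carries the log-likelihood trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = list(trace) if trace is not None else []


class DegenerateVarianceError(ValueError):
    """A variance required by a test statistic is estimated as zero."""


class InfeasibleErrorVarianceError(ValueError):
    """Assumed measurement-error variance is not smaller than Var(X*)."""


@dataclass
class GxEDataset:
    """Subject-level data for one gene-environment analysis.

    Parameters
    ----------
    x : array
        Continuous exposure (the response of the reverse linear model).
    d : array
        Binary disease status coded 0/1.
    g : array
        Genotype: 0/1 (carrier) or 0/1/2 dosage; may contain fractional
        imputed dosages when used by the scan module.
    covariates : pandas.DataFrame or None
        Confounders by name; columns may be continuous or binary.
    x_star : array or None
        Error-prone exposure measurement, present when classical additive
        measurement error has been injected or observed.
    """

    x: np.ndarray
    d: np.ndarray
    g: np.ndarray
    covariates: pd.DataFrame | None = None
    x_star: np.ndarray | None = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.d = np.asarray(self.d)
        self.g = np.asarray(self.g, dtype=float)
        if self.x_star is not None:
            self.x_star = np.asarray(self.x_star, dtype=float)
        n = self.x.shape[0]
        for name, arr in (("d", self.d), ("g", self.g)):
            if arr.shape[0] != n:
                raise ValueError(f"length of {name} ({arr.shape[0]}) != length of x ({n})")
        if self.x_star is not None and self.x_star.shape[0] != n:
            raise ValueError("length of x_star differs from x")
        if self.covariates is not None and len(self.covariates) != n:
            raise ValueError("covariate table length differs from x")

    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def analysis_exposure(self) -> np.ndarray:
        """The exposure actually analysed: x_star when present, else x."""
        return self.x_star if self.x_star is not None else self.x

    def subset(self, idx) -> "GxEDataset":
        """Row-subset by boolean mask or integer index array."""
        idx = np.asarray(idx)
        return GxEDataset(
            x=self.x[idx],
            d=self.d[idx],
            g=self.g[idx],
            covariates=None if self.covariates is None else self.covariates.iloc[idx].reset_index(drop=True),
            x_star=None if self.x_star is None else self.x_star[idx],
        )

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        exposure: str,
        outcome: str,
        genotype: str | None = None,
        confounders: tuple[str, ...] = (),
        exposure_star: str | None = None,
    ) -> "GxEDataset":
        """Build from a tabular file already read into a DataFrame.

        ``genotype`` may be None for scan workflows where per-variant
        dosages are supplied separately; a zero vector is used as a
        placeholder in that case.
        """
        g = frame[genotype].to_numpy(float) if genotype else np.zeros(len(frame))
        return cls(
            x=frame[exposure].to_numpy(float),
            d=frame[outcome].to_numpy(),
            g=g,
            covariates=frame.loc[:, list(confounders)].copy() if confounders else None,
            x_star=frame[exposure_star].to_numpy(float) if exposure_star else None,
        )

    def with_genotype(self, g: np.ndarray) -> "GxEDataset":
        return replace(self, g=np.asarray(g, dtype=float))
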