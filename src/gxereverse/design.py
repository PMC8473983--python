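"""Design-matrix construction for the reverse and logistic GxE models.

Both models share the confounder-adjustment machinery: each continuous
confounder Z_j can enter through a spline basis (cubic B-spline or
restricted cubic spline), and optional confounder-by-gene (ZG),
confounder-by-disease (ZD, reverse model) or confounder-by-exposure
(ZX, logistic model) product terms can be added for robustness.

Column layout (fixed order):

* reverse role:  ``[1, h-basis(Z), ZD, ZG, G, (G^2), D, GD]``
* logistic role: ``[1, m-basis(Z), ZX, ZG, G, X, GX]``

The trailing interaction column (GD or GX) is the term of scientific
interest; its index is exposed as ``gd_index`` / ``gx_index``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

from .datatypes import CollinearityError, DegenerateInputError, GxEDataset

__all__ = [
    "SplineConfig",
    "ConfounderSpec",
    "DesignSpec",
    "DesignMatrix",
    "spline_knots",
    "build_spline_basis",
    "build_design",
]


@dataclass(frozen=True)
class SplineConfig:
    """Spline basis settings for one continuous confounder.

    ``n_interior_knots`` counts the knots strictly between the boundary
    knots.  For ``restricted_cubic`` the conventional total knot count is
    M = n_interior_knots + 2 (boundaries included); M = 2 degenerates to
    a single linear column.  ``bspline_cubic`` with k interior knots
    yields k + 3 basis columns (the intercept column is dropped).
    """

    n_interior_knots: int = 3
    kind: str = "bspline_cubic"  # or "restricted_cubic"
    knot_placement: str = "quantile"  # or "uniform"

    def __post_init__(self):
        if self.n_interior_knots < 0:
            raise ValueError("n_interior_knots must be >= 0")
        if self.kind not in ("bspline_cubic", "restricted_cubic"):
            raise ValueError(f"unknown spline kind {self.kind!r}")
        if self.knot_placement not in ("quantile", "uniform"):
            raise ValueError(f"unknown knot placement {self.knot_placement!r}")

    @property
    def n_columns(self) -> int:
        if self.kind == "bspline_cubic":
            return self.n_interior_knots + 3
        # restricted cubic with M total knots -> M - 1 columns
        return self.n_interior_knots + 1


@dataclass(frozen=True)
class ConfounderSpec:
    name: str
    is_continuous: bool = True
    spline: SplineConfig | None = None

    @property
    def n_columns(self) -> int:
        if self.spline is not None and self.is_continuous:
            return self.spline.n_columns
        return 1


@dataclass(frozen=True)
class DesignSpec:
    """Which confounders and interaction blocks enter the design.

    ``include_zd_interactions`` applies only when building the reverse
    model and ``include_zx_interactions`` only when building the
    logistic model: the two blocks are mutually exclusive *within* any
    one model role, so a single spec can carry both flags and drive both
    models (each role picks up only its own block).
    """

    confounders: tuple[ConfounderSpec, ...] = ()
    include_zg_interactions: bool = False
    include_zd_interactions: bool = False
    include_zx_interactions: bool = False
    genotype_coding: str = "binary"  # or "ordinal"

    def __post_init__(self):
        if self.genotype_coding not in ("binary", "ordinal"):
            raise ValueError(f"unknown genotype coding {self.genotype_coding!r}")

    @property
    def includes_g_squared(self) -> bool:
        # G^2 enters only for ordinal dosages under ZG adjustment
        return self.genotype_coding == "ordinal" and self.include_zg_interactions


@dataclass
class DesignMatrix:
    values: np.ndarray
    column_map: dict[str, int]
    gd_index: int | None = None
    gx_index: int | None = None

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def columns(self) -> list[str]:
        inv = {v: k for k, v in self.column_map.items()}
        return [inv[i] for i in range(self.p)]


def spline_knots(z: np.ndarray, cfg: SplineConfig) -> tuple[float, np.ndarray, float]:
    """Choose (lower boundary, interior knots, upper boundary) for ``z``.

    Quantile placement puts the k interior knots at evenly spaced
    percentiles (i/(k+1), i = 1..k); uniform placement spaces them evenly
    between min and max.  Boundary knots sit at the observed min/max.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise DegenerateInputError("spline input contains non-finite values")
    lo, hi = float(z.min()), float(z.max())
    k = cfg.n_interior_knots
    n_distinct = np.unique(z).size
    if hi <= lo or n_distinct < k + 2:
        raise DegenerateInputError(
            f"need at least {k + 2} distinct values spanning an interval to "
            f"place {k} interior knots; got {n_distinct} distinct values"
        )
    if k == 0:
        interior = np.empty(0)
    elif cfg.knot_placement == "quantile":
        qs = np.arange(1, k + 1) / (k + 1)
        interior = np.quantile(z, qs)
    else:
        interior = lo + (hi - lo) * np.arange(1, k + 1) / (k + 1)
    if np.unique(np.concatenate(([lo], interior, [hi]))).size != k + 2:
        raise DegenerateInputError("tied knots: data too discrete for requested spline")
    return lo, interior, hi


def build_spline_basis(
    z: np.ndarray,
    cfg: SplineConfig,
    knots: tuple[float, np.ndarray, float] | None = None,
) -> np.ndarray:
    """Spline basis for one confounder; n x q with q = ``cfg.n_columns``.

    ``knots`` allows the basis to be frozen at fit time and re-evaluated
    on new data (e.g. a subsample of the vector the knots came from).
    The basis never contains its own intercept column: the cubic B-spline
    system of k+4 functions is a partition of unity, so its first column
    is dropped; the restricted cubic basis starts with the linear term.
    """
    z = np.asarray(z, dtype=float)
    if knots is None:
        knots = spline_knots(z, cfg)
    lo, interior, hi = knots
    interior = np.asarray(interior, dtype=float)

    if cfg.kind == "bspline_cubic":
        t = np.concatenate(([lo] * 4, interior, [hi] * 4))
        zc = np.clip(z, lo, hi)  # frozen basis: clamp points outside training range
        full = BSpline.design_matrix(zc, t, k=3).toarray()
        return full[:, 1:]

    # restricted (natural) cubic spline, Harrell parameterisation
    t = np.concatenate(([lo], interior, [hi]))
    m = t.size
    if m == 2:
        return z[:, None].copy()
    cols = [z]
    denom = (t[-1] - t[0]) ** 2
    for j in range(m - 2):
        cub = (
            np.maximum(z - t[j], 0) ** 3
            - np.maximum(z - t[-2], 0) ** 3 * (t[-1] - t[j]) / (t[-1] - t[-2])
            + np.maximum(z - t[-1], 0) ** 3 * (t[-2] - t[j]) / (t[-1] - t[-2])
        )
        cols.append(cub / denom)
    return np.column_stack(cols)


def _confounder_blocks(dataset: GxEDataset, spec: DesignSpec):
    """Per-confounder basis matrices plus the raw confounder columns."""
    bases: list[tuple[str, np.ndarray]] = []
    raw: list[tuple[str, np.ndarray]] = []
    for c in spec.confounders:
        if dataset.covariates is None or c.name not in dataset.covariates.columns:
            raise KeyError(f"confounder {c.name!r} not found in dataset covariates")
        z = dataset.covariates[c.name].to_numpy(float)
        raw.append((c.name, z))
        if c.is_continuous and c.spline is not None:
            basis = build_spline_basis(z, c.spline)
            bases.append((c.name, basis))
        else:
            bases.append((c.name, z[:, None]))
    return bases, raw


def assemble_design(
    *,
    model_role: str,
    spec: DesignSpec,
    bases: list[tuple[str, np.ndarray]],
    raw: list[tuple[str, np.ndarray]],
    g: np.ndarray,
    d: np.ndarray,
    x: np.ndarray | None,
    n: int,
    check_rank: bool = True,
) -> DesignMatrix:
    """Assemble the final design from precomputed confounder blocks.

    Shared by :func:`build_design` and the per-variant fast path of the
    scan module, so that the two can never drift apart.
    """
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]

    for name, basis in bases:
        q = basis.shape[1]
        cols.extend(basis.T)
        if q == 1:
            names.append(name)
        else:
            names.extend(f"{name}:s{j + 1}" for j in range(q))

    if model_role == "reverse" and spec.include_zd_interactions:
        for name, z in raw:
            cols.append(z * d)
            names.append(f"{name}:D")
    if model_role == "logistic" and spec.include_zx_interactions:
        if x is None:
            raise ValueError("logistic role with ZX interactions requires the exposure")
        for name, z in raw:
            cols.append(z * x)
            names.append(f"{name}:X")
    if spec.include_zg_interactions:
        for name, z in raw:
            cols.append(z * g)
            names.append(f"{name}:G")

    cols.append(g)
    names.append("G")
    if spec.includes_g_squared:
        cols.append(g**2)
        names.append("G2")

    interest: int
    if model_role == "reverse":
        cols.append(np.asarray(d, dtype=float))
        names.append("D")
        cols.append(g * d)
        names.append("GD")
    elif model_role == "logistic":
        if x is None:
            raise ValueError("logistic role requires the exposure as a covariate")
        cols.append(x)
        names.append("X")
        cols.append(g * x)
        names.append("GX")
    else:
        raise ValueError(f"unknown model role {model_role!r}")

    values = np.column_stack(cols)
    if check_rank:
        _check_degenerate_columns(values, names)
    column_map = {name: i for i, name in enumerate(names)}
    dm = DesignMatrix(values=values, column_map=column_map)
    if model_role == "reverse":
        dm.gd_index = column_map["GD"]
    else:
        dm.gx_index = column_map["GX"]
    return dm


def _check_degenerate_columns(values: np.ndarray, names: list[str]) -> None:
    # cheap screen: any constant non-intercept column makes the design singular
    spread = values[:, 1:].max(axis=0) - values[:, 1:].min(axis=0)
    flat = np.nonzero(spread == 0.0)[0]
    if flat.size:
        col = names[1 + flat[0]]
        raise CollinearityError(
            f"design column {col!r} is constant; the design is rank deficient", column=col
        )


def build_design(dataset: GxEDataset, spec: DesignSpec, model_role: str) -> DesignMatrix:
    """Build the full design for one model role.

    ``model_role='reverse'`` produces the regressors of the linear
    exposure model (response = exposure, not included here);
    ``model_role='logistic'`` produces the regressors of the disease
    model (outcome = D, not included here), with the analysed exposure
    (x_star when present) as a covariate.
    """
    d = np.asarray(dataset.d)
    if not np.isin(np.unique(d), (0, 1)).all():
        raise ValueError("disease status D must be coded 0/1")
    bases, raw = _confounder_blocks(dataset, spec)
    x = dataset.analysis_exposure if model_role == "logistic" else None
    return assemble_design(
        model_role=model_role,
        spec=spec,
        bases=bases,
        raw=raw,
        g=dataset.g,
        d=d.astype(float),
        x=x,
        n=dataset.n,
    )
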