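"""QSPR statistics: simple linear regression of properties on indices.

The model is P = A + b * TI for each (topological index, physicochemical
property) pair, fit by ordinary least squares on n molecules:

    b = cov(TI, P) / var(TI),      A = mean(P) - b * mean(TI)

with Pearson r, R^2 = r^2, Fisher's F = R^2 (n-2) / (1 - R^2) on (1, n-2)
degrees of freedom, its upper-tail p-value, and the standard error of
estimate SEE = sqrt(RSS / (n-2)).  A fit is flagged significant at p < 0.05;
no multiple-testing correction is applied (each model is reported as its own
univariate screen, matching standard QSPR practice for small panels).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .topo_indices import INDEX_FIELDS, compute_index_set

__all__ = [
    "PROPERTY_FIELDS",
    "PropertyRecord",
    "RegressionFit",
    "QsprReport",
    "DegenerateFitError",
    "pearson_correlation",
    "fit_simple_regression",
    "f_upper_tail_p",
    "build_qspr_report",
    "SIGNIFICANCE_LEVEL",
]

SIGNIFICANCE_LEVEL = 0.05

#: Property column order used by every table in this package.
PROPERTY_FIELDS = (
    "boiling_point", "melting_point", "enthalpy", "flash_point",
    "molar_refractivity", "polarizability", "surface_tension", "molar_volume",
)

#: Units, for report headers and documentation.
PROPERTY_UNITS = {
    "boiling_point": "degC",
    "melting_point": "degC",
    "enthalpy": "kJ/mol",
    "flash_point": "degC",
    "molar_refractivity": "cm^3",
    "polarizability": "1e-24 cm^3",
    "surface_tension": "dyne/cm",
    "molar_volume": "cm^3",
}


class DegenerateFitError(ValueError):
    """Raised when a correlation or regression is undefined (zero variance)."""


@dataclass(frozen=True)
class PropertyRecord:
    """The eight physicochemical properties of one molecule."""

    boiling_point: float
    melting_point: float
    enthalpy: float
    flash_point: float
    molar_refractivity: float
    polarizability: float
    surface_tension: float
    molar_volume: float

    def __post_init__(self) -> None:
        for f in PROPERTY_FIELDS:
            v = getattr(self, f)
            if not math.isfinite(v):
                raise ValueError(f"property {f} is not finite: {v!r}")

    def __getitem__(self, key: str) -> float:
        if key not in PROPERTY_FIELDS:
            raise KeyError(key)
        return getattr(self, key)


@dataclass(frozen=True)
class RegressionFit:
    """One fitted model P = A + b * TI with its diagnostics."""

    n: int
    intercept_A: float
    slope_b: float
    pearson_r: float
    r_squared: float
    f_stat: float
    p_value: float
    see: float

    @property
    def significant(self) -> bool:
        return self.p_value < SIGNIFICANCE_LEVEL

    def predict(self, ti) -> np.ndarray:
        return self.intercept_A + self.slope_b * np.asarray(ti, dtype=float)


def _as_arrays(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.ndim != 1 or ya.ndim != 1 or len(xa) != len(ya):
        raise ValueError("x and y must be equal-length 1-D sequences")
    if len(xa) < 3:
        raise ValueError(f"need at least 3 observations, got {len(xa)}")
    return xa, ya


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson product-moment correlation coefficient."""
    xa, ya = _as_arrays(x, y)
    dx = xa - xa.mean()
    dy = ya - ya.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0.0 or syy == 0.0:
        raise DegenerateFitError("correlation undefined: zero variance")
    return float(dx @ dy) / math.sqrt(sxx * syy)


def f_upper_tail_p(f: float, df1: int, df2: int) -> float:
    """P(F_{df1,df2} > f): upper tail of the F distribution."""
    if f < 0:
        raise ValueError(f"F statistic must be non-negative, got {f}")
    return float(_sps.f.sf(f, df1, df2))


def fit_simple_regression(ti: Sequence[float], p: Sequence[float]) -> RegressionFit:
    """Ordinary least squares fit of P = A + b * TI with full diagnostics."""
    x, y = _as_arrays(ti, p)
    n = len(x)
    dx = x - x.mean()
    sxx = float(dx @ dx)
    if sxx == 0.0:
        raise DegenerateFitError("degenerate fit: index has zero variance")
    b = float(dx @ (y - y.mean())) / sxx
    a = float(y.mean() - b * x.mean())
    resid = y - (a + b * x)
    rss = float(resid @ resid)
    syy = float((y - y.mean()) @ (y - y.mean()))
    if syy == 0.0:
        # a constant response is fit exactly by the horizontal line
        r = 0.0
        r2 = 0.0
    else:
        r = pearson_correlation(x, y)
        r2 = r * r
    if r2 >= 1.0:
        fstat = math.inf
        pval = 0.0
    else:
        fstat = r2 * (n - 2) / (1.0 - r2)
        pval = f_upper_tail_p(fstat, 1, n - 2)
    see = math.sqrt(rss / (n - 2))
    return RegressionFit(
        n=n, intercept_A=a, slope_b=b, pearson_r=r, r_squared=r2,
        f_stat=fstat, p_value=pval, see=see,
    )


@dataclass
class QsprReport:
    """All 40 (index, property) fits plus the derived summary grids.

    ``correlation_table`` and ``see_table`` are index-by-property DataFrames;
    ``fits`` maps (index_name, property_name) to a RegressionFit, and
    ``errors`` records any cell whose fit failed (the rest of the report is
    still produced).
    """

    n_molecules: int
    correlation_table: pd.DataFrame
    see_table: pd.DataFrame
    fits: dict[tuple[str, str], RegressionFit]
    errors: dict[tuple[str, str], str]
    index_source: str
    warnings: list[str]

    def fit(self, index_name: str, property_name: str) -> RegressionFit:
        return self.fits[(index_name, property_name)]


def build_qspr_report(
    fixtures: Sequence,
    index_source: str = "table",
    indices: Optional[dict] = None,
) -> QsprReport:
    """Fit all 40 QSPR models over a set of drug fixtures.

    Parameters
    ----------
    fixtures:
        Objects with ``name``, ``properties`` and either ``expected_indices``
        (for ``index_source="table"``) or ``to_graph()`` (for ``"computed"``).
    index_source:
        ``"table"`` regresses on the shipped published index values — the
        route that reproduces the published regression tables, since those
        were themselves computed from the published index table.
        ``"computed"`` recomputes every index from the structure first.
    indices:
        Optional pre-computed {name: IndexSet}, overriding both sources.
    """
    if len(fixtures) < 3:
        raise ValueError(f"need at least 3 molecules, got {len(fixtures)}")
    if index_source not in ("table", "computed"):
        raise ValueError(f"unknown index_source {index_source!r}")

    warnings: list[str] = []
    if len(fixtures) < 8:
        warnings.append(
            f"only n={len(fixtures)} molecules: fits have low power and "
            f"diagnostics are fragile"
        )

    index_sets = {}
    for fx in fixtures:
        if indices is not None:
            index_sets[fx.name] = indices[fx.name]
        elif index_source == "table":
            if fx.expected_indices is None:
                raise ValueError(f"{fx.name}: no tabulated indices available")
            index_sets[fx.name] = fx.expected_indices
        else:
            index_sets[fx.name] = compute_index_set(fx.to_graph())

    names = [fx.name for fx in fixtures]
    prop_vectors = {
        p: np.array([fx.properties[p] for fx in fixtures], dtype=float)
        for p in PROPERTY_FIELDS
    }
    ti_vectors = {
        i: np.array([index_sets[nm][i] for nm in names], dtype=float)
        for i in INDEX_FIELDS
    }

    corr = pd.DataFrame(index=list(INDEX_FIELDS), columns=list(PROPERTY_FIELDS), dtype=float)
    see = pd.DataFrame(index=list(INDEX_FIELDS), columns=list(PROPERTY_FIELDS), dtype=float)
    fits: dict[tuple[str, str], RegressionFit] = {}
    errors: dict[tuple[str, str], str] = {}
    for iname in INDEX_FIELDS:
        for pname in PROPERTY_FIELDS:
            try:
                fit = fit_simple_regression(ti_vectors[iname], prop_vectors[pname])
            except (DegenerateFitError, ValueError) as exc:
                errors[(iname, pname)] = str(exc)
                continue
            fits[(iname, pname)] = fit
            corr.loc[iname, pname] = fit.pearson_r
            see.loc[iname, pname] = fit.see

    return QsprReport(
        n_molecules=len(fixtures),
        correlation_table=corr,
        see_table=see,
        fits=fits,
        errors=errors,
        index_source=index_source,
        warnings=warnings,
    )
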