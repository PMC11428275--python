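"""Regression-based response estimation for trait-vs-c_a series.

Every response in the pipeline — iWUE, g_smax, stomatal density, pore
area — is summarised as an ordinary least-squares slope against ambient
CO2, with a t-based 95% confidence interval and a relative sensitivity:
the slope over a 100-ppm window expressed as a percentage of the fitted
trait value at a 300-ppm reference, which makes traits with different
units comparable. Supporting analyses: a one-way ANOVA of g_smax across
25-ppm c_a bins (does within-bin scatter dominate the across-c_a
signal?), an order-averaged incremental-r² variance partition of iWUE
between c_a and precipitation, and an RMSE comparing simulated to
empirical per-species slopes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ResponseFit", "DEFAULT_CA_BINS",
    "fit_trend", "relative_sensitivity", "anova_binned",
    "variance_partition", "slope_rmse", "range_summary",
]

#: Default c_a bin edges (ppm): 300-325, 326-350, 351-375, 376-400.
DEFAULT_CA_BINS = (300.0, 325.0, 350.0, 375.0, 400.0)


@dataclass(frozen=True)
class ResponseFit:
    """One trait-vs-c_a OLS fit."""

    trait: str
    species: str
    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    r2: float
    p_value: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05

    def value_at(self, ca: float) -> float:
        return self.intercept + self.slope * ca


def fit_trend(x: Sequence[float], y: Sequence[float],
              trait: str = "trait", species: str = "combined",
              alpha: float = 0.05) -> ResponseFit:
    """OLS of a trait on c_a with a two-sided slope CI and p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y lengths differ")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if len(np.unique(x)) < 2:
        raise ValueError("degenerate design: all x identical")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    ci = res.conf_int(alpha=alpha)
    r2 = float(res.rsquared) if np.ptp(y) > 0 else 0.0  # constant response
    return ResponseFit(
        trait=trait, species=species,
        slope=float(res.params[1]), intercept=float(res.params[0]),
        ci_low=float(ci[1, 0]), ci_high=float(ci[1, 1]),
        r2=r2, p_value=float(res.pvalues[1]), n=len(x),
    )


def relative_sensitivity(fit: ResponseFit, ref_ca: float = 300.0,
                         window: float = 100.0) -> float:
    """Percent change per ``window`` ppm relative to the fit at ``ref_ca``.

    100 · slope·window / (intercept + slope·ref_ca). Invariant to a
    positive rescaling of the trait.
    """
    ref_value = fit.value_at(ref_ca)
    scale = max(abs(fit.intercept), abs(fit.slope * ref_ca), 1e-300)
    if abs(ref_value) <= 1e-12 * scale:
        raise ValueError("fitted value at the reference ca is zero")
    return 100.0 * fit.slope * window / ref_value


def anova_binned(values: Sequence[float], ca: Sequence[float],
                 bins: Sequence[float] = DEFAULT_CA_BINS,
                 ) -> tuple[float, tuple[int, int], float]:
    """One-way ANOVA of values across c_a bins.

    Returns (F, (df_between, df_within), p). Every bin must be non-empty.
    Degenerate data (no variance anywhere) report F = 0, p = 1 as "no
    between-group variance".
    """
    values = np.asarray(values, dtype=float)
    ca = np.asarray(ca, dtype=float)
    edges = np.asarray(bins, dtype=float)
    idx = np.digitize(ca, edges[1:-1], right=True)
    groups = []
    for k in range(len(edges) - 1):
        g = values[idx == k]
        if len(g) == 0:
            raise ValueError(
                f"empty ca bin {edges[k]:g}-{edges[k + 1]:g} ppm")
        groups.append(g)
    df_between = len(groups) - 1
    df_within = sum(len(g) for g in groups) - len(groups)
    if all(np.ptp(g) == 0 for g in groups) and np.ptp(values) == 0:
        return 0.0, (df_between, df_within), 1.0
    f_stat, p = stats.f_oneway(*groups)
    return float(f_stat), (df_between, df_within), float(p)


def variance_partition(y: Sequence[float], x1: Sequence[float],
                       x2: Sequence[float],
                       ) -> tuple[float, float, float]:
    """Share of the model r² attributable to each of two predictors.

    Fits y ~ x1 + x2 and decomposes the model r² by averaging each
    predictor's incremental r² over both entry orders (the two-predictor
    case of dominance averaging), normalised so the shares sum to 100%
    of the model r². Returns (total_r2, share_x1_pct, share_x2_pct).
    """
    y = np.asarray(y, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if len(y) < 4:
        raise ValueError("need at least 4 observations")
    r12 = np.corrcoef(x1, x2)[0, 1]
    if abs(r12) > 0.999:
        raise ValueError("predictors are collinear")

    def r2_of(*cols) -> float:
        X = sm.add_constant(np.column_stack(cols))
        return float(sm.OLS(y, X).fit().rsquared)

    r2_1 = r2_of(x1)
    r2_2 = r2_of(x2)
    r2_full = r2_of(x1, x2)
    # order-averaged incremental contributions
    c1 = 0.5 * (r2_1 + (r2_full - r2_2))
    c2 = 0.5 * (r2_2 + (r2_full - r2_1))
    total = c1 + c2
    if total <= 0:
        return r2_full, 50.0, 50.0
    return r2_full, 100.0 * c1 / total, 100.0 * c2 / total


def slope_rmse(simulated: dict[str, float] | Sequence[float],
               empirical: dict[str, float] | Sequence[float]) -> float:
    """Root-mean-square difference between matched per-species slopes."""
    if isinstance(simulated, dict) != isinstance(empirical, dict):
        raise ValueError("simulated and empirical must both be dicts or "
                         "both sequences")
    if isinstance(simulated, dict):
        if set(simulated) != set(empirical):
            raise ValueError("species lists differ")
        keys = sorted(simulated)
        a = np.array([simulated[k] for k in keys], dtype=float)
        b = np.array([empirical[k] for k in keys], dtype=float)
    else:
        a = np.asarray(simulated, dtype=float)
        b = np.asarray(empirical, dtype=float)
        if len(a) != len(b):
            raise ValueError("species lists differ in length")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def range_summary(values: Sequence[float]) -> tuple[float, float, float]:
    """(min, max, range) of a non-empty sequence."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    return float(v.min()), float(v.max()), float(v.max() - v.min())
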