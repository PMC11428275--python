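"""Monte-Carlo propagation of intraspecific g_smax uncertainty.

Herbarium trait series are noisy: intraspecific variation and collection
gaps make any single fitted g_smax-vs-c_a line an uncertain summary. This
module propagates that uncertainty into the simulated physiological
responses, as a standalone statistical extension around a deterministic
process model (here the in-repo EB engine, run at annual resolution):

1. Per species, regress specimen g_smax on year-matched c_a (OLS) and
   keep both the coefficient estimates and their sampling covariance.
2. Draw ``n_draws`` (default 10,000) intercept/slope pairs from the
   multivariate-normal sampling distribution of the coefficients.
3. Each draw defines an annual g_smax trajectory over the study years;
   each trajectory is pushed through the process model with
   species-level mean trait parameterisation, giving annual iWUE, A and
   g_s series per draw.
4. Per draw, OLS slopes of the annual series against c_a yield the
   response coefficients ΔiWUE/Δc_a (δ₂), ΔA/Δc_a (γ₂) and Δg_s/Δc_a
   (η₂); equal-tailed 2.5/97.5 percentiles across draws give 95% CIs.

Draws whose trajectory would go nonpositive are floored at a small
positive conductance and counted, keeping the ensemble size fixed
without rejection bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core_data import AtmosphereSeries, SpecimenRecord
from .photosynthesis_eb import (
    DEFAULT_CONFIG, EBConfig, VcmaxTraitModel, gs_from_gsmax, kinetics_at,
    predict_vcmax25, solve_assimilation, total_conductance,
)
from .stomatal_morphology import leaf_gsmax

__all__ = [
    "GsmaxRegression", "CoefficientDraws", "EnsembleSeries",
    "EnsembleResponse",
    "fit_gsmax_regression", "sample_coefficients", "gsmax_trajectories",
    "run_ensemble", "summarize_responses", "species_ensemble_analysis",
    "responses_frame",
]

#: Floor applied to nonpositive sampled g_smax values, mol m^-2 s^-1 (1 mmol).
GSMAX_FLOOR = 1e-3


@dataclass(frozen=True)
class GsmaxRegression:
    """OLS fit of specimen g_smax (mol m⁻² s⁻¹) on c_a (ppm)."""

    species: str
    intercept: float
    slope: float
    cov: np.ndarray  # 2x2 sampling covariance, (intercept, slope) order
    n: int

    @property
    def coef(self) -> np.ndarray:
        return np.array([self.intercept, self.slope])


@dataclass(frozen=True)
class CoefficientDraws:
    """Multivariate-normal coefficient sample for one species."""

    species: str
    draws: np.ndarray  # (n_draws, 2): intercept, slope
    point: np.ndarray  # (2,)
    cov: np.ndarray
    seed: int

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]


@dataclass
class EnsembleSeries:
    """Per-draw annual series from the process model."""

    species: str
    years: np.ndarray
    ca: np.ndarray              # per-year c_a
    iwue: np.ndarray            # (n_draws, n_years)
    a_net: np.ndarray
    gs: np.ndarray
    floored_draws: int
    failed_draws: int


@dataclass
class EnsembleResponse:
    """Ensemble response slopes with equal-tailed 95% CIs.

    ``delta2`` = ΔiWUE/Δc_a, ``gamma2`` = ΔA/Δc_a, ``eta2`` = Δg_s/Δc_a;
    each entry is (mean, lo, hi) over the surviving draws.
    """

    species: str
    n_draws: int
    delta2: tuple[float, float, float]
    gamma2: tuple[float, float, float]
    eta2: tuple[float, float, float]
    per_draw: dict[str, np.ndarray] = field(default_factory=dict, repr=False)


def fit_gsmax_regression(records: Iterable[SpecimenRecord],
                         atmosphere: AtmosphereSeries,
                         species: str | None = None) -> GsmaxRegression:
    """Fit g_smax = β₁ + β₂·c_a across specimens of one species.

    Specimens without complete anatomy are ignored. Needs at least three
    usable specimens spanning at least two distinct c_a values.
    """
    records = list(records)
    if species is not None:
        records = [r for r in records if r.species == species]
    xs, ys = [], []
    name = species
    for rec in records:
        morpho = leaf_gsmax(rec)
        if morpho is None:
            continue
        xs.append(atmosphere.ca(rec.year))
        ys.append(morpho.gsmax)
        name = name or rec.species
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 specimens with gsmax")
    if len(np.unique(x)) < 2:
        raise ValueError("rank-deficient design: a single distinct ca value")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    return GsmaxRegression(
        species=name or "combined",
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        cov=np.asarray(res.cov_params()),
        n=len(x),
    )


def sample_coefficients(fit: GsmaxRegression, n_draws: int = 10_000,
                        seed: int = 0) -> CoefficientDraws:
    """Draw coefficient pairs from the fit's sampling distribution.

    Reproducible under a fixed seed. A zero covariance collapses every
    draw onto the point estimates. A non-positive-semidefinite covariance
    raises.
    """
    cov = np.asarray(fit.cov, dtype=float)
    eig = np.linalg.eigvalsh((cov + cov.T) / 2.0)
    if np.any(eig < -1e-10 * max(1.0, float(np.max(np.abs(eig))))):
        raise ValueError("coefficient covariance is not positive semi-definite")
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(fit.coef, cov, size=n_draws, method="svd")
    return CoefficientDraws(species=fit.species, draws=draws,
                            point=fit.coef, cov=cov, seed=seed)


def gsmax_trajectories(draws: CoefficientDraws,
                       atmosphere: AtmosphereSeries,
                       years: Sequence[int],
                       floor: float = GSMAX_FLOOR,
                       ) -> tuple[np.ndarray, int]:
    """Annual g_smax series per draw: g_smax(t) = β₁ + β₂·c_a(t).

    Returns an (n_draws, n_years) array and the number of draws that
    needed flooring at ``floor`` in at least one year.
    """
    years = np.asarray(years, dtype=int)
    ca = np.asarray(atmosphere.ca(years), dtype=float)
    traj = draws.draws[:, [0]] + draws.draws[:, [1]] * ca[None, :]
    floored = int(np.sum(np.any(traj <= 0, axis=1)))
    traj = np.maximum(traj, floor)
    return traj, floored


def run_ensemble(trajectories: np.ndarray,
                 species: str,
                 years: Sequence[int],
                 atmosphere: AtmosphereSeries,
                 model: VcmaxTraitModel,
                 mean_n_area: float,
                 mean_lma: float,
                 config: EBConfig = DEFAULT_CONFIG,
                 floored_draws: int = 0) -> EnsembleSeries:
    """Push every g_smax trajectory through the process model.

    Species-level parameterisation: one V_cmax,25 from the species mean
    N_area and LMA (SLA = 1/LMA), fixed kinetics at the operating leaf
    temperature; only g_smax (hence g_s, g_t) and c_a vary by draw/year.
    Draws with any inadmissible solver year are flagged (all-NaN rows)
    and excluded from the summaries.
    """
    years = np.asarray(years, dtype=int)
    ca = np.asarray(atmosphere.ca(years), dtype=float)
    vcmax25 = predict_vcmax25(model, mean_n_area, 1.0 / mean_lma, species)
    kin = kinetics_at(config.t_leaf, vcmax25, config)
    gs = gs_from_gsmax(trajectories, config.gs_ratio)
    _, gt = total_conductance(gs, config.gcb)
    a_net, _ci = solve_assimilation(kin, gt, ca[None, :])
    iwue = a_net / gs
    failed_mask = np.any(~np.isfinite(a_net), axis=1)
    a_net[failed_mask] = np.nan
    iwue[failed_mask] = np.nan
    gs = np.where(failed_mask[:, None], np.nan, gs)
    return EnsembleSeries(species=species, years=years, ca=ca,
                          iwue=iwue, a_net=a_net, gs=gs,
                          floored_draws=floored_draws,
                          failed_draws=int(np.sum(failed_mask)))


def _per_draw_slopes(series: np.ndarray, ca: np.ndarray) -> np.ndarray:
    """Vectorised OLS slope of each row of ``series`` against ``ca``."""
    ca_c = ca - ca.mean()
    denom = float(np.sum(ca_c ** 2))
    if denom == 0:
        raise ValueError("ca values are constant; slope undefined")
    y_c = series - np.nanmean(series, axis=1, keepdims=True)
    return np.nansum(y_c * ca_c[None, :], axis=1) / denom


def summarize_responses(ensemble: EnsembleSeries,
                        keep_per_draw: bool = False) -> EnsembleResponse:
    """Per-draw response slopes vs c_a, with mean and 2.5/97.5% CI."""
    if len(ensemble.years) < 2:
        raise ValueError("need at least two years per draw")
    out: dict[str, tuple[float, float, float]] = {}
    per_draw: dict[str, np.ndarray] = {}
    for key, series in (("delta2", ensemble.iwue),
                        ("gamma2", ensemble.a_net),
                        ("eta2", ensemble.gs)):
        slopes = _per_draw_slopes(series, ensemble.ca)
        ok = slopes[np.isfinite(slopes)]
        lo, hi = np.percentile(ok, [2.5, 97.5])
        out[key] = (float(np.mean(ok)), float(lo), float(hi))
        if keep_per_draw:
            per_draw[key] = ok
    n_ok = int(np.sum(np.isfinite(_per_draw_slopes(ensemble.iwue, ensemble.ca))))
    return EnsembleResponse(species=ensemble.species, n_draws=n_ok,
                            delta2=out["delta2"], gamma2=out["gamma2"],
                            eta2=out["eta2"], per_draw=per_draw)


def species_ensemble_analysis(records: Iterable[SpecimenRecord],
                              atmosphere: AtmosphereSeries,
                              model: VcmaxTraitModel,
                              species: str,
                              n_draws: int = 10_000,
                              seed: int = 0,
                              years: Sequence[int] | None = None,
                              config: EBConfig = DEFAULT_CONFIG,
                              keep_per_draw: bool = False,
                              ) -> EnsembleResponse:
    """End-to-end Monte-Carlo analysis for one species.

    Convenience wrapper: regression → coefficient draws → trajectories →
    process-model ensemble → response summary. Species mean N_area and
    LMA are taken over the specimens that carry them.
    """
    records = [r for r in records if r.species == species]
    if not records:
        raise ValueError(f"no records for species {species!r}")
    fit = fit_gsmax_regression(records, atmosphere)
    draws = sample_coefficients(fit, n_draws=n_draws, seed=seed)
    if years is None:
        lo, hi = atmosphere.year_range
        years = np.arange(lo, hi + 1)
    traj, floored = gsmax_trajectories(draws, atmosphere, years)
    n_area = np.mean([r.n_area for r in records if r.n_area is not None])
    lma = np.mean([r.lma for r in records if r.lma is not None])
    if not np.isfinite(n_area) or not np.isfinite(lma):
        raise ValueError(f"species {species!r} lacks N_area/LMA for "
                         "parameterisation")
    ens = run_ensemble(traj, species, years, atmosphere, model,
                       float(n_area), float(lma), config,
                       floored_draws=floored)
    return summarize_responses(ens, keep_per_draw=keep_per_draw)


def responses_frame(responses: Iterable[EnsembleResponse]) -> pd.DataFrame:
    """Ensemble summaries as a tidy DataFrame (one row per species)."""
    rows = []
    for r in responses:
        row = {"species": r.species, "n_draws": r.n_draws}
        for key in ("delta2", "gamma2", "eta2"):
            mean, lo, hi = getattr(r, key)
            row[f"{key}_mean"] = mean
            row[f"{key}_lo"] = lo
            row[f"{key}_hi"] = hi
        rows.append(row)
    return pd.DataFrame(rows)
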