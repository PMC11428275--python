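"""Empirical–biochemical (EB) gas-exchange engine.

Per specimen, the engine chains:

1. A trait-based prediction of the maximum Rubisco carboxylation rate at
   25 °C from leaf nitrogen per area and specific leaf area, via a mixed
   model on transformed scales::

       ln V_cmax,25 = a·(1/N_area) + b·ln SLA + c·(1/N_area)·ln SLA + d
                      + (1 | species)

2. Arrhenius temperature scaling of V_cmax and the Rubisco kinetic
   constants (K_C, K_O, Γ*) from 25 °C to the operating leaf temperature
   (29 °C, the present-day mean in the study region), with day
   respiration R_d = 0.015·V_cmax at leaf temperature.

3. An operational stomatal conductance g_s = 0.51·g_smax — the measured
   mean ratio of light-saturated field conductance to the anatomical
   maximum — converted to a total CO2 conductance g_t through the 1.6
   H2O:CO2 diffusivity ratio and a boundary-layer conductance g_cb in
   series (mesophyll conductance treated as non-limiting).

4. The Rubisco-limited FvCB assimilation rate coupled to Fick's law
   (c_i = c_a − A/g_t), which collapses to a quadratic in A; the
   admissible root (0 < c_i ≤ c_a) gives A and c_i, and iWUE = A/g_s.

Rubisco limitation is assumed throughout (valid under saturating light at
c_a ≤ 400 ppm); the RuBP-regeneration-limited rate A_j is provided for
completeness but is not on the default path. Ternary H2O–CO2
interaction effects on c_i (~2%) are not modelled.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .core_data import AtmosphereSeries, SpecimenRecord
from .stomatal_morphology import leaf_gsmax

__all__ = [
    "EBConfig", "KineticParams", "VcmaxTraitModel", "EBResult",
    "DEFAULT_CONFIG",
    "arrhenius_factor", "kinetics_at",
    "fit_vcmax_model", "predict_vcmax25", "vcmax_one_point",
    "gs_from_gsmax", "total_conductance",
    "solve_assimilation", "aj_rate", "eb_simulate", "eb_results_frame",
]

R_GAS = 8.314  # J mol^-1 K^-1
T_REF_K = 298.15


@dataclass(frozen=True)
class EBConfig:
    """Constants of the EB engine, with published defaults.

    Kinetic reference values at 25 °C and activation energies follow the
    standard leaf-level Rubisco temperature-response parameterisation
    (Bernacchi-type): K_C,25 = 404.9 µmol mol⁻¹ (Ha 79.43 kJ mol⁻¹),
    K_O,25 = 278.4 mmol mol⁻¹ (36.38), Γ*_25 = 42.75 µmol mol⁻¹ (37.83),
    V_cmax Ha 65.33 kJ mol⁻¹; ambient O2 = 210 mmol mol⁻¹.
    """

    gs_ratio: float = 0.51          # operational gs / anatomical gsmax
    gcb: float = 2.0                # boundary-layer CO2 conductance, mol m-2 s-1
    t_leaf: float = 29.0            # operating leaf temperature, degC
    rd_ratio: float = 0.015         # Rd / Vcmax at leaf temperature
    oxygen: float = 210.0           # mmol mol^-1
    kc25: float = 404.9             # umol mol^-1
    ko25: float = 278.4             # mmol mol^-1
    gamma_star25: float = 42.75     # umol mol^-1
    ha_vcmax: float = 65330.0       # J mol^-1
    ha_kc: float = 79430.0
    ha_ko: float = 36380.0
    ha_gamma_star: float = 37830.0

    @classmethod
    def from_dict(cls, d: dict) -> "EBConfig":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


DEFAULT_CONFIG = EBConfig()


@dataclass(frozen=True)
class KineticParams:
    """Rubisco kinetics and respiration at a leaf temperature."""

    vcmax: float        # umol m^-2 s^-1, at t_leaf
    kc: float           # umol mol^-1
    ko: float           # mmol mol^-1
    gamma_star: float   # umol mol^-1
    oxygen: float       # mmol mol^-1
    rd: float           # umol m^-2 s^-1
    t_leaf: float       # degC

    @property
    def km(self) -> float:
        """Effective Michaelis constant K_C (1 + O/K_O), µmol mol⁻¹."""
        return self.kc * (1.0 + self.oxygen / self.ko)


def arrhenius_factor(activation_energy: float, t_leaf: float) -> float:
    """Multiplier taking a 25 °C value to ``t_leaf`` (°C).

    exp(Ha (T − 25) / (298.15 · R · T_K)); its reciprocal is the exact
    inverse scaling back to 25 °C.
    """
    t_k = t_leaf + 273.15
    return math.exp(activation_energy * (t_leaf - 25.0) / (T_REF_K * R_GAS * t_k))


def kinetics_at(t_leaf: float, vcmax25: float,
                config: EBConfig = DEFAULT_CONFIG) -> KineticParams:
    """Kinetics at leaf temperature from the 25 °C references."""
    if not 0.0 < t_leaf < 50.0:
        raise ValueError("leaf temperature outside the supported 0-50 degC")
    vcmax = vcmax25 * arrhenius_factor(config.ha_vcmax, t_leaf)
    return KineticParams(
        vcmax=vcmax,
        kc=config.kc25 * arrhenius_factor(config.ha_kc, t_leaf),
        ko=config.ko25 * arrhenius_factor(config.ha_ko, t_leaf),
        gamma_star=config.gamma_star25 * arrhenius_factor(config.ha_gamma_star, t_leaf),
        oxygen=config.oxygen,
        rd=config.rd_ratio * vcmax,
        t_leaf=t_leaf,
    )


# ---------------------------------------------------------------------------
# Trait-based Vcmax,25 model
# ---------------------------------------------------------------------------

@dataclass
class VcmaxTraitModel:
    """Fitted ln-V_cmax,25 trait model.

    Fixed coefficients apply to 1/N_area, ln SLA, their product and an
    intercept. Species seen during training carry a random intercept;
    unseen species get the fixed part only.
    """

    coef_rec_n: float
    coef_ln_sla: float
    coef_interaction: float
    intercept: float
    random_intercepts: dict[str, float] = field(default_factory=dict)
    random_intercept_var: float = 0.0
    pseudo_r2: float = float("nan")
    resid_normality_p: float = float("nan")
    is_mixed: bool = True
    aic: float = float("nan")


def _design_frame(training: Sequence[tuple[str, float, float, float]]) -> pd.DataFrame:
    df = pd.DataFrame(training, columns=["species", "vcmax25", "sla", "n_area"])
    if (df[["vcmax25", "sla", "n_area"]] <= 0).any().any():
        raise ValueError("training traits and Vcmax25 must be positive")
    df["ln_v"] = np.log(df["vcmax25"])
    df["rec_n"] = 1.0 / df["n_area"]
    df["ln_sla"] = np.log(df["sla"])
    df["inter"] = df["rec_n"] * df["ln_sla"]
    return df


def fit_vcmax_model(training: Sequence[tuple[str, float, float, float]],
                    selection: str = "mixed") -> VcmaxTraitModel:
    """Fit the trait model on (species, Vcmax25, SLA, N_area) tuples.

    ``selection``:
      * ``"mixed"`` (default) — species random intercept, REML;
      * ``"fixed"`` — ordinary least squares, no species term;
      * ``"aic"`` — both candidates refit by full maximum likelihood and
        the lower-AIC form is returned.

    A single-species design cannot identify a random intercept; the fit
    falls back to fixed effects with a warning.
    """
    df = _design_frame(training)
    n_species = df["species"].nunique()
    formula = "ln_v ~ rec_n + ln_sla + inter"

    def _fixed() -> VcmaxTraitModel:
        res = smf.ols(formula, data=df).fit()
        fitted = res.fittedvalues.to_numpy()
        return _finalise(res.params, {}, 0.0, fitted, df, is_mixed=False,
                         aic=res.aic)

    if selection not in {"mixed", "fixed", "aic"}:
        raise ValueError(f"unknown selection {selection!r}")
    if selection == "fixed":
        return _fixed()
    if n_species < 2:
        warnings.warn("single species in training data: falling back to a "
                      "fixed-effects fit", UserWarning, stacklevel=2)
        return _fixed()

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mixed = smf.mixedlm(formula, data=df, groups=df["species"]).fit(reml=True)
    except (np.linalg.LinAlgError, ValueError):
        # degenerate designs (e.g. zero residual variance) leave the random
        # intercept unidentifiable
        warnings.warn("mixed-effects fit is singular: falling back to a "
                      "fixed-effects fit", UserWarning, stacklevel=2)
        return _fixed()
    re = {sp: float(v.iloc[0]) for sp, v in mixed.random_effects.items()}
    re_var = float(np.asarray(mixed.cov_re)[0, 0])
    fitted = (mixed.fittedvalues.to_numpy()
              + df["species"].map(re).to_numpy())

    if selection == "aic":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mixed_ml = smf.mixedlm(formula, data=df, groups=df["species"]).fit(reml=False)
        fixed_model = _fixed()
        if fixed_model.aic <= mixed_ml.aic:
            return fixed_model
        return _finalise(mixed.params, re, re_var, fitted, df, is_mixed=True,
                         aic=mixed_ml.aic)
    return _finalise(mixed.params, re, re_var, fitted, df, is_mixed=True,
                     aic=float("nan"))


def _finalise(params, re, re_var, fitted, df, *, is_mixed, aic) -> VcmaxTraitModel:
    obs = df["ln_v"].to_numpy()
    resid = obs - fitted
    # pseudo-R2: squared correlation of observed and conditional fitted values
    if np.std(fitted) > 0 and np.std(obs) > 0:
        r2 = float(np.corrcoef(obs, fitted)[0, 1] ** 2)
    else:
        r2 = 0.0
    if len(resid) >= 3 and np.std(resid) > 0:
        norm_p = float(stats.shapiro(resid).pvalue)
    else:
        norm_p = float("nan")
    return VcmaxTraitModel(
        coef_rec_n=float(params["rec_n"]),
        coef_ln_sla=float(params["ln_sla"]),
        coef_interaction=float(params["inter"]),
        intercept=float(params["Intercept"]),
        random_intercepts=re,
        random_intercept_var=re_var,
        pseudo_r2=r2,
        resid_normality_p=norm_p,
        is_mixed=is_mixed,
        aic=aic,
    )


def predict_vcmax25(model: VcmaxTraitModel, n_area, sla,
                    species: str | None = None):
    """Predicted V_cmax,25 (µmol m⁻² s⁻¹) from N_area (g m⁻²) and SLA (m² g⁻¹).

    SLA must be in the units the model was trained with. A species present
    in the training set contributes its random intercept; an unseen (or
    unspecified) species gets the fixed part only.
    """
    n_arr = np.asarray(n_area, dtype=float)
    s_arr = np.asarray(sla, dtype=float)
    if np.any(n_arr <= 0) or np.any(s_arr <= 0):
        raise ValueError("traits must be strictly positive")
    rec_n = 1.0 / n_arr
    ln_sla = np.log(s_arr)
    ln_v = (model.coef_rec_n * rec_n + model.coef_ln_sla * ln_sla
            + model.coef_interaction * rec_n * ln_sla + model.intercept)
    if species is not None:
        ln_v = ln_v + model.random_intercepts.get(species, 0.0)
    out = np.exp(ln_v)
    scalar = np.ndim(n_area) == 0 and np.ndim(sla) == 0
    return float(out) if scalar else out


def vcmax_one_point(a_net: float, ci: float, kinetics: KineticParams,
                    rd_ratio: float = 0.015) -> float:
    """One-point V_cmax from a single light-saturated gas-exchange point.

    Solves A = Vcmax·(c_i − Γ*)/(c_i + K_m) − rd_ratio·Vcmax for Vcmax at
    the measurement temperature. The denominator must be positive: a
    measurement with (c_i − Γ*)/(c_i + K_m) ≤ rd_ratio is inconsistent
    with Rubisco-limited photosynthesis.
    """
    denom = (ci - kinetics.gamma_star) / (ci + kinetics.km) - rd_ratio
    if denom <= 0:
        raise ValueError("gas-exchange point inconsistent with Rubisco "
                         "limitation: (ci - gamma*)/(ci + Km) <= rd ratio")
    return a_net / denom


# ---------------------------------------------------------------------------
# Conductances and the coupled solver
# ---------------------------------------------------------------------------

def gs_from_gsmax(gsmax, ratio: float = DEFAULT_CONFIG.gs_ratio):
    """Operational g_s from anatomical g_smax (both mol m⁻² s⁻¹)."""
    g = np.asarray(gsmax, dtype=float)
    if np.any(g < 0):
        raise ValueError("gsmax must be nonnegative")
    out = ratio * g
    return float(out) if np.ndim(gsmax) == 0 else out


def total_conductance(gs, gcb: float = DEFAULT_CONFIG.gcb):
    """Total CO2 conductance g_t from g_s (water vapour).

    g_c = g_s/1.6; g_t combines g_c and the boundary-layer conductance
    g_cb in series: g_t = g_c·g_cb/(g_c + g_cb). Returns (g_c, g_t).
    """
    g = np.asarray(gs, dtype=float)
    if np.any(g <= 0):
        raise ValueError("gs must be strictly positive")
    gc = g / 1.6
    gt = gc * gcb / (gc + gcb)
    if np.ndim(gs) == 0:
        return float(gc), float(gt)
    return gc, gt


def solve_assimilation(kinetics: KineticParams, gt, ca):
    """Rubisco-limited A and c_i coupled through Fick's law.

    Substituting c_i = c_a − A/g_t into the Rubisco-limited rate yields

        (1/g_t)·A² − (c_a + K_m + (Vcmax − R_d)/g_t)·A
            + Vcmax·(c_a − Γ*) − R_d·(c_a + K_m) = 0,

    whose smaller root is the physical solution (the larger root puts c_i
    below −K_m). The root is validated to give 0 < c_i ≤ c_a·(1 + tiny).

    Accepts scalar or array ``gt``/``ca``; arrays flag inadmissible
    entries as NaN, scalars raise.
    """
    gt_arr = np.asarray(gt, dtype=float)
    ca_arr = np.asarray(ca, dtype=float)
    scalar = np.ndim(gt) == 0 and np.ndim(ca) == 0
    gt_b, ca_b = np.broadcast_arrays(gt_arr, ca_arr)
    if np.any(gt_b <= 0):
        raise ValueError("gt must be strictly positive")
    if np.any(ca_b <= kinetics.gamma_star):
        raise ValueError("ca must exceed the CO2 compensation point gamma*")

    vc, rd, km, gstar = (kinetics.vcmax, kinetics.rd, kinetics.km,
                         kinetics.gamma_star)
    a2 = 1.0 / gt_b
    b2 = -(ca_b + km + (vc - rd) / gt_b)
    c2 = vc * (ca_b - gstar) - rd * (ca_b + km)
    disc = b2 ** 2 - 4.0 * a2 * c2
    bad = disc < 0
    disc = np.where(bad, 0.0, disc)
    # smaller root, in the cancellation-free form (b2 < 0 always)
    a_net = 2.0 * c2 / (-b2 + np.sqrt(disc))
    ci = ca_b - a_net / gt_b
    # c_i may exceed c_a only marginally (A slightly negative when Rd wins).
    bad = bad | (ci <= 0) | (ci > ca_b * (1.0 + 1e-9) + 1e-9)
    if scalar:
        if bool(bad):
            raise ValueError("no admissible root with 0 < ci <= ca")
        return float(a_net), float(ci)
    a_net = np.where(bad, np.nan, a_net)
    ci = np.where(bad, np.nan, ci)
    return a_net, ci


def aj_rate(ci, jmax: float, kinetics: KineticParams):
    """RuBP-regeneration-limited rate A_j (not on the default path).

    A_j = (c_i − Γ*)·(J_max/4)/(c_i + 2Γ*) − R_d. Provided so the full
    min(A_c, A_j) form can be assembled; under saturating light at
    c_a ≤ 400 ppm Rubisco limitation is assumed.
    """
    if jmax <= 0:
        raise ValueError("Jmax must be positive")
    ci_arr = np.asarray(ci, dtype=float)
    out = ((ci_arr - kinetics.gamma_star) * (jmax / 4.0)
           / (ci_arr + 2.0 * kinetics.gamma_star) - kinetics.rd)
    return float(out) if np.ndim(ci) == 0 else out


# ---------------------------------------------------------------------------
# Per-specimen simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EBResult:
    """Simulated gas exchange for one specimen."""

    specimen_id: str
    species: str
    year: int
    ca: float                 # ppm
    vcmax25: float            # umol m^-2 s^-1
    gs: float                 # mol m^-2 s^-1 (water vapour)
    gc: float                 # mol m^-2 s^-1 (CO2)
    gt: float                 # mol m^-2 s^-1 (CO2, total)
    a_net: float              # umol m^-2 s^-1
    ci: float                 # umol mol^-1
    iwue: float               # umol mol^-1


def eb_simulate(records: Iterable[SpecimenRecord],
                atmosphere: AtmosphereSeries,
                model: VcmaxTraitModel,
                config: EBConfig = DEFAULT_CONFIG,
                ) -> tuple[list[EBResult], dict[str, int]]:
    """Run the EB chain on every complete specimen.

    A specimen needs full stomatal anatomy (for g_smax), LMA (for SLA) and
    N_area; incomplete specimens are skipped and counted, solver failures
    flagged and counted — the pipeline never aborts mid-table.

    Returns (results, counts) with counts keyed ``simulated``,
    ``skipped_incomplete`` and ``solver_failed``.
    """
    results: list[EBResult] = []
    counts = {"simulated": 0, "skipped_incomplete": 0, "solver_failed": 0}
    for rec in records:
        morpho = leaf_gsmax(rec)
        if morpho is None or rec.lma is None or rec.n_area is None:
            counts["skipped_incomplete"] += 1
            continue
        ca_t = atmosphere.ca(rec.year)
        vcmax25 = predict_vcmax25(model, rec.n_area, rec.sla, rec.species)
        kin = kinetics_at(config.t_leaf, vcmax25, config)
        gs = gs_from_gsmax(morpho.gsmax, config.gs_ratio)
        gc, gt = total_conductance(gs, config.gcb)
        try:
            a_net, ci = solve_assimilation(kin, gt, ca_t)
        except ValueError:
            counts["solver_failed"] += 1
            continue
        results.append(EBResult(
            specimen_id=rec.specimen_id, species=rec.species, year=rec.year,
            ca=ca_t, vcmax25=vcmax25, gs=gs, gc=gc, gt=gt,
            a_net=a_net, ci=ci, iwue=a_net / gs,
        ))
        counts["simulated"] += 1
    return results, counts


def eb_results_frame(results: Iterable[EBResult]) -> pd.DataFrame:
    """EB results as a tidy DataFrame (one row per simulated specimen)."""
    return pd.DataFrame([r.__dict__ for r in results])
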