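"""End-to-end analysis: peak table -> calibration -> g series -> kinetic
fits -> synthesis rates -> pathway reports.

Two labeling modes are supported. In ``cell`` mode the water enrichment p is
known (set by the experimenter, 0.05 for 5% D2O) and only per-sterol site
counts N are estimated. In ``mouse`` mode p is estimated jointly with the N
values across all tissues by alternating RMS regression against the
asymptotic M+0 observations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import calibration as cal
from .errors import InvalidInputError, SterolFluxError
from .isa import LabelModel, TurnoverSeries, fraction_new_from_m0
from .isotopes import CARBON_ONLY_ABUNDANCES, asymptotic_m0
from .kinetics import fit_first_order, quantify_concentration
from .pathway import PathwayReport, utilization_vs_logflux
from .registry import SterolRegistry, default_registry
from .simulate import PeakTable

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "extract_asymptotic_observations",
           "observed_m0_series"]


@dataclass
class PipelineResult:
    """Everything the pipeline computed, in report-ready tables."""

    mode: str
    p: float
    calibration: pd.DataFrame      # sterol, condition, m0_n, m0_t_obs, N, m0_t_model
    fits: pd.DataFrame             # sterol, condition, g_inf, k, rss, conc, rate
    reports: list[PathwayReport]
    rms: float | None = None
    warnings: list[str] = field(default_factory=list)

    def utilization(self) -> dict:
        return utilization_vs_logflux(self.reports)


def observed_m0_series(table: PeakTable, registry: SterolRegistry,
                       window: int = 3) -> pd.DataFrame:
    """Windowed M+0 fraction per (sterol, condition, time, replicate),
    masked peaks excluded per registry."""
    rows = []
    for (sterol, condition), grp in table.peaks.groupby(["sterol", "condition"]):
        if sterol not in registry:
            continue
        sdef = registry[sterol]
        if not sdef.measurable or sdef.pathway == "standard":
            continue
        shifts = set(registry.shifts_for(sterol, window))
        for (t, rep), obs in grp.groupby(["time_hr", "replicate"]):
            obs = obs[obs["mass_shift"].isin(shifts)]
            total = obs["intensity"].sum()
            m0 = obs.loc[obs["mass_shift"] == 0, "intensity"].sum()
            if total > 0 and m0 > 0:
                rows.append((sterol, condition, float(t), rep, float(m0 / total)))
    return pd.DataFrame(rows, columns=["sterol", "condition", "time_hr",
                                       "replicate", "m0"])


def _plateau_m0(times: np.ndarray, m0: np.ndarray) -> float:
    """Extrapolated asymptote of M0(t) = m0_n - A (1 - exp(-kappa t))."""
    m0_n = float(np.mean(m0[times == 0])) if np.any(times == 0) else float(m0.max())

    def resid(theta):
        a, kappa = theta
        return (m0_n - a * (1.0 - np.exp(-kappa * times))) - m0

    drop = max(m0_n - float(m0.min()), 1e-3)
    sol = least_squares(resid, x0=[drop, 0.05], bounds=([0.0, 1e-6], [1.0, 10.0]))
    return float(np.clip(m0_n - sol.x[0], 1e-6, 1.0 - 1e-6))


def extract_asymptotic_observations(m0_series: pd.DataFrame,
                                    mode: str = "last",
                                    ) -> list[cal.AsymptoticObservation]:
    """One asymptotic M+0 observation per (sterol, condition).

    ``mode='last'`` averages the replicate M+0 fractions at the final time
    point (valid when labeling ran long enough for full pool turnover);
    ``mode='plateau'`` extrapolates the fitted exponential plateau of the
    M0(t) curve, which tolerates series that have not fully saturated.
    """
    obs = []
    for (sterol, condition), grp in m0_series.groupby(["sterol", "condition"]):
        if mode == "last":
            t_max = grp["time_hr"].max()
            if t_max <= 0:
                continue
            m0_t = float(grp.loc[grp["time_hr"] == t_max, "m0"].mean())
        elif mode == "plateau":
            m0_t = _plateau_m0(grp["time_hr"].to_numpy(dtype=float),
                               grp["m0"].to_numpy(dtype=float))
        else:
            raise InvalidInputError(f"unknown asymptote mode {mode!r}")
        if not (0.0 < m0_t < 1.0):
            continue
        obs.append(cal.AsymptoticObservation(str(sterol), str(condition), m0_t))
    return obs


def run_pipeline(table: PeakTable, registry: SterolRegistry | None = None,
                 mode: str = "cell", p: float | str = 0.05, window: int = 3,
                 init_N: int = 21, asymptote_mode: str = "last",
                 search_range: tuple[int, int] | None = None,
                 abundances=CARBON_ONLY_ABUNDANCES) -> PipelineResult:
    """Run calibration, deconvolution, kinetic fitting and pathway reporting.

    ``p`` is a fixed enrichment in cell mode; in mouse mode (or when
    ``p='estimate'``) a single global p is estimated jointly with the N
    values across all conditions.
    """
    registry = registry or default_registry()
    warnings_log: list[str] = []

    m0s = observed_m0_series(table, registry, window)
    if len(m0s) == 0:
        raise InvalidInputError("peak table contains no measurable sterol data")

    # --- M0_n per (sterol, condition) from the unlabeled (t = 0) samples ---
    m0n_map: dict[tuple[str, str], float] = {}
    for (sterol, condition), grp in m0s.groupby(["sterol", "condition"]):
        at0 = grp[grp["time_hr"] == 0]
        key = (str(sterol), str(condition))
        if len(at0):
            m0n_map[key] = float(at0["m0"].mean())
        else:
            sdef = registry[str(sterol)]
            m0n_map[key] = cal.natural_m0(
                sdef.formula, window, abundances,
                registry.shifts_for(str(sterol), window))
            warnings_log.append(f"{sterol}/{condition}: no unlabeled samples; "
                                "M0_n from natural-abundance model")

    # --- asymptotic observations and (N, p) calibration --------------------
    obs = extract_asymptotic_observations(m0s, asymptote_mode)
    formulas = {o.sterol: registry[o.sterol].formula for o in obs}
    shifts_map = {o.sterol: registry.shifts_for(o.sterol, window) for o in obs}

    estimate_p = mode == "mouse" or p == "estimate"
    rms = None
    if estimate_p:
        joint_kw = {"search_range": search_range} if search_range else {}
        joint = cal.joint_estimate_Np(
            obs, formulas, init_N=init_N, window=window,
            abundances=abundances, measurable_shifts=shifts_map, **joint_kw)
        p_hat = joint.p
        # joint calibration shares one N per sterol across tissues
        N_map = {(o.sterol, o.tissue): joint.N[o.sterol] for o in obs}
        rms = joint.rms
        if joint.degenerate:
            warnings_log.append("p estimation degenerate (too few observations)")
        if mode == "mouse":
            tissues = {o.tissue for o in obs}
            if len(tissues) < 2:
                warnings_log.append(
                    "mouse mode with < 2 tissues: p estimate is weakly identified")
    else:
        p_hat = float(p)
        N_map = {}
        for o in obs:
            N_map[(o.sterol, o.tissue)] = cal.estimate_N(
                o, p_hat, formulas[o.sterol], window, search_range or (5, 40),
                abundances, shifts_map[o.sterol])

    # --- label models and g series -----------------------------------------
    cal_rows = []
    models_by_condition: dict[str, dict[str, LabelModel]] = {}
    obs_by_key = {(o.sterol, o.tissue): o for o in obs}
    for (sterol, condition), N in N_map.items():
        shifts = shifts_map[sterol]
        m0_t_model = asymptotic_m0(formulas[sterol], N, p_hat, window,
                                   abundances, shifts)
        m0_n = m0n_map[(sterol, condition)]
        try:
            model = LabelModel(p=p_hat, N=N, M0_n=m0_n, M0_t=m0_t_model)
        except SterolFluxError as exc:
            warnings_log.append(f"{sterol}/{condition}: label model invalid ({exc})")
            continue
        models_by_condition.setdefault(condition, {})[sterol] = model
        cal_rows.append((sterol, condition, m0_n,
                         obs_by_key[(sterol, condition)].m0_t, N, m0_t_model))
    calibration_df = pd.DataFrame(
        cal_rows, columns=["sterol", "condition", "m0_n", "m0_t_obs", "N",
                           "m0_t_model"])

    # --- g from each replicate M+0, kinetic fit, quantitation --------------
    fit_rows = []
    reports = []
    samples = table.samples.set_index("sample_id")
    for condition, models in sorted(models_by_condition.items()):
        cond_m0 = m0s[m0s["condition"] == condition]
        rates: dict[str, float] = {}
        for sterol, model in models.items():
            grp = cond_m0[cond_m0["sterol"] == sterol]
            g = grp["m0"].map(lambda v: fraction_new_from_m0(v, model))
            series_df = pd.DataFrame({"time_hr": grp["time_hr"], "g": g,
                                      "replicate": grp["replicate"]})
            series = TurnoverSeries(sterol=sterol, condition=condition,
                                    observations=series_df.reset_index(drop=True))
            try:
                fit = fit_first_order(series)
            except SterolFluxError as exc:
                warnings_log.append(f"{sterol}/{condition}: unfittable ({exc})")
                continue

            # internal-standard quantitation, averaged over samples
            concs = []
            peaks = table.peaks
            sel = peaks[(peaks["condition"] == condition)
                        & (peaks["sterol"] == sterol)]
            for sample_id, sgrp in sel.groupby("sample_id"):
                meta = samples.loc[sample_id]
                is_area = table.is_area_for(sample_id)
                if is_area <= 0:
                    continue
                q = quantify_concentration(
                    float(sgrp["intensity"].sum()), is_area,
                    float(meta["is_amount_ng"]), float(meta["normalizer_amount"]),
                    sterol=sterol, normalizer_kind=str(meta["normalizer_kind"]))
                concs.append(q.concentration)
            conc = float(np.mean(concs)) if concs else 0.0
            rate = fit.k * conc
            rates[sterol] = rate
            fit_rows.append((sterol, condition, fit.g_inf, fit.k, fit.se_k,
                             fit.rss, fit.n_obs, conc, rate, rate * 24.0,
                             fit.zero_turnover, series.out_of_range))
        reports.append(PathwayReport.from_rates(condition, rates, registry))

    fits_df = pd.DataFrame(fit_rows, columns=[
        "sterol", "condition", "g_inf", "k_per_hr", "se_k", "rss", "n_obs",
        "conc", "rate_per_hr", "rate_per_day", "zero_turnover", "g_out_of_range"])
    return PipelineResult(mode=mode, p=p_hat, calibration=calibration_df,
                          fits=fits_df, reports=reports, rms=rms,
                          warnings=warnings_log)
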