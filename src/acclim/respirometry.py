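"""Reduction of raw respirometry data to per-fish metabolic summaries.

The chain is: closed-phase O2 trace -> least-squares decline rate ->
whole-animal oxygen consumption MO2 = (decline - blank) * (V - Vm) * 60
(mg O2/h, with V the chamber and Vm the fish volume in litres) -> routine
metabolic rate as the mean of the three closed-phase estimates. The maximal
rate comes from the post-exhaustion recovery series: MO2 regressed on the
natural log of time since chamber re-entry, read off at ``eval_time`` (1 min
by default, where ln t = 0, i.e. the curve's intercept on the log-time scale);
the slope of that regression is the recovery-rate statistic, and aerobic scope
is MMR - RMR.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, GeometryError, ParameterError
from .records import (BLANK_ID, MetabolicSummary, O2Trace, PeakResult,
                      RecoveryFit, RecoverySeries, RoutineMR, SlopeFit)

__all__ = [
    "fit_o2_slope", "mo2_from_slope", "routine_mr", "fit_recovery_curve",
    "mmr_peak", "summarize_fish", "process_study",
]


def fit_o2_slope(trace: O2Trace, trim_start: float = 0.0,
                 clamp_negative: bool = False) -> SlopeFit:
    """Ordinary least squares of O2 concentration on time.

    ``trim_start`` (min) drops any initial mixing transient; the default keeps
    the whole trace. A rising-O2 window yields a negative ``decline_rate``
    flagged via ``negative_decline`` (or clamped to 0 if ``clamp_negative``).
    """
    keep = trace.time_min >= trim_start
    t = trace.time_min[keep]
    y = trace.o2_mg_per_l[keep]
    if t.size < 3:
        raise DataError(
            f"trace {trace.fish_id}/{trace.window_id}: {t.size} samples after "
            f"trimming at {trim_start} min; need >= 3")
    if np.ptp(t) == 0:
        raise DataError(f"trace {trace.fish_id}/{trace.window_id}: zero time variance")
    if np.ptp(y) == 0:
        slope, intercept, r2 = 0.0, float(y[0]), 0.0
    else:
        res = stats.linregress(t, y)
        slope, intercept, r2 = float(res.slope), float(res.intercept), float(res.rvalue**2)
    decline = -slope
    negative = decline < 0
    if negative and clamp_negative:
        decline = 0.0
    return SlopeFit(decline_rate=decline, intercept=intercept, r_squared=r2,
                    n_points=int(t.size), negative_decline=negative)


def mo2_from_slope(fit: SlopeFit | float, chamber_volume: float,
                   fish_volume: float, blank_rate: float = 0.0) -> float:
    """Whole-animal oxygen consumption (mg O2/h) from a decline rate.

    The blank (bacterial background) rate is subtracted on the concentration
    scale before scaling by the effective water volume: MO2 = (decline -
    blank) * (V - Vm) * 60.
    """
    if chamber_volume <= fish_volume:
        raise GeometryError(
            f"chamber volume {chamber_volume} l must exceed fish volume {fish_volume} l")
    if fish_volume < 0:
        raise GeometryError(f"fish volume must be >= 0 l, got {fish_volume}")
    if blank_rate < 0:
        raise ParameterError(f"blank_rate must be >= 0 mg/l/min, got {blank_rate}")
    decline = fit.decline_rate if isinstance(fit, SlopeFit) else float(fit)
    return (decline - blank_rate) * (chamber_volume - fish_volume) * 60.0


def routine_mr(mo2_values, fish_id: str = "", expected_n: int = 3) -> RoutineMR:
    """Arithmetic mean of the closed-phase MO2 estimates.

    The protocol expects three windows; a different count is flagged
    (``count_mismatch``) but not rejected.
    """
    values = np.atleast_1d(np.asarray(mo2_values, dtype=float))
    if values.size == 0:
        raise DataError(f"routine_mr({fish_id!r}): needs at least one MO2 value")
    return RoutineMR(fish_id=fish_id, value=float(values.mean()),
                     n=int(values.size), expected_n=expected_n)


def fit_recovery_curve(series: RecoverySeries, eval_time: float = 1.0) -> RecoveryFit:
    """OLS of post-exhaustion MO2 on ln(minutes since re-entry).

    ``mmr_estimate`` is the fitted curve at ``eval_time``; at the default of
    1 min this equals the intercept on the log-time scale, the conventional
    back-extrapolated maximal metabolic rate. ``beta1`` is the recovery-rate
    statistic (decline in metabolic rate per ln-minute).
    """
    if eval_time <= 0:
        raise DataError(f"eval_time must be > 0 min, got {eval_time}")
    if series.midpoint_min.size < 3:
        raise DataError(f"recovery {series.fish_id}: needs >= 3 measurements")
    x = np.log(series.midpoint_min)
    y = series.mo2_mg_per_h
    if np.ptp(y) == 0:
        beta1, beta0, r2 = 0.0, float(y[0]), 0.0
    else:
        res = stats.linregress(x, y)
        beta0, beta1, r2 = float(res.intercept), float(res.slope), float(res.rvalue**2)
    return RecoveryFit(fish_id=series.fish_id, beta0=beta0, beta1=beta1,
                       mmr_estimate=beta0 + beta1 * np.log(eval_time),
                       eval_time=float(eval_time), r_squared=r2)


def mmr_peak(series: RecoverySeries) -> PeakResult:
    """Highest post-chase measurement (no back-extrapolation); earliest
    window wins ties."""
    if series.mo2_mg_per_h.size == 0:
        raise DataError(f"recovery {series.fish_id}: empty series")
    i = int(np.argmax(series.mo2_mg_per_h))
    return PeakResult(fish_id=series.fish_id,
                      value=float(series.mo2_mg_per_h[i]), window_index=i + 1)


def summarize_fish(rmr: RoutineMR, recovery_fit: RecoveryFit,
                   peak: PeakResult) -> MetabolicSummary:
    """Combine the per-fish reductions; scope = MMR - RMR exactly.

    A negative scope is physiologically suspect but retained with a QC flag so
    the inference layer sees unbiased values.
    """
    ids = {rmr.fish_id, recovery_fit.fish_id, peak.fish_id}
    if len(ids) != 1:
        raise DataError(f"summarize_fish: inputs belong to different fish {sorted(ids)}")
    flags = []
    if rmr.count_mismatch:
        flags.append(f"rmr_n={rmr.n}")
    scope = recovery_fit.mmr_estimate - rmr.value
    if scope <= 0:
        flags.append("nonpositive_scope")
    return MetabolicSummary(
        fish_id=rmr.fish_id, rmr=rmr.value, mmr=recovery_fit.mmr_estimate,
        mmr_peak=peak.value, scope=scope, recovery_slope=recovery_fit.beta1,
        qc_flags=flags)


# ---------------------------------------------------------------------------
# table-level driver
# ---------------------------------------------------------------------------

def _blank_rates(blanks: pd.DataFrame, trim_start: float) -> tuple[dict, float]:
    """Per-(chamber, day) background decline rates and their global mean.

    Negative blank estimates (probe noise on a near-flat trace) are clamped to
    zero, since bacterial respiration cannot add oxygen.
    """
    rates = {}
    for (chamber, day), grp in blanks.groupby(["chamber", "day"]):
        tr = O2Trace(fish_id=BLANK_ID, window_id=f"blank-c{chamber}-d{day}",
                     time_min=grp["time_min"].to_numpy(),
                     o2_mg_per_l=grp["o2_mg_per_l"].to_numpy(),
                     chamber_volume=1.0, fish_volume=0.0)
        fit = fit_o2_slope(tr, trim_start=trim_start, clamp_negative=True)
        rates[(chamber, day)] = fit.decline_rate
    global_rate = float(np.mean(list(rates.values()))) if rates else 0.0
    return rates, global_rate


def process_study(fish: pd.DataFrame, traces: pd.DataFrame,
                  recovery: pd.DataFrame, blanks: pd.DataFrame | None = None,
                  *, chamber_volume: float = 1.1, fish_density: float = 1.0,
                  eval_time: float = 1.0, trim_start: float = 0.0,
                  expected_rmr_windows: int = 3) -> pd.DataFrame:
    """Reduce a whole study's tables to one metabolic summary row per fish.

    ``traces`` may carry ``chamber``/``day`` columns linking each fish to the
    blank measured in its chamber on its day; fish without a matching blank
    fall back to the study-wide mean background rate.
    """
    required = {"fish": ({"fish_id", "mass"}, fish),
                "traces": ({"fish_id", "window_id", "time_min", "o2_mg_per_l"}, traces),
                "recovery": ({"fish_id", "midpoint_min", "mo2_mg_per_h"}, recovery)}
    from .workflow import check_columns  # local import to avoid a cycle
    for name, (cols, df) in required.items():
        check_columns(df, cols, name)

    blank_by_key: dict = {}
    global_blank = 0.0
    if blanks is not None and len(blanks):
        check_columns(blanks, {"chamber", "day", "time_min", "o2_mg_per_l"}, "blanks")
        blank_by_key, global_blank = _blank_rates(blanks, trim_start)

    mass_by_fish = fish.set_index("fish_id")["mass"]
    have_chamber = {"chamber", "day"}.issubset(traces.columns)

    rows = []
    for fish_id, f_traces in traces.groupby("fish_id", sort=False):
        if fish_id not in mass_by_fish.index:
            raise DataError(f"traces: fish_id {fish_id!r} missing from fish table")
        vm = float(mass_by_fish.loc[fish_id]) / (fish_density * 1000.0)
        if have_chamber:
            key = (f_traces["chamber"].iloc[0], f_traces["day"].iloc[0])
            blank = blank_by_key.get(key, global_blank)
        else:
            blank = global_blank
        mo2s, flags = [], []
        for window_id, w in f_traces.groupby("window_id", sort=True):
            tr = O2Trace(fish_id=fish_id, window_id=str(window_id),
                         time_min=w["time_min"].to_numpy(),
                         o2_mg_per_l=w["o2_mg_per_l"].to_numpy(),
                         chamber_volume=chamber_volume, fish_volume=vm)
            sfit = fit_o2_slope(tr, trim_start=trim_start)
            if sfit.negative_decline:
                flags.append(f"negative_decline:{window_id}")
            mo2s.append(mo2_from_slope(sfit, chamber_volume, vm, blank))
        rmr = routine_mr(mo2s, fish_id=fish_id, expected_n=expected_rmr_windows)

        rec = recovery[recovery["fish_id"] == fish_id].sort_values("midpoint_min")
        if rec.empty:
            raise DataError(f"recovery: no measurements for fish {fish_id!r}")
        series = RecoverySeries(
            fish_id=fish_id, midpoint_min=rec["midpoint_min"].to_numpy(),
            mo2_mg_per_h=rec["mo2_mg_per_h"].to_numpy(),
            chase_duration=float(rec["chase_duration_min"].iloc[0])
            if "chase_duration_min" in rec.columns else float("nan"),
            transfer_delay=float(rec["transfer_delay_min"].iloc[0])
            if "transfer_delay_min" in rec.columns else float("nan"))
        rfit = fit_recovery_curve(series, eval_time=eval_time)
        peak = mmr_peak(series)
        summary = summarize_fish(rmr, rfit, peak)
        summary.qc_flags = flags + summary.qc_flags
        rows.append({
            "fish_id": fish_id, "rmr": summary.rmr, "mmr": summary.mmr,
            "mmr_peak": summary.mmr_peak, "scope": summary.scope,
            "recovery_slope": summary.recovery_slope,
            "eval_time_min": eval_time,
            "qc_flags": ";".join(summary.qc_flags),
        })
    return pd.DataFrame(rows)
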