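"""Critical thermal maximum (CTmax) extraction from ramping trials.

A trial holds a constant-rate temperature ramp and one loss-of-equilibrium
event per fish, recorded either as minutes on the ramp or directly as a
temperature. The per-fish CTmax is the ramp temperature at the event.
"""

from __future__ import annotations

import pandas as pd

from .errors import DataError, DomainError
from .records import CTMTrial, LOEEvent, RampSchedule

__all__ = ["temperature_at", "time_for", "ctm_values", "ctm_table", "events_to_trials"]


def temperature_at(ramp: RampSchedule, t: float) -> float:
    """Water temperature (degC) at minute ``t`` of a linear ramp."""
    if t < 0:
        raise DomainError(f"time on ramp must be >= 0 min, got {t}")
    return ramp.start_temp + ramp.rate * t


def time_for(ramp: RampSchedule, temp: float) -> float:
    """Minutes on the ramp at which ``temp`` is reached (inverse of
    :func:`temperature_at`)."""
    if temp < ramp.start_temp:
        raise DomainError(
            f"temperature {temp} degC is below the ramp start {ramp.start_temp} degC")
    return (temp - ramp.start_temp) / ramp.rate


def ctm_values(trial: CTMTrial) -> pd.DataFrame:
    """Per-fish CTmax for one trial: ``(fish_id, ctm_C)``.

    An event carrying a time is converted through the ramp; a recorded
    temperature passes through unchanged.
    """
    rows = []
    for ev in trial.events:
        if ev.loe_time_min is not None:
            ctm = temperature_at(trial.ramp, ev.loe_time_min)
        else:
            ctm = ev.loe_temp
        rows.append({"trial_id": trial.trial_id, "fish_id": ev.fish_id, "ctm_C": ctm})
    return pd.DataFrame(rows, columns=["trial_id", "fish_id", "ctm_C"])


def ctm_table(trials: list[CTMTrial]) -> pd.DataFrame:
    """CTmax values pooled over trials, joinable to fish metadata by fish_id."""
    if not trials:
        raise DataError("no trials supplied")
    return pd.concat([ctm_values(tr) for tr in trials], ignore_index=True)


def events_to_trials(events: pd.DataFrame) -> list[CTMTrial]:
    """Rebuild trial objects from the flat events table written by the
    generator (columns: trial_id, fish_id, start_temp_C, ramp_rate_C_per_min,
    and loe_time_min and/or loe_temp_C)."""
    from .workflow import check_columns
    check_columns(events, {"trial_id", "fish_id", "start_temp_C",
                           "ramp_rate_C_per_min"}, "ctm events")
    has_time = "loe_time_min" in events.columns
    has_temp = "loe_temp_C" in events.columns
    if not has_time and not has_temp:
        raise DataError("ctm events: need a loe_time_min or loe_temp_C column")
    trials = []
    for trial_id, grp in events.groupby("trial_id", sort=False):
        ramp = RampSchedule(start_temp=float(grp["start_temp_C"].iloc[0]),
                            rate=float(grp["ramp_rate_C_per_min"].iloc[0]))
        evs = []
        for _, row in grp.iterrows():
            t = row["loe_time_min"] if has_time and pd.notna(row.get("loe_time_min")) else None
            temp = row["loe_temp_C"] if has_temp and pd.notna(row.get("loe_temp_C")) else None
            evs.append(LOEEvent(fish_id=row["fish_id"],
                                loe_time_min=None if t is None else float(t),
                                loe_temp=None if temp is None else float(temp)))
        trials.append(CTMTrial(trial_id=str(trial_id), ramp=ramp, events=evs))
    return trials
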