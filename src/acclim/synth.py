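"""Synthetic study generator.

Emulates the raw material of a 4-population x 4-acclimation-temperature
common-garden thermal physiology study so that every downstream stage
(trace reduction, CTmax extraction, factorial inference) can be exercised and
calibrated without any field data:

* cohorts of fish with log-normal body masses around per-cell targets and fork
  lengths derived from per-cell Fulton condition factors,
* closed-phase dissolved-oxygen traces declining linearly at the rate implied
  by the fish's oxygen consumption plus a bacterial background term,
* post-exhaustion recovery series following MO2(t) = MMR + beta1 * ln(t)
  sampled as eight 5-min windows alternating with 5-min flushes over 75 min,
* constant-ramp thermal challenge trials with Gaussian loss-of-equilibrium
  temperatures per acclimation group.

All draws flow through one ``numpy.random.Generator`` seeded explicitly, so
identical config + seed reproduces every study bit for bit.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .config import GeneratorConfig
from .errors import ConfigError, DataError, GeometryError, ParameterError
from .records import BLANK_ID, CTMTrial, FishRecord, LOEEvent, RampSchedule, RecoverySeries, O2Trace

__all__ = [
    "build_cohort", "cohort_frame", "simulate_closed_trace",
    "simulate_recovery_series", "simulate_ctm_cohort",
    "simulate_respirometry_study", "simulate_ctm_study", "true_metabolic_rates",
]


def build_cohort(config: GeneratorConfig, seed: int, id_prefix: str = "F") -> list[FishRecord]:
    """Draw one fish per design slot.

    Masses are log-normal around the cell mean with CV ``mass_cv``; fork
    length inverts Fulton's condition factor, L = (100 m / K)^(1/3), with the
    cell's K target plus Gaussian noise. Fish alternate between the two
    replicate acclimation tanks of their temperature.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    fish: list[FishRecord] = []
    idx = 0
    for temp in config.acclimation_temps:
        for pop in config.populations:
            n = config.n_per_cell[temp][pop]
            mean = config.mass_mean_by_cell[temp][pop]
            sigma = math.sqrt(math.log1p(config.mass_cv**2))
            mu = math.log(mean) - sigma**2 / 2.0
            masses = rng.lognormal(mu, sigma, n)
            ks = config.condition_by_cell[temp][pop] + rng.normal(0.0, config.condition_sd, n)
            ks = np.clip(ks, 0.5, None)
            lengths = (100.0 * masses / ks) ** (1.0 / 3.0)
            for i in range(n):
                idx += 1
                fish.append(FishRecord(
                    fish_id=f"{id_prefix}{idx:04d}",
                    population=pop,
                    acclimation_temp=float(temp),
                    mass=float(masses[i]),
                    fork_length=float(lengths[i]),
                    tank=f"T{temp:g}{'ab'[i % 2]}",
                ))
    return fish


def cohort_frame(cohort: list[FishRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "fish_id": f.fish_id, "population": f.population,
        "acclimation_temp": f.acclimation_temp, "mass": f.mass,
        "fork_length": f.fork_length, "tank": f.tank,
    } for f in cohort])


def true_metabolic_rates(cohort: list[FishRecord], config: GeneratorConfig,
                         seed: int) -> pd.DataFrame:
    """Per-fish latent truth: RMR, MMR (with between-fish biological scatter)
    and the acclimation group's recovery slope. Scope is emergent (MMR - RMR),
    so only the RMR and MMR allometries are imposed."""
    rng = np.random.default_rng(seed)
    rows = []
    for f in cohort:
        rmr = config.true_rmr(f.mass, f.acclimation_temp)
        mmr = config.true_mmr(f.mass, f.acclimation_temp)
        if config.rmr_cv > 0:
            rmr *= _lognormal_factor(rng, config.rmr_cv)
        if config.mmr_cv > 0:
            mmr *= _lognormal_factor(rng, config.mmr_cv)
        # keep the latent ordering physiological: MMR strictly above RMR
        mmr = max(mmr, rmr * 1.05)
        rows.append({
            "fish_id": f.fish_id, "true_rmr": rmr, "true_mmr": mmr,
            "true_recovery_slope": config.recovery_log_slope_by_acclimation[f.acclimation_temp],
        })
    return pd.DataFrame(rows)


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    sigma = math.sqrt(math.log1p(cv**2))
    return float(rng.lognormal(-sigma**2 / 2.0, sigma))


def simulate_closed_trace(true_mo2: float, fish: FishRecord | None,
                          config: GeneratorConfig, seed: int | None = None,
                          *, window_id: str = "w1",
                          rng: np.random.Generator | None = None) -> O2Trace:
    """One closed-phase O2 trace for a fish consuming ``true_mo2`` mg O2/h.

    The decline rate inverts the respirometry formula: MO2 / ((V - Vm) * 60)
    mg l^-1 min^-1, plus the bacterial ``background_slope``. ``fish=None``
    produces a blank (background-only) chamber trace with the sentinel id.
    """
    if true_mo2 < 0:
        raise ParameterError(f"true_mo2 must be >= 0 mg O2/h, got {true_mo2}")
    v = config.chamber_volume
    vm = config.fish_volume_l(fish.mass) if fish is not None else 0.0
    if vm >= v:
        raise GeometryError(f"fish volume {vm} l must be below chamber volume {v} l")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = int(round(config.measure_min * 60.0 / config.sample_interval_s)) + 1
    t = np.arange(n) * config.sample_interval_s / 60.0
    rate = true_mo2 / ((v - vm) * 60.0) + config.background_slope
    o2 = config.o2_start - rate * t
    if config.trace_noise_sd > 0:
        o2 = o2 + rng.normal(0.0, config.trace_noise_sd, n)
    return O2Trace(
        fish_id=fish.fish_id if fish is not None else BLANK_ID,
        window_id=window_id, time_min=t, o2_mg_per_l=o2,
        chamber_volume=v, fish_volume=vm,
    )


def simulate_recovery_series(fish: FishRecord, mmr_true: float,
                             config: GeneratorConfig, seed: int | None = None,
                             *, rmr_floor: float | None = None,
                             recovery_slope: float | None = None,
                             rng: np.random.Generator | None = None) -> RecoverySeries:
    """Post-exhaustion MO2 windows following MMR + beta1 * ln(t).

    ``t`` is the window midpoint in minutes since chamber re-entry (2.5, 12.5,
    ..., 72.5 at defaults). Values are floored at the fish's routine rate so
    late recovery never undershoots rest. Multiplicative Gaussian noise with
    CV ``recovery_noise_cv`` is applied per window.
    """
    if mmr_true <= 0:
        raise ParameterError(f"mmr_true must be > 0 mg O2/h, got {mmr_true}")
    if rng is None:
        rng = np.random.default_rng(seed)
    beta1 = (config.recovery_log_slope_by_acclimation[fish.acclimation_temp]
             if recovery_slope is None else recovery_slope)
    if beta1 > 0:
        raise ParameterError(f"recovery slope must be <= 0, got {beta1}")
    if rmr_floor is None:
        rmr_floor = config.true_rmr(fish.mass, fish.acclimation_temp)
    mid = config.recovery_midpoints()
    mo2 = mmr_true + beta1 * np.log(mid)
    if config.recovery_noise_cv > 0:
        mo2 = mo2 * (1.0 + rng.normal(0.0, config.recovery_noise_cv, mid.size))
    mo2 = np.maximum(mo2, rmr_floor)
    chase = max(float(rng.normal(config.chase_duration_mean_min,
                                 config.chase_duration_sd_min)), 0.5)
    return RecoverySeries(
        fish_id=fish.fish_id, midpoint_min=mid, mo2_mg_per_h=mo2,
        chase_duration=chase, transfer_delay=config.transfer_delay_min,
    )


def simulate_ctm_cohort(cohort: list[FishRecord], config: GeneratorConfig,
                        seed: int, max_retries: int = 100) -> list[CTMTrial]:
    """Thermal-challenge trials for a cohort.

    Fish sharing an acclimation temperature are interleaved across populations
    and grouped into trials of at most ``ctm_trial_capacity`` (mirroring the
    two mixed-population challenge tanks); each trial ramps from the group's
    acclimation temperature at ``ramp_rate``. Per fish, the loss-of-
    equilibrium temperature is Normal(group mean, ctm_sd), redrawn (bounded)
    if it falls at or below the start temperature.
    """
    if not cohort:
        raise DataError("cohort must be nonempty")
    config.validate()
    rng = np.random.default_rng(seed)
    trials: list[CTMTrial] = []
    for temp in config.acclimation_temps:
        group = [f for f in cohort if f.acclimation_temp == temp]
        if not group:
            continue
        # round-robin across populations so tanks mix populations evenly
        by_pop = [[f for f in group if f.population == p] for p in config.populations]
        ordered: list[FishRecord] = []
        i = 0
        while any(by_pop):
            for lst in by_pop:
                if i < len(lst):
                    ordered.append(lst[i])
            if all(i >= len(lst) for lst in by_pop):
                break
            i += 1
        ramp = RampSchedule(start_temp=float(temp), rate=config.ramp_rate)
        mean = config.ctm_mean_by_acclimation[temp]
        for k in range(0, len(ordered), config.ctm_trial_capacity):
            chunk = ordered[k:k + config.ctm_trial_capacity]
            events = []
            for f in chunk:
                loe_temp = None
                for _ in range(max_retries):
                    draw = float(rng.normal(mean, config.ctm_sd))
                    if draw > ramp.start_temp:
                        loe_temp = draw
                        break
                if loe_temp is None:
                    raise ConfigError(
                        f"ctm_mean_by_acclimation[{temp:g}]: cannot draw a loss-of-"
                        f"equilibrium temperature above the start temperature {temp:g}")
                events.append(LOEEvent(
                    fish_id=f.fish_id,
                    loe_time_min=(loe_temp - ramp.start_temp) / ramp.rate,
                ))
            trials.append(CTMTrial(
                trial_id=f"CT{temp:g}-{k // config.ctm_trial_capacity + 1}",
                ramp=ramp, events=events))
    return trials


# ---------------------------------------------------------------------------
# whole-study simulators (DataFrame products consumed by the pipeline)
# ---------------------------------------------------------------------------

def simulate_respirometry_study(config: GeneratorConfig, seed: int) -> dict:
    """Generate a complete metabolic-rate study.

    Returns a dict of DataFrames: ``fish`` (metadata), ``traces`` (closed-
    phase RMR windows), ``blanks`` (daily background traces per chamber),
    ``recovery`` (post-exhaustion window MO2), and ``truth`` (latent per-fish
    rates, for calibration checks only -- the pipeline never reads it).

    Fish are assigned round-robin to ``n_chambers`` chambers, four per day;
    each (chamber, day) has one blank trace measured after the trials.
    """
    config.validate()
    ss = np.random.SeedSequence(seed)
    s_cohort, s_truth, s_trace, s_blank, s_recov = [
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(5)]

    cohort = build_cohort(config, s_cohort, id_prefix="R")
    fish_df = cohort_frame(cohort)
    truth = true_metabolic_rates(cohort, config, s_truth)
    truth_map = truth.set_index("fish_id")

    trace_rng = np.random.default_rng(s_trace)
    recov_rng = np.random.default_rng(s_recov)
    blank_rng = np.random.default_rng(s_blank)

    trace_parts, recov_parts = [], []
    chamber_day = {}
    for i, f in enumerate(cohort):
        chamber = i % config.n_chambers
        day = i // config.n_chambers
        chamber_day[f.fish_id] = (chamber, day)
        t_rmr = float(truth_map.loc[f.fish_id, "true_rmr"])
        t_mmr = float(truth_map.loc[f.fish_id, "true_mmr"])
        beta1 = float(truth_map.loc[f.fish_id, "true_recovery_slope"])
        for w in range(config.n_rmr_windows):
            tr = simulate_closed_trace(t_rmr, f, config, rng=trace_rng,
                                       window_id=f"rmr{w + 1}")
            trace_parts.append(pd.DataFrame({
                "fish_id": tr.fish_id, "window_id": tr.window_id,
                "time_min": tr.time_min, "o2_mg_per_l": tr.o2_mg_per_l,
                "temp_C": f.acclimation_temp, "chamber": chamber, "day": day,
            }))
        series = simulate_recovery_series(f, t_mmr, config, rng=recov_rng,
                                          rmr_floor=t_rmr, recovery_slope=beta1)
        recov_parts.append(pd.DataFrame({
            "fish_id": series.fish_id,
            "window_index": np.arange(1, series.midpoint_min.size + 1),
            "midpoint_min": series.midpoint_min,
            "mo2_mg_per_h": series.mo2_mg_per_h,
            "chase_duration_min": series.chase_duration,
            "transfer_delay_min": series.transfer_delay,
        }))

    blank_parts = []
    n_days = (len(cohort) + config.n_chambers - 1) // config.n_chambers
    for day in range(n_days):
        for chamber in range(config.n_chambers):
            tr = simulate_closed_trace(0.0, None, config, rng=blank_rng,
                                       window_id=f"blank-c{chamber}-d{day}")
            blank_parts.append(pd.DataFrame({
                "chamber": chamber, "day": day,
                "time_min": tr.time_min, "o2_mg_per_l": tr.o2_mg_per_l,
            }))

    return {
        "fish": fish_df,
        "traces": pd.concat(trace_parts, ignore_index=True),
        "blanks": pd.concat(blank_parts, ignore_index=True),
        "recovery": pd.concat(recov_parts, ignore_index=True),
        "truth": truth,
        "chamber_day": chamber_day,
        "config": config,
        "seed": seed,
    }


def simulate_ctm_study(config: GeneratorConfig, seed: int) -> dict:
    """Generate a complete thermal-challenge study (cohort + trial events)."""
    config.validate()
    ss = np.random.SeedSequence(seed)
    s_cohort, s_trials = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2)]
    cohort = build_cohort(config, s_cohort, id_prefix="C")
    trials = simulate_ctm_cohort(cohort, config, s_trials)
    events = pd.DataFrame([{
        "trial_id": tr.trial_id, "fish_id": ev.fish_id,
        "start_temp_C": tr.ramp.start_temp,
        "ramp_rate_C_per_min": tr.ramp.rate,
        "loe_time_min": ev.loe_time_min,
    } for tr in trials for ev in tr.events])
    return {
        "fish": cohort_frame(cohort), "trials": trials, "events": events,
        "config": config, "seed": seed,
    }
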