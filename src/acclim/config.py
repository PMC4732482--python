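"""Generator and run configuration.

A :class:`GeneratorConfig` describes one cohort-level study: the factorial
design (populations x acclimation temperatures and per-cell counts), the body
size and condition targets per cell, the metabolic calibration (whole-animal
RMR/MMR at the reference mass per acclimation temperature plus allometric mass
exponents), the post-exhaustion recovery curve, the closed-phase trace
geometry/noise, and the thermal-challenge ramp.

Two presets ship with the package:

``default_respirometry_config()``
    The 158-fish metabolic-rate design (two cells of 9, fourteen of 10) with
    the heavier ~85-120 g fish measured in the 1.1 l chambers.

``default_ctm_config()``
    The 160-fish thermal-challenge design (10 fish per population per
    acclimation temperature) with the smaller ~35-60 g fish and loss-of-
    equilibrium temperature anchors of 26.1 / 26.6 / 28.1 / 28.9 degC for the
    8 / 11 / 15 / 19 degC acclimation groups.

All dictionaries keyed "by cell" are nested ``{acclimation_temp: {population:
value}}``; dictionaries keyed "by acclimation" are flat ``{acclimation_temp:
value}``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigError

POPULATIONS = ["Myrt Lake", "Lake Louisa", "Opeongo Lake", "Lake Manitou"]
ACCLIMATION_TEMPS = [8.0, 11.0, 15.0, 19.0]

#: reference body mass (g) at which calibrated metabolic rates are specified
#: and to which adjusted means are corrected (overall cohort mean mass).
REFERENCE_MASS_G = 108.6


def _by_cell(values: dict[float, list[float]]) -> dict[float, dict[str, float]]:
    return {t: dict(zip(POPULATIONS, row)) for t, row in values.items()}


# Realized per-cell sample sizes of the metabolic-rate design (N column of the
# cohort table, respirometry side): Myrt Lake lost one fish at 8 and 11 degC.
RESPIROMETRY_N = _by_cell({8.0: [9, 10, 10, 10], 11.0: [9, 10, 10, 10],
                           15.0: [10, 10, 10, 10], 19.0: [10, 10, 10, 10]})
# Cell mean body mass (g) and Fulton condition factor targets, respirometry side.
RESPIROMETRY_MASS = _by_cell({8.0: [116.9, 114.4, 111.4, 112.3],
                              11.0: [111.7, 116.5, 115.9, 120.7],
                              15.0: [116.5, 120.8, 111.7, 115.2],
                              19.0: [88.8, 84.3, 98.5, 84.1]})
RESPIROMETRY_K = _by_cell({8.0: [1.3, 1.2, 1.2, 1.1],
                           11.0: [1.2, 1.2, 1.2, 1.1],
                           15.0: [1.4, 1.2, 1.3, 1.2],
                           19.0: [1.4, 1.3, 1.4, 1.2]})

# Thermal-challenge side: 10 fish per population per acclimation temperature.
CTM_N = _by_cell({t: [10, 10, 10, 10] for t in ACCLIMATION_TEMPS})
CTM_MASS = _by_cell({8.0: [58.6, 52.0, 54.0, 51.7],
                     11.0: [53.0, 52.9, 59.9, 53.3],
                     15.0: [52.2, 33.7, 48.0, 46.2],
                     19.0: [47.0, 44.1, 51.5, 43.2]})
CTM_K = _by_cell({8.0: [1.1, 1.1, 1.1, 1.0],
                  11.0: [1.2, 1.2, 1.1, 1.1],
                  15.0: [1.2, 1.1, 1.2, 1.0],
                  19.0: [1.2, 1.1, 1.2, 1.1]})

# Mean loss-of-equilibrium temperature (degC) per acclimation group. The 8 and
# 19 degC anchors sit mid-way in the observed 26.0-26.2 and 28.7-29.1 degC
# population bands; 11 and 15 degC are placed so the 11->15 step is ~1.5 degC.
DEFAULT_CTM_MEANS = {8.0: 26.1, 11.0: 26.6, 15.0: 28.1, 19.0: 28.9}

# Whole-animal metabolic rates (mg O2/h) of a reference-mass (108.6 g) fish per
# acclimation temperature. The 8 degC RMR equals the mass-specific anchor of
# 48.41 mg O2 kg^-1 h^-1 x 0.1086 kg; RMR rises ~2.5-3x to 19 degC, MMR peaks
# at 15 degC and declines above it, so aerobic scope collapses at 19 degC.
DEFAULT_RMR_REF = {8.0: 5.257, 11.0: 8.2, 15.0: 12.3, 19.0: 13.4}
DEFAULT_MMR_REF = {8.0: 35.0, 11.0: 38.5, 15.0: 42.0, 19.0: 34.0}

# Logarithmic recovery slope beta1 (mg O2/h per ln-minute); 19 degC-acclimated
# fish repay the post-exercise oxygen debt more slowly (smaller magnitude).
DEFAULT_RECOVERY_SLOPE = {8.0: -3.8, 11.0: -4.0, 15.0: -4.4, 19.0: -2.6}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic study generator. See module docstring."""

    populations: list[str] = field(default_factory=lambda: list(POPULATIONS))
    acclimation_temps: list[float] = field(default_factory=lambda: list(ACCLIMATION_TEMPS))
    n_per_cell: dict[float, dict[str, int]] = field(
        default_factory=lambda: _copy_cells(RESPIROMETRY_N))
    mass_mean_by_cell: dict[float, dict[str, float]] = field(
        default_factory=lambda: _copy_cells(RESPIROMETRY_MASS))
    mass_cv: float = 0.12
    condition_by_cell: dict[float, dict[str, float]] = field(
        default_factory=lambda: _copy_cells(RESPIROMETRY_K))
    condition_sd: float = 0.04

    # thermal challenge
    ctm_mean_by_acclimation: dict[float, float] = field(
        default_factory=lambda: dict(DEFAULT_CTM_MEANS))
    ctm_sd: float = 0.5
    ramp_rate: float = 0.17  # degC/min
    ctm_trial_capacity: int = 20  # fish per challenge tank

    # metabolic calibration (whole-animal rates at reference_mass, mg O2/h)
    rmr_ref: dict[float, float] = field(default_factory=lambda: dict(DEFAULT_RMR_REF))
    mmr_ref: dict[float, float] = field(default_factory=lambda: dict(DEFAULT_MMR_REF))
    rmr_mass_exponent: float = 1.12
    mmr_mass_exponent: float = 0.82
    rmr_cv: float = 0.08  # between-fish biological CV
    mmr_cv: float = 0.08
    reference_mass: float = REFERENCE_MASS_G

    # post-exhaustion recovery
    recovery_log_slope_by_acclimation: dict[float, float] = field(
        default_factory=lambda: dict(DEFAULT_RECOVERY_SLOPE))
    recovery_noise_cv: float = 0.05
    n_recovery_windows: int = 8
    measure_min: float = 5.0
    flush_min: float = 5.0
    chase_duration_mean_min: float = 4.75
    chase_duration_sd_min: float = 0.25
    transfer_delay_min: float = 0.2

    # closed-phase traces
    chamber_volume: float = 1.1  # l
    fish_density: float = 1.0  # g/ml, converts mass to displaced volume
    o2_start: float = 9.0  # mg/l at the start of a closed phase
    trace_noise_sd: float = 0.005  # mg/l
    background_slope: float = 0.002  # mg/l/min bacterial O2 consumption
    sample_interval_s: float = 5.0
    n_rmr_windows: int = 3
    n_chambers: int = 4

    seed: int = 0

    # -- validation ---------------------------------------------------------
    def validate(self) -> "GeneratorConfig":
        if not self.populations:
            raise ConfigError("populations: must list at least one population")
        if len(set(self.populations)) != len(self.populations):
            raise ConfigError("populations: labels must be unique")
        if not self.acclimation_temps:
            raise ConfigError("acclimation_temps: must list at least one temperature")
        for t in self.acclimation_temps:
            for p in self.populations:
                n = self._cell(self.n_per_cell, t, p, "n_per_cell")
                if n < 1:
                    raise ConfigError(f"n_per_cell[{t:g}][{p}]: counts must be >= 1, got {n}")
                if self._cell(self.mass_mean_by_cell, t, p, "mass_mean_by_cell") <= 0:
                    raise ConfigError(f"mass_mean_by_cell[{t:g}][{p}]: must be > 0 g")
                if self._cell(self.condition_by_cell, t, p, "condition_by_cell") <= 0:
                    raise ConfigError(f"condition_by_cell[{t:g}][{p}]: must be > 0")
        for name, d in (("ctm_mean_by_acclimation", self.ctm_mean_by_acclimation),
                        ("rmr_ref", self.rmr_ref), ("mmr_ref", self.mmr_ref),
                        ("recovery_log_slope_by_acclimation",
                         self.recovery_log_slope_by_acclimation)):
            for t in self.acclimation_temps:
                if t not in d:
                    raise ConfigError(f"{name}: missing entry for {t:g} degC")
        for t in self.acclimation_temps:
            if self.mmr_ref[t] <= self.rmr_ref[t]:
                raise ConfigError(
                    f"mmr_ref[{t:g}]: MMR ({self.mmr_ref[t]}) must exceed RMR "
                    f"({self.rmr_ref[t]}) at every acclimation temperature")
            if self.recovery_log_slope_by_acclimation[t] > 0:
                raise ConfigError(
                    f"recovery_log_slope_by_acclimation[{t:g}]: must be <= 0")
        if self.chamber_volume <= 0:
            raise ConfigError("chamber_volume: must be > 0 l")
        if self.fish_density <= 0:
            raise ConfigError("fish_density: must be > 0 g/ml")
        if self.ramp_rate <= 0:
            raise ConfigError("ramp_rate: must be > 0 degC/min")
        if self.ctm_trial_capacity < 1:
            raise ConfigError("ctm_trial_capacity: must be >= 1")
        if self.n_recovery_windows < 1 or self.n_rmr_windows < 1 or self.n_chambers < 1:
            raise ConfigError("window/chamber counts must be >= 1")
        if self.measure_min <= 0 or self.flush_min < 0:
            raise ConfigError("measure_min must be > 0 and flush_min >= 0")
        if self.sample_interval_s <= 0:
            raise ConfigError("sample_interval_s: must be > 0")
        for name in ("mass_cv", "condition_sd", "ctm_sd", "rmr_cv", "mmr_cv",
                     "recovery_noise_cv", "trace_noise_sd", "background_slope",
                     "chase_duration_sd_min"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name}: must be >= 0")
        if self.reference_mass <= 0:
            raise ConfigError("reference_mass: must be > 0 g")
        if self.chase_duration_mean_min <= 0:
            raise ConfigError("chase_duration_mean_min: must be > 0")
        if self.transfer_delay_min < 0:
            raise ConfigError("transfer_delay_min: must be >= 0")
        if self.o2_start <= 0:
            raise ConfigError("o2_start: must be > 0 mg/l")
        return self

    @staticmethod
    def _cell(d: dict, t: float, p: str, name: str):
        try:
            return d[t][p]
        except KeyError as exc:
            raise ConfigError(f"{name}: missing entry for cell ({t:g} degC, {p})") from exc

    # -- derived quantities --------------------------------------------------
    @property
    def recovery_span_min(self) -> float:
        """Total span of the alternating measure/flush recovery schedule."""
        return (self.n_recovery_windows * self.measure_min
                + (self.n_recovery_windows - 1) * self.flush_min)

    def recovery_midpoints(self):
        import numpy as np
        period = self.measure_min + self.flush_min
        return np.arange(self.n_recovery_windows) * period + self.measure_min / 2.0

    def n_planned(self) -> int:
        """Total fish enumerated by the design."""
        return sum(self.n_per_cell[t][p]
                   for t in self.acclimation_temps for p in self.populations)

    def fish_volume_l(self, mass_g: float) -> float:
        return mass_g / (self.fish_density * 1000.0)

    def true_rmr(self, mass_g: float, acclimation_temp: float) -> float:
        """Expected whole-animal RMR (mg O2/h) from the allometric calibration."""
        return self.rmr_ref[acclimation_temp] * (
            mass_g / self.reference_mass) ** self.rmr_mass_exponent

    def true_mmr(self, mass_g: float, acclimation_temp: float) -> float:
        return self.mmr_ref[acclimation_temp] * (
            mass_g / self.reference_mass) ** self.mmr_mass_exponent

    # -- serialisation -------------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "GeneratorConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration fields: {sorted(unknown)}")
        cfg = cls(**{k: _coerce_keys(k, v) for k, v in d.items()})
        return cfg.validate()

    def copy(self, **updates) -> "GeneratorConfig":
        return replace(self, **updates)


def _copy_cells(d: dict[float, dict[str, Any]]) -> dict[float, dict[str, Any]]:
    return {t: dict(row) for t, row in d.items()}


_TEMP_KEYED = {"n_per_cell", "mass_mean_by_cell", "condition_by_cell",
               "ctm_mean_by_acclimation", "rmr_ref", "mmr_ref",
               "recovery_log_slope_by_acclimation"}


def _coerce_keys(name: str, value: Any) -> Any:
    """YAML round-trips float dict keys as numbers or strings; normalise."""
    if name == "acclimation_temps":
        return [float(v) for v in value]
    if name in _TEMP_KEYED and isinstance(value, dict):
        return {float(k): (dict(v) if isinstance(v, dict) else v) for k, v in value.items()}
    return value


def default_respirometry_config(**updates) -> GeneratorConfig:
    """The default 158-fish metabolic-rate study."""
    return GeneratorConfig(**updates).validate() if updates else GeneratorConfig().validate()


def default_ctm_config(**updates) -> GeneratorConfig:
    """The default 160-fish thermal-challenge study."""
    cfg = GeneratorConfig(
        n_per_cell=_copy_cells(CTM_N),
        mass_mean_by_cell=_copy_cells(CTM_MASS),
        condition_by_cell=_copy_cells(CTM_K),
    )
    if updates:
        cfg = cfg.copy(**updates)
    return cfg.validate()


@dataclass
class RunConfig:
    """End-to-end pipeline options on top of the two generator presets."""

    respirometry: GeneratorConfig = field(default_factory=default_respirometry_config)
    ctm: GeneratorConfig = field(default_factory=default_ctm_config)
    eval_time: float = 1.0  # min; where the recovery curve is read off as MMR
    reference_mass: float = REFERENCE_MASS_G  # g, covariate value for adjusted means
    alpha: float = 0.05
    ss_type: int = 1  # sequential sums of squares by default
    seed: int = 0

    def validate(self) -> "RunConfig":
        self.respirometry.validate()
        self.ctm.validate()
        if self.eval_time <= 0:
            raise ConfigError("eval_time: must be > 0 min")
        if self.reference_mass <= 0:
            raise ConfigError("reference_mass: must be > 0 g")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha: must be in (0, 1)")
        if self.ss_type not in (1, 3):
            raise ConfigError("ss_type: must be 1 (sequential) or 3 (partial)")
        return self

    def to_dict(self) -> dict[str, Any]:
        return {"respirometry": self.respirometry.to_dict(), "ctm": self.ctm.to_dict(),
                "eval_time": self.eval_time, "reference_mass": self.reference_mass,
                "alpha": self.alpha, "ss_type": self.ss_type, "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        resp = d.pop("respirometry", None)
        ctm = d.pop("ctm", None)
        known = {"eval_time", "reference_mass", "alpha", "ss_type", "seed"}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown run configuration fields: {sorted(unknown)}")
        cfg = cls(
            respirometry=(GeneratorConfig.from_dict(resp) if resp
                          else default_respirometry_config()),
            ctm=GeneratorConfig.from_dict(ctm) if ctm else default_ctm_config(),
            **d,
        )
        return cfg.validate()


def config_sha(config: GeneratorConfig | RunConfig) -> str:
    """Short stable digest of a configuration, stamped into every output."""
    payload = json.dumps(config.to_dict(), sort_keys=True, default=float)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_run_config(path: str | Path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    return RunConfig.from_dict(data)


def save_run_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
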