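"""Core record types shared across the pipeline stages.

These are deliberately small frozen-ish dataclasses: one fish, one closed-phase
oxygen trace, one post-exhaustion recovery series, one temperature-ramp trial.
Tabular collections of them travel as pandas DataFrames (see
:mod:`acclim.workflow` for the CSV schemas).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, GeometryError

#: sentinel fish id used by blank (no-fish, background-only) traces
BLANK_ID = "BLANK"


@dataclass
class FishRecord:
    """One animal in the factorial design."""

    fish_id: str
    population: str
    acclimation_temp: float  # degC
    mass: float  # g
    fork_length: float  # cm
    tank: str

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise DataError(f"fish {self.fish_id}: mass must be > 0 g")
        if self.fork_length <= 0:
            raise DataError(f"fish {self.fish_id}: fork_length must be > 0 cm")

    @property
    def volume_l(self) -> float:
        """Body volume in litres assuming unit tissue density (1 g/ml)."""
        return self.mass / 1000.0


@dataclass
class O2Trace:
    """One closed-phase measurement: dissolved O2 versus time.

    ``time_min`` is minutes since the flush pump was switched off;
    ``o2_mg_per_l`` is the dissolved oxygen concentration.
    """

    fish_id: str
    window_id: str
    time_min: np.ndarray
    o2_mg_per_l: np.ndarray
    chamber_volume: float  # l
    fish_volume: float  # l

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.o2_mg_per_l = np.asarray(self.o2_mg_per_l, dtype=float)
        if self.time_min.size != self.o2_mg_per_l.size:
            raise DataError(f"trace {self.fish_id}/{self.window_id}: time and O2 differ in length")
        if self.time_min.size < 3:
            raise DataError(f"trace {self.fish_id}/{self.window_id}: needs >= 3 samples")
        if np.any(np.diff(self.time_min) <= 0):
            raise DataError(f"trace {self.fish_id}/{self.window_id}: times must strictly increase")
        if self.fish_volume < 0 or self.chamber_volume <= self.fish_volume:
            raise GeometryError(
                f"trace {self.fish_id}/{self.window_id}: require chamber volume "
                f"{self.chamber_volume} l > fish volume {self.fish_volume} l >= 0"
            )


@dataclass
class SlopeFit:
    """Least-squares line through an O2 trace.

    ``decline_rate`` is the negated fitted slope (mg O2 l^-1 min^-1); it is
    negative when oxygen *rose* during the window, in which case
    ``negative_decline`` flags the trace for QC instead of clamping.
    """

    decline_rate: float
    intercept: float
    r_squared: float
    n_points: int
    negative_decline: bool = False


@dataclass
class RecoverySeries:
    """Timed post-exhaustion oxygen consumption measurements for one fish."""

    fish_id: str
    midpoint_min: np.ndarray  # window midpoints, minutes since chamber re-entry
    mo2_mg_per_h: np.ndarray
    chase_duration: float = float("nan")  # min
    transfer_delay: float = float("nan")  # min

    def __post_init__(self) -> None:
        self.midpoint_min = np.asarray(self.midpoint_min, dtype=float)
        self.mo2_mg_per_h = np.asarray(self.mo2_mg_per_h, dtype=float)
        if self.midpoint_min.size != self.mo2_mg_per_h.size:
            raise DataError(f"recovery {self.fish_id}: midpoints and MO2 differ in length")
        if np.any(self.midpoint_min <= 0):
            raise DataError(f"recovery {self.fish_id}: midpoints must be > 0 min")
        if np.any(np.diff(self.midpoint_min) <= 0):
            raise DataError(f"recovery {self.fish_id}: midpoints must strictly increase")


@dataclass
class RecoveryFit:
    """Logarithmic recovery curve MO2 = beta0 + beta1 * ln(t)."""

    fish_id: str
    beta0: float  # mg O2/h at ln t = 0 (t = 1 min)
    beta1: float  # mg O2/h per ln-minute (<= 0 for a recovering fish)
    mmr_estimate: float  # curve evaluated at eval_time
    eval_time: float  # min
    r_squared: float


@dataclass
class PeakResult:
    """Highest post-chase measurement; earliest window wins ties."""

    fish_id: str
    value: float
    window_index: int


@dataclass
class RoutineMR:
    """Mean of the closed-phase MO2 estimates used as routine metabolic rate."""

    fish_id: str
    value: float
    n: int
    expected_n: int = 3

    @property
    def count_mismatch(self) -> bool:
        return self.n != self.expected_n


@dataclass
class MetabolicSummary:
    """Per-fish reduction: RMR, MMR, scope and recovery-rate statistic."""

    fish_id: str
    rmr: float
    mmr: float
    mmr_peak: float
    scope: float
    recovery_slope: float
    qc_flags: list[str] = field(default_factory=list)


@dataclass
class RampSchedule:
    """Constant-rate temperature ramp."""

    start_temp: float  # degC
    rate: float  # degC/min

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise DataError(f"ramp rate must be > 0 degC/min, got {self.rate}")


@dataclass
class LOEEvent:
    """Loss-of-equilibrium event: a time on the ramp, a temperature, or both."""

    fish_id: str
    loe_time_min: float | None = None
    loe_temp: float | None = None

    def __post_init__(self) -> None:
        if self.loe_time_min is None and self.loe_temp is None:
            raise DataError(f"event {self.fish_id}: needs a LOE time or temperature")
        if self.loe_time_min is not None and self.loe_time_min < 0:
            raise DataError(f"event {self.fish_id}: LOE time must be >= 0 min")


@dataclass
class CTMTrial:
    """One ramping trial with the fish that shared the challenge tank."""

    trial_id: str
    ramp: RampSchedule
    events: list[LOEEvent]

    def __post_init__(self) -> None:
        ids = [e.fish_id for e in self.events]
        if len(ids) != len(set(ids)):
            raise DataError(f"trial {self.trial_id}: at most one event per fish")
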