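"""Adaptive glove-pressure control strategy and a simulated training plant.

The controller maintains a predetermined muscle-activity intensity (e.g.
ECRL RMS = 1.5 V) by proportional pressure adjustment: the gap between the
setpoint and the measured EMG intensity is turned into a pressure command
for the pneumatic glove, clipped to the pump's 0-75 kPa working range.
On detected fatigue the pressure is additionally attenuated (default x0.8
per fatigue-confirmed step) and the setpoint ramped down, protecting the
muscle from over-training; in the excited state the proportional term is
free to strengthen assistance.

The human-plus-glove system is replaced by a minimal simulated plant: the
subject's intrinsic activity intensity decays multiplicatively with elapsed
time (training fatigue), and glove assistance adds linearly,

    measured = baseline0 * (1 - decay)^(t / 1 h) + assist_gain * pressure + noise.

With zero noise and decay the closed loop is the linear recurrence
``p <- p + g (s - b - a p)``; it converges for ``0 < g*a < 2`` to the fixed
point where the measured intensity equals the setpoint exactly. Defaults
put ``g*a = 0.5``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidParameterError
from .types import Status

__all__ = [
    "MAX_PRESSURE_KPA",
    "ControlState",
    "PlantState",
    "SessionTrace",
    "control_step",
    "plant_step",
    "run_session",
]

#: Working range of the pneumatic pump (kPa).
MAX_PRESSURE_KPA = 75.0


@dataclass
class ControlState:
    """Controller state: current command, target and tuning.

    ``gain`` is the proportional gain in kPa per volt of intensity error;
    ``fatigue_scale`` multiplies the pressure on each fatigue-confirmed
    step and ``setpoint_ramp`` is the fractional setpoint reduction applied
    at the same time.
    """

    pressure_cmd: float = 0.0
    setpoint: float = 1.5
    gain: float = 10.0
    fatigue_scale: float = 0.8
    setpoint_ramp: float = 0.10
    status: Status = Status.EXCITED

    def __post_init__(self):
        if not (0.0 <= self.pressure_cmd <= MAX_PRESSURE_KPA):
            raise InvalidParameterError(
                f"pressure_cmd must lie in [0, {MAX_PRESSURE_KPA}] kPa"
            )
        if self.gain <= 0:
            raise InvalidParameterError("gain must be positive")
        if not (0.0 < self.fatigue_scale <= 1.0):
            raise InvalidParameterError("fatigue_scale must lie in (0, 1]")
        if not (0.0 <= self.setpoint_ramp < 1.0):
            raise InvalidParameterError("setpoint_ramp must lie in [0, 1)")


@dataclass
class PlantState:
    """Simulated subject + glove: intrinsic intensity and assistance.

    ``decay_per_hour`` is the fractional loss of intrinsic intensity per
    hour of training (0.3 means the unassisted intensity falls to 70% after
    one hour); ``assist_gain`` converts glove pressure to added intensity.
    """

    baseline_intensity: float = 1.5
    decay_per_hour: float = 0.0
    assist_gain: float = 0.05
    noise_sd: float = 0.0
    elapsed_min: float = 0.0

    def __post_init__(self):
        if self.baseline_intensity < 0 or self.noise_sd < 0 or self.elapsed_min < 0:
            raise InvalidParameterError("plant fields must be nonnegative")
        if not (0.0 <= self.decay_per_hour < 1.0):
            raise InvalidParameterError("decay_per_hour must lie in [0, 1)")
        if self.assist_gain <= 0:
            raise InvalidParameterError("assist_gain must be positive")


@dataclass
class SessionTrace:
    """Per-step closed-loop records of one simulated session."""

    time_ms: list[float] = field(default_factory=list)
    measured_rms: list[float] = field(default_factory=list)
    pressure_cmd: list[float] = field(default_factory=list)
    status: list[Status] = field(default_factory=list)
    setpoint: list[float] = field(default_factory=list)

    def append(self, t, rms, p, st, sp):
        if self.time_ms and t <= self.time_ms[-1]:
            raise InvalidParameterError("trace times must be strictly increasing")
        self.time_ms.append(float(t))
        self.measured_rms.append(float(rms))
        self.pressure_cmd.append(float(p))
        self.status.append(Status(st))
        self.setpoint.append(float(sp))

    def __len__(self) -> int:
        return len(self.time_ms)

    def third_means(self) -> tuple[float, float, float]:
        """Mean measured intensity over the first/middle/final thirds."""
        x = np.asarray(self.measured_rms)
        n = x.size // 3
        return float(x[:n].mean()), float(x[n : 2 * n].mean()), float(x[-n:].mean())


def control_step(state: ControlState, measured_rms: float, status: Status | str) -> ControlState:
    """One proportional-control update.

    ``pressure += gain * (setpoint - measured)``; on fatigue the pressure
    is then scaled by ``fatigue_scale`` and the setpoint ramped down by
    ``setpoint_ramp``. The command is clipped to the pump range; clipping
    absorbs out-of-range requests rather than raising.
    """
    if measured_rms < 0:
        raise InvalidParameterError("measured RMS must be nonnegative")
    status = Status(status)
    pressure = state.pressure_cmd + state.gain * (state.setpoint - measured_rms)
    setpoint = state.setpoint
    if status is Status.FATIGUE:
        pressure *= state.fatigue_scale
        setpoint *= 1.0 - state.setpoint_ramp
    pressure = float(np.clip(pressure, 0.0, MAX_PRESSURE_KPA))
    return replace(state, pressure_cmd=pressure, setpoint=setpoint, status=status)


def plant_step(
    plant: PlantState,
    pressure_cmd: float,
    dt_min: float,
    rng: np.random.Generator | None = None,
) -> tuple[PlantState, float]:
    """Advance the simulated subject by ``dt_min`` and measure intensity.

    The intrinsic intensity decays by ``(1 - decay)^(dt / 60 min)`` so the
    hourly loss is exactly ``decay_per_hour`` regardless of step size; the
    measurement adds linear assistance and Gaussian sensor noise.
    """
    if dt_min <= 0:
        raise InvalidParameterError("dt must be positive")
    factor = (1.0 - plant.decay_per_hour) ** (dt_min / 60.0)
    new = replace(
        plant,
        baseline_intensity=plant.baseline_intensity * factor,
        elapsed_min=plant.elapsed_min + dt_min,
    )
    noise = float(rng.normal(0.0, plant.noise_sd)) if (rng is not None and plant.noise_sd > 0) else 0.0
    measured = new.baseline_intensity + new.assist_gain * pressure_cmd + noise
    return new, max(measured, 0.0)


def run_session(
    adaptive: bool,
    duration_min: float,
    plant: PlantState,
    control: ControlState,
    ecg_source: Status | str | "object" = Status.EXCITED,
    seed: int | np.random.Generator | None = None,
    step_s: float = 0.2,
    hrv_k: int = 10,
) -> SessionTrace:
    """Simulate a full training session, with or without adaptation.

    ``ecg_source`` is either a target status (``"excited"``/``"fatigue"``
    — an R-R series of that status is generated internally) or an existing
    :class:`~rehabsig.types.RRSeries`; the consecutive-beat fatigue rule is
    applied to its windowed HRV to produce the per-step status stream.
    When ``adaptive`` is false the pressure command is held at its initial
    constant and only the plant evolves. The default step cadence (0.2 s)
    matches the EMG feature rate of one 200-sample segment at 1 kHz.
    """
    from . import ecg as _ecg
    from . import fatigue as _fatigue
    from . import synth as _synth
    from .types import RRSeries

    if duration_min < 1:
        raise InvalidParameterError("duration must be at least 1 minute")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    duration_ms = duration_min * 60000.0
    if isinstance(ecg_source, RRSeries):
        rr = ecg_source
    else:
        status = Status(ecg_source)
        mean_rr = _synth.DEFAULT_MEAN_RR[status]
        n = int(np.ceil(duration_ms / mean_rr)) + hrv_k + 2
        intervals = _synth.gen_rr_series(status, n=n, mean_rr=mean_rr, seed=rng)
        rr = RRSeries(intervals=intervals, anchor_times=np.cumsum(intervals))
    stats = _ecg.hrv_windows(rr, k=hrv_k)
    fired, first = _fatigue.rule_fatigue(stats, _fatigue.FatigueRuleParams(k=hrv_k))
    # Status timeline: fatigue from the first window whose variation drops
    # below the rule threshold, evaluated at each window's anchor time.
    anchor_times = np.array([s.anchor_time_ms for s in stats])
    sub = np.array([s.variation < _fatigue.FatigueRuleParams(k=hrv_k).epsilon_ms for s in stats])

    def status_at(t_ms: float) -> Status:
        i = int(np.searchsorted(anchor_times, t_ms, side="right")) - 1
        if i < 0:
            return Status.EXCITED
        return Status.FATIGUE if sub[i] else Status.EXCITED

    trace = SessionTrace()
    state = control
    dt_min = step_s / 60.0
    n_steps = int(round(duration_min * 60.0 / step_s))
    t = 0.0
    for _ in range(n_steps):
        t += step_s * 1000.0
        plant, measured = plant_step(plant, state.pressure_cmd, dt_min, rng)
        st = status_at(t)
        if adaptive:
            state = control_step(state, measured, st)
        else:
            state = replace(state, status=st)
        trace.append(t, measured, state.pressure_cmd, st, state.setpoint)
    return trace
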