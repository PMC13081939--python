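"""Trapezoidal tilt-step stimulus: construction and segmentation.

The behavioral assay delivers pitch tilts with a trapezoidal velocity
profile: a constant-acceleration ramp up to a velocity plateau, then a
symmetric deceleration back to rest.  Each experiment is a fixed number of
cycles of four steps — nose-up away from the horizon, back to the horizon,
nose-down away, and back — with a dwell between steps so the eye settles
before the next tilt.

This module builds those protocols on a uniform sample grid and, inversely,
segments a recorded platform trace back into its constituent steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "StimulusParams",
    "PositionTrace",
    "StepSegment",
    "trapezoid_step",
    "build_session",
    "segment_steps",
]

#: Canonical ordering of the four steps within one stimulus cycle.
DEFAULT_STEP_ORDER = ("up_toward", "up_away", "down_toward", "down_away")


@dataclass(frozen=True)
class StimulusParams:
    """Parameters of the tilt-step protocol.

    Defaults reproduce the printed protocol: +/-15 deg steps with a
    trapezoidal velocity profile peaking at 35 deg/s, peak acceleration
    150 deg/s^2, 50 cycles of four steps, sampled at 200 Hz.

    ``hold_duration`` (dwell at each endpoint between steps) is a free
    protocol parameter; 7.5 s leaves ample time for responses to decay.
    """

    amplitude: float = 15.0          # deg, unsigned step size
    peak_velocity: float = 35.0      # deg/s
    peak_acceleration: float = 150.0  # deg/s^2
    n_cycles: int = 50
    steps_per_cycle: int = 4
    sample_rate: float = 200.0       # Hz
    hold_duration: float = 7.5       # s, dwell after each step
    step_order: tuple[str, ...] = DEFAULT_STEP_ORDER

    def __post_init__(self) -> None:
        for name in ("amplitude", "peak_velocity", "peak_acceleration",
                     "sample_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"StimulusParams.{name} must be > 0")
        if self.hold_duration < 0:
            raise ValueError("StimulusParams.hold_duration must be >= 0")
        if self.n_cycles < 1:
            raise ValueError("StimulusParams.n_cycles must be >= 1")
        if set(self.step_order) != set(DEFAULT_STEP_ORDER):
            raise ValueError(
                "StimulusParams.step_order must be a permutation of "
                f"{DEFAULT_STEP_ORDER}")
        _check_trapezoid(self.amplitude, self.peak_velocity,
                         self.peak_acceleration)


def _check_trapezoid(amplitude: float, v: float, a: float) -> None:
    """A trapezoid (not a triangle) requires amplitude >= v^2/a."""
    if amplitude < v ** 2 / a:
        raise ValueError(
            f"amplitude {amplitude} deg cannot reach peak_velocity {v} deg/s "
            f"at peak_acceleration {a} deg/s^2 (needs >= v^2/a = "
            f"{v ** 2 / a:.4g} deg): profile would be a triangle")


@dataclass(frozen=True)
class PositionTrace:
    """An angle time series on a uniform grid."""

    time: np.ndarray   # s
    angle: np.ndarray  # deg

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        a = np.asarray(self.angle, dtype=float)
        if t.shape != a.shape or t.ndim != 1:
            raise ValueError("time and angle must be 1-D arrays of equal length")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "angle", a)

    @property
    def sample_rate(self) -> float:
        dt = np.diff(self.time)
        if dt.size == 0:
            raise ValueError("trace has fewer than two samples")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("trace is not on a uniform time grid")
        return 1.0 / dt[0]

    def __len__(self) -> int:
        return self.time.size


@dataclass(frozen=True)
class StepSegment:
    """One tilt step located within a session trace."""

    onset_index: int
    offset_index: int        # first sample after the step's motion ends
    direction: str           # "nose_up" | "nose_down"
    phase: str               # "toward" | "away" (relative to the horizon)
    start_angle: float       # deg
    end_angle: float         # deg

    @property
    def displacement(self) -> float:
        return self.end_angle - self.start_angle


def _trapezoid_position(t: np.ndarray, amplitude: float, v: float,
                        a: float) -> np.ndarray:
    """Closed-form position of an unsigned trapezoidal-velocity step."""
    t_ramp = v / a
    t_plateau = (amplitude - v ** 2 / a) / v
    t_total = 2.0 * t_ramp + t_plateau
    pos = np.empty_like(t)
    # accelerating ramp
    m = t < t_ramp
    pos[m] = 0.5 * a * t[m] ** 2
    # plateau
    m = (t >= t_ramp) & (t < t_ramp + t_plateau)
    pos[m] = 0.5 * a * t_ramp ** 2 + v * (t[m] - t_ramp)
    # decelerating ramp
    m = (t >= t_ramp + t_plateau) & (t < t_total)
    td = t_total - t[m]
    pos[m] = amplitude - 0.5 * a * td ** 2
    pos[t >= t_total] = amplitude
    return pos


def step_duration(params: StimulusParams) -> float:
    """Total duration of one step: 2 v/a + (A - v^2/a)/v seconds."""
    v, a, A = params.peak_velocity, params.peak_acceleration, params.amplitude
    return 2.0 * v / a + (A - v ** 2 / a) / v


def trapezoid_step(params: StimulusParams,
                   signed_amplitude: float) -> PositionTrace:
    """Sample one trapezoidal step of ``signed_amplitude`` degrees.

    The continuous-time profile (ramp, plateau, ramp) is evaluated exactly
    at the grid times, so the sampled trace's numerical velocity and
    acceleration never exceed the configured peaks beyond one-sample
    discretization slack.
    """
    A = abs(signed_amplitude)
    if A == 0:
        raise ValueError("signed_amplitude must be nonzero "
                         "(zero-length motion is not a step)")
    _check_trapezoid(A, params.peak_velocity, params.peak_acceleration)
    v, a = params.peak_velocity, params.peak_acceleration
    t_total = 2.0 * v / a + (A - v ** 2 / a) / v
    n = int(np.ceil(t_total * params.sample_rate)) + 1
    t = np.arange(n) / params.sample_rate
    pos = _trapezoid_position(t, A, v, a) * np.sign(signed_amplitude)
    return PositionTrace(time=t, angle=pos)


# signed amplitudes of each named step, in units of params.amplitude
_STEP_SIGNS = {"up_toward": +1, "up_away": -1, "down_toward": -1,
               "down_away": +1}


def build_session(params: StimulusParams) -> PositionTrace:
    """Concatenate ``n_cycles`` four-step cycles into one session trace.

    Each cycle tilts nose-up away from the horizon, returns, tilts
    nose-down, and returns, with a ``hold_duration`` dwell after every
    step.  The trace starts and ends at 0 deg.
    """
    fs = params.sample_rate
    n_hold = int(round(params.hold_duration * fs))
    chunks: list[np.ndarray] = []
    angle = 0.0
    for _ in range(params.n_cycles):
        for name in params.step_order:
            signed = _STEP_SIGNS[name] * params.amplitude
            step = trapezoid_step(params, signed)
            chunks.append(angle + step.angle)
            angle += signed
            if n_hold:
                chunks.append(np.full(n_hold, angle))
    full = np.concatenate(chunks)
    t = np.arange(full.size) / fs
    return PositionTrace(time=t, angle=full)


def segment_steps(trace: PositionTrace, velocity_threshold: float = 5.0,
                  min_interval: float = 0.5) -> list[StepSegment]:
    """Locate step onsets as upward |velocity| threshold crossings.

    Crossings closer than ``min_interval`` seconds to the previous onset
    are ignored (they belong to the same step).  Direction and phase are
    assigned from the start/end angles: the step is nose-up if its
    excursion extreme is positive, and "toward" if it moves away from the
    horizon (0 deg).

    A trace with no crossings yields an empty list.
    """
    if velocity_threshold <= 0:
        raise ValueError("velocity_threshold must be > 0")
    fs = trace.sample_rate  # raises on non-uniform grid
    v = np.gradient(trace.angle) * fs
    above = np.abs(v) > velocity_threshold
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above.size and above[0]:
        crossings = np.insert(crossings, 0, 0)

    min_gap = int(round(min_interval * fs))
    # walk each crossing back to the start of motion so onsets land on the
    # first moving sample, not partway up the acceleration ramp
    eps = 0.02 * velocity_threshold
    onsets: list[int] = []
    for c in crossings:
        j = int(c)
        while j > 0 and abs(v[j - 1]) > eps:
            j -= 1
        if not onsets or j - onsets[-1] >= min_gap:
            onsets.append(j)

    segments: list[StepSegment] = []
    for i, onset in enumerate(onsets):
        next_onset = onsets[i + 1] if i + 1 < len(onsets) else len(trace)
        # motion offset: first sample within [onset, next_onset) where
        # |v| falls back below threshold
        below = np.flatnonzero(~above[onset:next_onset])
        offset = onset + int(below[0]) if below.size else next_onset
        start_angle = float(trace.angle[max(onset - 1, 0)])
        end_idx = min(next_onset - 1, len(trace) - 1)
        end_angle = float(trace.angle[end_idx])
        extreme = start_angle if abs(start_angle) >= abs(end_angle) else end_angle
        direction = "nose_up" if extreme > 0 else "nose_down"
        phase = "toward" if abs(end_angle) > abs(start_angle) else "away"
        segments.append(StepSegment(onset_index=onset, offset_index=offset,
                                    direction=direction, phase=phase,
                                    start_angle=start_angle,
                                    end_angle=end_angle))
    return segments
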