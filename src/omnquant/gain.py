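"""Vestibulo-ocular reflex gain from eye and platform angle traces.

The behavioral statistic is the gain: the ratio of the peak compensatory
eye velocity — the maximum over the first second after each step onset —
to the peak platform velocity (35 deg/s under the default protocol),
averaged across all retained steps of a direction.  Steps contaminated by
saccade-like jumps or implausible velocities are excluded automatically,
replacing the manual trial curation of the original assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .stimulus import PositionTrace, StepSegment, segment_steps

__all__ = [
    "GainConfig",
    "VelocityTrace",
    "StepResponse",
    "FishResponse",
    "compute_velocity",
    "reject_artifacts",
    "peak_response",
    "fish_gain",
]


@dataclass(frozen=True)
class GainConfig:
    """Tunable knobs of the gain computation.

    ``response_window`` is the scoring window after each step onset (s).
    ``savgol_window`` is the Savitzky-Golay differentiation window in
    samples (odd).  The 31-sample default (155 ms at 200 Hz) fits inside
    the 195 ms constant-velocity plateau of the default trapezoid, so
    peak velocities are undistorted, while suppressing differentiated
    measurement noise enough for accurate peak statistics.  ``vel_ceiling`` (deg/s)
    and ``jump_ceiling`` (deg per sample) are the artifact-exclusion
    thresholds.  When ``toward_only`` is set, only steps tilting away
    from the horizon count toward a direction's gain; return-to-horizon
    steps are ignored.  ``signed_mode`` selects whether the peak is taken
    over compensatory-signed velocity ("compensatory") or |velocity|
    ("unsigned").  ``peak_platform_velocity`` fixes the denominator; None
    measures it from the platform trace.
    """

    response_window: float = 1.0
    savgol_window: int = 31
    vel_ceiling: float = 120.0
    jump_ceiling: float = 3.0
    velocity_threshold: float = 5.0
    toward_only: bool = True
    signed_mode: str = "compensatory"   # "compensatory" | "unsigned"
    peak_platform_velocity: float | None = None

    def __post_init__(self) -> None:
        if self.signed_mode not in ("compensatory", "unsigned"):
            raise ValueError(f"signed_mode invalid: {self.signed_mode!r}")
        if self.savgol_window < 3 or self.savgol_window % 2 == 0:
            raise ValueError("savgol_window must be an odd integer >= 3")
        if self.vel_ceiling <= 0 or self.jump_ceiling <= 0:
            raise ValueError("artifact ceilings must be > 0")


@dataclass(frozen=True)
class VelocityTrace:
    """Angular velocity on the same grid as its source position trace."""

    time: np.ndarray
    velocity: np.ndarray     # deg/s
    source: str              # "eye" | "platform"
    smoothing: str = ""

    def __len__(self) -> int:
        return self.time.size


@dataclass(frozen=True)
class StepResponse:
    """Per-step measurement and exclusion outcome."""

    segment: StepSegment
    peak_eye_velocity: float         # deg/s, >= 0; nan if not measured
    retained: bool
    rejection_reason: str            # "none" | "saccade" | "tracking_quality"


@dataclass(frozen=True)
class FishResponse:
    """Per-fish, per-direction gain summary."""

    fish_id: str
    genotype: str
    gain_up: float | None
    gain_down: float | None
    n_retained_up: int
    n_retained_down: int
    missing_reason: dict = field(default_factory=dict)


def compute_velocity(trace: PositionTrace, window_samples: int = 31,
                     source: str = "eye") -> VelocityTrace:
    """Savitzky-Golay first derivative (quadratic fit) of an angle trace.

    With ``window_samples = 3`` this reduces to central differences.
    Exact on linear ramps at interior samples.
    """
    if window_samples < 3 or window_samples % 2 == 0:
        raise ValueError("window_samples must be an odd integer >= 3")
    fs = trace.sample_rate  # raises on non-uniform grid
    v = savgol_filter(trace.angle, window_samples, polyorder=2, deriv=1,
                      delta=1.0 / fs)
    return VelocityTrace(time=trace.time.copy(), velocity=v, source=source,
                         smoothing=f"savgol(window={window_samples}, order=2)")


def _window_slice(segment: StepSegment, window: float, fs: float,
                  n: int) -> slice:
    start = segment.onset_index
    stop = start + int(round(window * fs)) + 1
    if stop > n:
        raise ValueError(
            f"response window extends past trace end for step at sample "
            f"{segment.onset_index} ({segment.direction}/{segment.phase})")
    return slice(start, stop)


def peak_response(eye_velocity: VelocityTrace, segment: StepSegment,
                  window: float = 1.0,
                  signed_mode: str = "compensatory") -> float:
    """Peak eye velocity (deg/s, magnitude) in the post-onset window.

    In "compensatory" mode only velocity of the compensatory sign —
    opposite the platform's step displacement — is considered; in
    "unsigned" mode the max |velocity| is returned regardless of sign.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    fs = 1.0 / (eye_velocity.time[1] - eye_velocity.time[0])
    sl = _window_slice(segment, window, fs, len(eye_velocity))
    v = eye_velocity.velocity[sl]
    if signed_mode == "unsigned":
        return float(np.max(np.abs(v)))
    comp_sign = -np.sign(segment.displacement)
    return float(max(np.max(comp_sign * v), 0.0))


def reject_artifacts(eye: PositionTrace, eye_velocity: VelocityTrace,
                     segments: list[StepSegment],
                     vel_ceiling: float = 120.0, jump_ceiling: float = 3.0,
                     window: float = 1.0) -> list[StepResponse]:
    """Flag steps contaminated by saccades or tracking failures.

    A step is rejected iff, within its response window, any single-sample
    position change exceeds ``jump_ceiling`` degrees (saccade) or
    |eye velocity| exceeds ``vel_ceiling`` deg/s (tracking_quality).
    Exclusion is independent of measurement: peak values are not
    computed here.
    """
    if vel_ceiling <= 0 or jump_ceiling <= 0:
        raise ValueError("ceilings must be > 0")
    fs = eye.sample_rate
    jumps = np.abs(np.diff(eye.angle))
    out: list[StepResponse] = []
    for seg in segments:
        sl = _window_slice(seg, window, fs, len(eye))
        jump_bad = bool(np.any(jumps[sl.start:min(sl.stop, jumps.size)]
                               > jump_ceiling))
        vel_bad = bool(np.any(np.abs(eye_velocity.velocity[sl])
                              > vel_ceiling))
        if jump_bad:
            reason = "saccade"
        elif vel_bad:
            reason = "tracking_quality"
        else:
            reason = "none"
        out.append(StepResponse(segment=seg, peak_eye_velocity=np.nan,
                                retained=reason == "none",
                                rejection_reason=reason))
    return out


def fish_gain(platform: PositionTrace, eye: PositionTrace,
              fish_id: str = "", genotype: str = "",
              config: GainConfig | None = None,
              segments: list[StepSegment] | None = None,
              ) -> tuple[FishResponse, list[StepResponse]]:
    """Per-direction VOR gain for one fish.

    For each direction, gain = mean over retained steps of the peak
    compensatory eye velocity, divided by the peak platform velocity.
    Directions with zero retained (or zero scorable) steps report a
    missing gain with an explicit reason — never 0 and never imputed.

    Returns the summary plus a per-step audit trail.
    """
    cfg = config or GainConfig()
    if segments is None:
        segments = segment_steps(platform, cfg.velocity_threshold)
    eye_vel = compute_velocity(eye, cfg.savgol_window, source="eye")

    if cfg.peak_platform_velocity is not None:
        peak_platform = cfg.peak_platform_velocity
    else:
        plat_vel = compute_velocity(platform, cfg.savgol_window,
                                    source="platform")
        peak_platform = float(np.max(np.abs(plat_vel.velocity)))
    if peak_platform <= 0:
        raise ValueError("peak platform velocity must be > 0")

    responses = reject_artifacts(eye, eye_vel, segments,
                                 cfg.vel_ceiling, cfg.jump_ceiling,
                                 cfg.response_window)
    audited: list[StepResponse] = []
    peaks: dict[str, list[float]] = {"nose_up": [], "nose_down": []}
    for resp in responses:
        seg = resp.segment
        scorable = (not cfg.toward_only) or seg.phase == "toward"
        peak = peak_response(eye_vel, seg, cfg.response_window,
                             cfg.signed_mode) if scorable else np.nan
        audited.append(StepResponse(segment=seg, peak_eye_velocity=peak,
                                    retained=resp.retained,
                                    rejection_reason=resp.rejection_reason))
        if resp.retained and scorable:
            peaks[seg.direction].append(peak)

    gains: dict[str, float | None] = {}
    counts: dict[str, int] = {}
    missing: dict[str, str] = {}
    for direction in ("nose_up", "nose_down"):
        vals = peaks[direction]
        counts[direction] = len(vals)
        if vals:
            gains[direction] = float(np.mean(vals)) / peak_platform
        else:
            gains[direction] = None
            missing[direction] = ("no retained steps"
                                  if any(r.segment.direction == direction
                                         for r in audited)
                                  else "no steps found")
    summary = FishResponse(fish_id=fish_id, genotype=genotype,
                           gain_up=gains["nose_up"],
                           gain_down=gains["nose_down"],
                           n_retained_up=counts["nose_up"],
                           n_retained_down=counts["nose_down"],
                           missing_reason=missing)
    return summary, audited
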