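"""Synthetic-data generators with recorded ground truth.

Every input the pipeline consumes can be generated here: tilt sessions
from a simulated compensatory eye plant, rotating eye-texture image
stacks, per-cell fluorescence tables with a bimodal red channel
(photoconverted vs. unconverted cells), and differential-expression / QC
tables with spiked effects.  Each generator is a pure function of its
parameters, including the seed, and returns the injected truth alongside
the data so downstream estimates can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, signal
from skimage.transform import rotate as _rotate

from .stimulus import StimulusParams, PositionTrace, build_session

__all__ = [
    "EyePlantParams",
    "SyntheticSession",
    "SyntheticImageParams",
    "generate_session",
    "generate_eye_image_stack",
    "generate_fluorescence_table",
    "generate_de_table",
    "generate_qc_table",
]


@dataclass(frozen=True)
class EyePlantParams:
    """A simulated compensatory eye plant.

    The eye counter-rotates against the platform with direction-specific
    gain: ``gain_up`` scales responses to nose-up tilts (positive platform
    angles) and ``gain_down`` to nose-down tilts.  In ``proportional``
    mode the eye tracks the (negated, gain-scaled) platform instantly; in
    ``first_order_lag`` mode it follows through a single exponential lag
    with time constant ``tau``.  Saccades are instantaneous position jumps
    arriving as a Poisson process; measurement noise is additive Gaussian
    on the angle.
    """

    gain_up: float = 0.8
    gain_down: float = 0.8
    mode: str = "proportional"          # "proportional" | "first_order_lag"
    tau: float = 0.1                    # s, used only in lag mode
    noise_sd: float = 0.0               # deg
    saccade_rate: float = 0.0           # events / s
    saccade_amplitude_sd: float = 5.0   # deg
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gain_up < 0 or self.gain_down < 0:
            raise ValueError("EyePlantParams gains must be >= 0")
        if self.mode not in ("proportional", "first_order_lag"):
            raise ValueError(f"EyePlantParams.mode invalid: {self.mode!r}")
        if self.mode == "first_order_lag" and self.tau <= 0:
            raise ValueError("EyePlantParams.tau must be > 0 in lag mode")
        if self.noise_sd < 0:
            raise ValueError("EyePlantParams.noise_sd must be >= 0")
        if self.saccade_rate < 0:
            raise ValueError("EyePlantParams.saccade_rate must be >= 0")


@dataclass(frozen=True)
class SyntheticSession:
    """A simulated session with its injected ground truth."""

    time: np.ndarray            # s
    platform_angle: np.ndarray  # deg
    eye_angle: np.ndarray       # deg
    truth: dict                 # gain_up, gain_down, saccade_times (s)

    @property
    def platform_trace(self) -> PositionTrace:
        return PositionTrace(time=self.time, angle=self.platform_angle)

    @property
    def eye_trace(self) -> PositionTrace:
        return PositionTrace(time=self.time, angle=self.eye_angle)


def generate_session(stim: StimulusParams,
                     plant: EyePlantParams) -> SyntheticSession:
    """Simulate eye and platform angle traces for one session.

    The noiseless eye target is ``-gain(direction) * platform_angle``
    (compensatory sign convention: the eye rotates opposite the
    platform), with the direction-specific gain applied to the positive
    (nose-up) and negative (nose-down) parts of the platform angle.
    """
    platform = build_session(stim)
    p = platform.angle
    target = -(plant.gain_up * np.clip(p, 0.0, None)
               + plant.gain_down * np.clip(p, None, 0.0))

    if plant.mode == "first_order_lag":
        dt = 1.0 / stim.sample_rate
        decay = np.exp(-dt / plant.tau)
        # exact zero-order-hold discretization of dy/dt = (x - y)/tau
        eye = signal.lfilter([1.0 - decay], [1.0, -decay], target)
    else:
        eye = target.copy()

    rng = np.random.default_rng(plant.seed)
    saccade_times: list[float] = []
    if plant.saccade_rate > 0:
        dt = 1.0 / stim.sample_rate
        events = rng.random(eye.size) < plant.saccade_rate * dt
        idx = np.flatnonzero(events)
        jumps = rng.normal(0.0, plant.saccade_amplitude_sd, idx.size)
        for i, j in zip(idx, jumps):
            eye[i:] += j  # instantaneous, persistent position jump
        saccade_times = list(platform.time[idx])
    if plant.noise_sd > 0:
        eye = eye + rng.normal(0.0, plant.noise_sd, eye.size)

    truth = {"gain_up": plant.gain_up, "gain_down": plant.gain_down,
             "saccade_times": saccade_times}
    return SyntheticSession(time=platform.time, platform_angle=p,
                            eye_angle=eye, truth=truth)


@dataclass(frozen=True)
class SyntheticImageParams:
    """Geometry and texture of the synthetic eye video."""

    height: int = 100
    width: int = 100
    pixel_scale: float = 6.0            # um / pixel
    texture_seed: int = 0
    contrast: float = 1.0
    smoothing_sigma: float = 2.0        # px, band-limits the texture
    rotation_center: tuple[float, float] | None = None  # (row, col)

    def __post_init__(self) -> None:
        if self.height < 16 or self.width < 16:
            raise ValueError("image dimensions must be >= 16 px")
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be > 0")


def make_base_texture(params: SyntheticImageParams) -> np.ndarray:
    """Band-limited Gaussian noise inside a circular mask."""
    rng = np.random.default_rng(params.texture_seed)
    img = rng.normal(0.0, 1.0, (params.height, params.width))
    img = ndimage.gaussian_filter(img, params.smoothing_sigma)
    img *= params.contrast / max(img.std(), 1e-12)
    img[~circular_mask(params.height, params.width,
                       params.rotation_center)] = 0.0
    return img


def circular_mask(height: int, width: int,
                  center: tuple[float, float] | None = None) -> np.ndarray:
    """Inscribed circular boolean mask (True inside)."""
    if center is None:
        center = ((height - 1) / 2.0, (width - 1) / 2.0)
    r = min(height, width) / 2.0 - 1.0
    rr, cc = np.mgrid[0:height, 0:width]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= r ** 2


@dataclass(frozen=True)
class ImageStack:
    """Ordered grayscale frames with timestamps and an optional ROI mask."""

    frames: np.ndarray                 # (n, H, W) float
    timestamps: np.ndarray             # s, strictly increasing
    mask: np.ndarray | None = None     # (H, W) bool

    def __post_init__(self) -> None:
        f = np.asarray(self.frames, dtype=float)
        t = np.asarray(self.timestamps, dtype=float)
        if f.ndim != 3:
            raise ValueError("frames must be a (n, H, W) array")
        if f.shape[0] == 0:
            raise ValueError("image stack must contain at least one frame")
        if t.shape != (f.shape[0],):
            raise ValueError("timestamps must match the number of frames")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        object.__setattr__(self, "frames", f)
        object.__setattr__(self, "timestamps", t)

    def __len__(self) -> int:
        return self.frames.shape[0]


def generate_eye_image_stack(angles: Sequence[float],
                             params: SyntheticImageParams | None = None,
                             sample_rate: float = 200.0) -> ImageStack:
    """Render a fixed texture rotated by each requested angle.

    Frame 0 is the unrotated reference (its angle must be 0); frame k is
    the base texture rotated by ``angles[k]`` about ``rotation_center``
    with bilinear interpolation.  Equal angles yield bit-identical frames.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("angles must be non-empty")
    if angles[0] != 0.0:
        raise ValueError("frame 0 is the reference and must have angle 0")
    if np.any(np.abs(angles) > 45.0):
        raise ValueError("all |angles| must be <= 45 deg")
    if params is None:
        params = SyntheticImageParams()
    base = make_base_texture(params)
    center = params.rotation_center
    if center is not None:
        center = (center[1], center[0])  # skimage expects (col, row)
    cache: dict[float, np.ndarray] = {}
    frames = np.empty((angles.size, params.height, params.width))
    for k, a in enumerate(angles):
        if a not in cache:
            if a == 0.0:
                cache[a] = base.copy()
            else:
                # skimage rotates counterclockwise for positive angles
                cache[a] = _rotate(base, a, center=center, order=1,
                                   mode="constant", cval=0.0)
        frames[k] = cache[a]
    t = np.arange(angles.size) / sample_rate
    mask = circular_mask(params.height, params.width, params.rotation_center)
    return ImageStack(frames=frames, timestamps=t, mask=mask)


def generate_fluorescence_table(n_converted: int, n_unconverted: int,
                                n_controls: int, separation: float = 8.0,
                                seed: int = 0,
                                baseline_mean: float = 50.0,
                                baseline_sd: float = 5.0,
                                z_range: tuple[float, float] = (0.0, 90.0),
                                timepoint_hpf: float = 33.0,
                                fish_id: str = "fish1",
                                ) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-cell fluorescence table plus non-converted control intensities.

    Unconverted cells and controls share a low red-intensity distribution
    N(baseline_mean, baseline_sd); converted cells are shifted upward by
    ``separation`` baseline standard deviations.  Intensities are clipped
    at 0.  The ``true_converted`` column records ground truth.
    """
    if min(n_converted, n_unconverted, n_controls) < 0:
        raise ValueError("cell counts must be >= 0")
    if separation <= 0:
        raise ValueError("separation must be > 0")
    rng = np.random.default_rng(seed)
    n = n_converted + n_unconverted
    red = np.concatenate([
        rng.normal(baseline_mean + separation * baseline_sd, baseline_sd,
                   n_converted),
        rng.normal(baseline_mean, baseline_sd, n_unconverted),
    ])
    controls = np.clip(rng.normal(baseline_mean, baseline_sd, n_controls),
                       0.0, None)
    green = np.clip(rng.normal(200.0, 20.0, n), 0.0, None)
    z0, z1 = z_range
    cells = pd.DataFrame({
        "cell_id": [f"cell{i:04d}" for i in range(n)],
        "fish_id": fish_id,
        "red_intensity": np.clip(red, 0.0, None),
        "green_intensity": green,
        "x_um": rng.uniform(0.0, 100.0, n),
        "y_um": rng.uniform(0.0, 100.0, n),
        "z_um": rng.uniform(z0, z1, n),
        "timepoint_hpf": timepoint_hpf,
        "true_converted": np.r_[np.ones(n_converted, bool),
                                np.zeros(n_unconverted, bool)],
    })
    return cells, controls


def generate_de_table(n_null: int, n_spiked_up: int, n_spiked_down: int,
                      effect_log2fc: float = 2.0,
                      seed: int = 0) -> pd.DataFrame:
    """Differential-expression table with spiked true positives.

    Null genes: log2FC ~ N(0, 0.2), padj ~ Uniform(0.2, 1) — by
    construction no null gene can pass a padj < 0.01 filter.  Spiked
    genes: |log2FC| >= ``effect_log2fc`` and padj <= 1e-4, signed up
    (early-enriched) or down (late-enriched).  ``true_label`` records
    ground truth ("null", "up", "down").
    """
    if min(n_null, n_spiked_up, n_spiked_down) < 0:
        raise ValueError("gene counts must be >= 0")
    rng = np.random.default_rng(seed)
    lfc = np.concatenate([
        effect_log2fc + np.abs(rng.normal(0.0, 0.3, n_spiked_up)),
        -(effect_log2fc + np.abs(rng.normal(0.0, 0.3, n_spiked_down))),
        rng.normal(0.0, 0.2, n_null),
    ])
    padj = np.concatenate([
        rng.uniform(1e-8, 1e-4, n_spiked_up + n_spiked_down),
        rng.uniform(0.2, 1.0, n_null),
    ])
    labels = (["up"] * n_spiked_up + ["down"] * n_spiked_down
              + ["null"] * n_null)
    n = len(labels)
    return pd.DataFrame({
        "gene_id": [f"gene{i:05d}" for i in range(n)],
        "log2_fold_change": lfc,
        "p_value": padj * rng.uniform(0.1, 1.0, n),
        "adjusted_p": padj,
        "true_label": labels,
    })


def generate_qc_table(n_pass: int = 84, n_low_genes: int = 60,
                      n_high_genes: int = 8, n_high_mito: int = 40,
                      seed: int = 0) -> pd.DataFrame:
    """Single-cell QC table with known pass/fail composition.

    Passing cells draw gene counts from the retained range (centered near
    4,400 genes/cell, matching a plate-based deep-coverage library) and
    low mitochondrial fractions; the three failure classes violate exactly
    one exclusion each.
    """
    if min(n_pass, n_low_genes, n_high_genes, n_high_mito) < 0:
        raise ValueError("cell counts must be >= 0")
    rng = np.random.default_rng(seed)
    genes = np.concatenate([
        np.clip(rng.normal(4400, 1000, n_pass), 1100, 15000),
        rng.integers(50, 1100, n_low_genes),
        rng.integers(15001, 30000, n_high_genes),
        np.clip(rng.normal(4400, 1000, n_high_mito), 1100, 15000),
    ]).astype(int)
    mito = np.concatenate([
        rng.uniform(0.0, 4.0, n_pass),
        rng.uniform(0.0, 4.0, n_low_genes + n_high_genes),
        rng.uniform(4.0 + 1e-6, 60.0, n_high_mito),
    ])
    labels = (["pass"] * n_pass + ["low_genes"] * n_low_genes
              + ["high_genes"] * n_high_genes + ["high_mito"] * n_high_mito)
    n = len(labels)
    perm = rng.permutation(n)
    return pd.DataFrame({
        "cell_id": [f"cell{i:03d}" for i in range(n)],
        "n_genes_detected": genes[perm],
        "pct_mito": mito[perm],
        "true_label": np.asarray(labels, dtype=object)[perm],
    })
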