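"""Plain-text and TIFF input/output for pipeline artifacts."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .stimulus import PositionTrace
from .synthetic import ImageStack, SyntheticSession
from .torsion import TorsionTrace

__all__ = [
    "write_session_csv", "read_session_csv",
    "write_torsion_csv", "write_image_stack", "read_image_stack",
]


def write_session_csv(session: SyntheticSession, path: str | Path,
                      truth_path: str | Path | None = None) -> None:
    """Session to CSV (time_s, platform_deg, eye_deg); truth to JSON side-car."""
    pd.DataFrame({"time_s": session.time,
                  "platform_deg": session.platform_angle,
                  "eye_deg": session.eye_angle}).to_csv(path, index=False)
    if truth_path is not None:
        Path(truth_path).write_text(json.dumps(session.truth, indent=1))


def read_session_csv(path: str | Path) -> tuple[PositionTrace, PositionTrace]:
    """Read a session CSV into (platform, eye) position traces."""
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(float)
    return (PositionTrace(time=t, angle=df["platform_deg"].to_numpy(float)),
            PositionTrace(time=t, angle=df["eye_deg"].to_numpy(float)))


def write_torsion_csv(trace: TorsionTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.time, "angle_deg": trace.angle,
                  "score": trace.score}).to_csv(path, index=False)


def write_image_stack(stack: ImageStack, path: str | Path,
                      angles_truth: np.ndarray | None = None,
                      truth_path: str | Path | None = None) -> None:
    """Stack to multi-page grayscale TIFF; true angles to JSON side-car."""
    tifffile.imwrite(path, stack.frames.astype(np.float32),
                     photometric="minisblack")
    if truth_path is not None and angles_truth is not None:
        Path(truth_path).write_text(json.dumps(
            {"angles_deg": list(map(float, angles_truth))}))


def read_image_stack(path: str | Path, sample_rate: float = 200.0,
                     mask_path: str | Path | None = None) -> ImageStack:
    frames = np.asarray(tifffile.imread(path), dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    mask = None
    if mask_path is not None:
        mask = np.asarray(tifffile.imread(mask_path)) > 0
    t = np.arange(frames.shape[0]) / sample_rate
    return ImageStack(frames=frames, timestamps=t, mask=mask)
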