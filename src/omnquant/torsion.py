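"""Torsional eye-angle estimation by rotational registration.

Each video frame is compared against rotated copies of a reference frame;
the torsion estimate is the rotation maximizing the normalized
cross-correlation over a circular region of interest, refined to
sub-grid precision by parabolic interpolation of the correlation peak.
The original on-line pattern-matching tracker this stands in for is not
described algorithmically; this module is an explicit, testable
realization of the same measurement, not a bit-for-bit replication.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.transform import rotate as _rotate

from .synthetic import ImageStack, circular_mask

__all__ = ["TorsionTrace", "estimate_torsion", "track_session"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TorsionTrace:
    """Per-frame torsion angle (deg, relative to the reference frame),
    peak correlation score in [-1, 1], and a low-confidence flag."""

    time: np.ndarray
    angle: np.ndarray
    score: np.ndarray
    flagged: np.ndarray  # True where score < the configured floor

    def __len__(self) -> int:
        return self.time.size


class _RotatedReferenceBank:
    """Caches z-scored masked pixel vectors of the rotated reference."""

    def __init__(self, reference: np.ndarray, mask: np.ndarray):
        self.reference = reference
        self.mask = mask
        self._cache: dict[float, np.ndarray | None] = {}

    def __call__(self, angle: float) -> np.ndarray | None:
        key = round(float(angle), 9)
        if key not in self._cache:
            if key == 0.0:
                img = self.reference
            else:
                img = _rotate(self.reference, key, order=1,
                              mode="constant", cval=0.0)
            self._cache[key] = _zscore(img[self.mask])
        return self._cache[key]


def _zscore(v: np.ndarray) -> np.ndarray | None:
    sd = v.std()
    if sd == 0:
        return None
    return (v - v.mean()) / (sd * np.sqrt(v.size))


def _ncc(frame_z: np.ndarray | None, ref_z: np.ndarray | None) -> float:
    if frame_z is None or ref_z is None:
        return 0.0
    return float(frame_z @ ref_z)


def _parabolic_refine(grid: np.ndarray, scores: np.ndarray, i: int,
                      refine_points: int) -> tuple[float, float]:
    """Refine the argmax by a least-squares parabola around the peak.

    ``refine_points`` grid points centered on the peak are fitted (3
    reduces to the classic exact 3-point parabola); near a grid boundary
    the window shrinks, and with fewer than 3 points — or a non-concave
    fit, or an already perfect correlation — the grid value is kept.
    """
    if scores[i] >= 1.0 - 1e-9:  # exact match: nothing to refine
        return float(grid[i]), float(scores[i])
    h = refine_points // 2
    lo, hi = max(0, i - h), min(len(grid), i + h + 1)
    if hi - lo < 3:
        return float(grid[i]), float(scores[i])
    x = grid[lo:hi] - grid[i]
    c2, c1, c0 = np.polyfit(x, scores[lo:hi], 2)
    if c2 >= 0:  # degenerate (flat or concave-up): keep the grid peak
        return float(grid[i]), float(scores[i])
    shift = -c1 / (2.0 * c2)
    step = float(grid[1] - grid[0]) if len(grid) > 1 else 0.0
    shift = float(np.clip(shift, -h * step, h * step))
    # refinement never leaves the searched range
    angle = float(np.clip(grid[i] + shift, grid[0], grid[-1]))
    shift = angle - grid[i]
    return angle, float(c0 + c1 * shift + c2 * shift ** 2)


def _best_angle(frame_z, bank, grid, refine_points=5):
    scores = np.array([_ncc(frame_z, bank(a)) for a in grid])
    best = float(scores.max())
    # ties broken toward the smallest |angle|
    candidates = np.flatnonzero(scores >= best - 1e-12)
    i = int(candidates[np.argmin(np.abs(grid[candidates]))])
    return _parabolic_refine(grid, scores, i, refine_points)


def estimate_torsion(stack: ImageStack, reference_index: int = 0,
                     search_range: float = 20.0, coarse_step: float = 0.5,
                     score_floor: float = 0.5,
                     refine_points: int = 5) -> TorsionTrace:
    """Full-range rotational registration of every frame.

    For each frame the candidate rotations span ``[-search_range,
    +search_range]`` in ``coarse_step`` increments; the returned angle is
    the parabolic refinement of the best-correlated candidate.  A
    zero-variance (blank) frame gets score 0 and carries the previous
    frame's angle.
    """
    grid = _candidate_grid(search_range, coarse_step)
    bank, mask = _prepare(stack, reference_index)
    n = len(stack)
    angle = np.zeros(n)
    score = np.zeros(n)
    prev = 0.0
    for k in range(n):
        frame_z = _zscore(stack.frames[k][mask])
        if frame_z is None:
            angle[k], score[k] = prev, 0.0
        else:
            angle[k], score[k] = _best_angle(frame_z, bank, grid,
                                             refine_points)
        prev = angle[k]
    return _finish(stack, angle, score, score_floor)


def track_session(stack: ImageStack, reference_index: int = 0,
                  search_range: float = 20.0, coarse_step: float = 0.5,
                  local_range: float = 2.0, score_floor: float = 0.5,
                  refine_points: int = 5) -> TorsionTrace:
    """Frame-by-frame tracking with a warm start.

    Each frame is searched over ``+/- local_range`` around the previous
    frame's estimate (snapped to the global candidate grid so rotated
    references are shared).  If the best candidate sits on the local
    window's edge the search falls back to the full range, so slow traces
    give results identical to :func:`estimate_torsion`.
    """
    full_grid = _candidate_grid(search_range, coarse_step)
    bank, mask = _prepare(stack, reference_index)
    n = len(stack)
    angle = np.zeros(n)
    score = np.zeros(n)
    prev = 0.0
    for k in range(n):
        frame_z = _zscore(stack.frames[k][mask])
        if frame_z is None:
            angle[k], score[k] = prev, 0.0
            continue
        center = np.clip(prev, -search_range, search_range)
        center = round(center / coarse_step) * coarse_step
        lo = max(center - local_range, -search_range)
        hi = min(center + local_range, search_range)
        local = full_grid[(full_grid >= lo - 1e-9) & (full_grid <= hi + 1e-9)]
        a, s = _best_angle(frame_z, bank, local, refine_points)
        snapped = round(a / coarse_step) * coarse_step
        at_edge = (snapped <= local[0] + 1e-9 or snapped >= local[-1] - 1e-9)
        interior_window = local[0] > full_grid[0] or local[-1] < full_grid[-1]
        if at_edge and interior_window:
            a, s = _best_angle(frame_z, bank, full_grid, refine_points)
        angle[k], score[k] = a, s
        prev = a
    return _finish(stack, angle, score, score_floor)


def _candidate_grid(search_range: float, coarse_step: float) -> np.ndarray:
    if search_range <= 0:
        raise ValueError("search_range must be > 0")
    if not 0 < coarse_step <= search_range:
        raise ValueError("coarse_step must be in (0, search_range]")
    n = int(np.floor(search_range / coarse_step + 1e-9))
    return np.arange(-n, n + 1) * coarse_step


def _prepare(stack: ImageStack, reference_index: int):
    if len(stack) == 0:
        raise ValueError("empty image stack")
    if not 0 <= reference_index < len(stack):
        raise IndexError(f"reference_index {reference_index} out of range")
    h, w = stack.frames.shape[1:]
    mask = stack.mask if stack.mask is not None else circular_mask(h, w)
    return _RotatedReferenceBank(stack.frames[reference_index], mask), mask


def _finish(stack: ImageStack, angle, score, score_floor) -> TorsionTrace:
    flagged = score < score_floor
    frac = flagged.mean() if flagged.size else 0.0
    if frac > 0.10:
        logger.warning("torsion tracking: %.0f%% of frames below the "
                       "correlation floor %.2f", 100 * frac, score_floor)
    return TorsionTrace(time=stack.timestamps.copy(), angle=angle,
                        score=score, flagged=flagged)
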