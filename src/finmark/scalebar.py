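"""Scale-bar detection and per-image pixel-to-millimetre calibration.

Pipeline per image: line-enhancing pre-processing (grayscale, Gaussian
smoothing, hysteresis edge detection) -> probabilistic Hough transform
parameterized by vote threshold, minimum line length and maximum line gap
-> selection of the longest near-horizontal segment -> mm-per-pixel
factor from its known physical length. Calibration is per image because
small camera or subject movements change the scale from shot to shot.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from skimage.feature import canny
from skimage.transform import probabilistic_hough_line

logger = logging.getLogger(__name__)

__all__ = [
    "HoughParams",
    "PreprocessConfig",
    "LineSegment",
    "ScaleCalibration",
    "ScaleBarError",
    "preprocess_for_lines",
    "detect_lines",
    "select_scale_bar",
    "refine_segment",
    "calibrate",
    "to_mm",
    "detect_scale_bar",
    "calibrate_directory",
]


class ScaleBarError(RuntimeError):
    """Raised when no scale-bar candidate survives the selection filters."""


@dataclass(frozen=True)
class HoughParams:
    """The three user-facing knobs of the probabilistic Hough transform."""

    threshold: int = 10
    min_line_length: int = 50
    max_line_gap: int = 10

    def __post_init__(self) -> None:
        if self.threshold < 1:
            raise ValueError("threshold must be >= 1")
        if self.min_line_length < 1:
            raise ValueError("min_line_length must be >= 1")
        if self.max_line_gap < 0:
            raise ValueError("max_line_gap must be >= 0")


@dataclass(frozen=True)
class PreprocessConfig:
    """Line-enhancement recipe: smoothing sigma + hysteresis thresholds."""

    blur_sigma: float = 2.0
    low_threshold: float = 0.1
    high_threshold: float = 0.3


@dataclass(frozen=True)
class LineSegment:
    x1: float
    y1: float
    x2: float
    y2: float

    @property
    def length_px(self) -> float:
        return math.hypot(self.x2 - self.x1, self.y2 - self.y1)

    @property
    def angle_deg(self) -> float:
        """Orientation in degrees, normalized to [-90, 90)."""
        ang = math.degrees(math.atan2(self.y2 - self.y1, self.x2 - self.x1))
        while ang >= 90.0:
            ang -= 180.0
        while ang < -90.0:
            ang += 180.0
        return ang


@dataclass(frozen=True)
class ScaleCalibration:
    mm_per_px: float
    bar_length_px: float
    bar_length_mm: float
    image: str

    def __post_init__(self) -> None:
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")


def _as_gray_float(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 3:
        arr = 0.299 * arr[..., 0] + 0.587 * arr[..., 1] + 0.114 * arr[..., 2]
    if arr.max() > 1.0:
        arr = arr / 255.0
    return arr


def preprocess_for_lines(
    image: np.ndarray, config: PreprocessConfig = PreprocessConfig()
) -> np.ndarray:
    """Grayscale -> Gaussian smoothing -> hysteresis edge detection.

    Returns a boolean edge map; deterministic.
    """
    gray = _as_gray_float(image)
    if gray.size == 0:
        raise ValueError("empty image")
    return canny(
        gray,
        sigma=config.blur_sigma,
        low_threshold=config.low_threshold,
        high_threshold=config.high_threshold,
    )


def detect_lines(edges: np.ndarray, params: HoughParams) -> List[LineSegment]:
    """Probabilistic Hough transform over a binary edge map.

    Every returned segment has length >= ``min_line_length``; collinear
    fragments separated by <= ``max_line_gap`` merge into one segment.
    The stochastic accumulator is seeded for determinism.
    """
    edges = np.asarray(edges).astype(bool)
    raw = probabilistic_hough_line(
        edges,
        threshold=params.threshold,
        line_length=params.min_line_length,
        line_gap=params.max_line_gap,
        rng=0,
    )
    return [LineSegment(x1=p0[0], y1=p0[1], x2=p1[0], y2=p1[1]) for p0, p1 in raw]


def select_scale_bar(
    lines: Sequence[LineSegment],
    max_tilt_deg: float = 5.0,
    roi: Optional[Tuple[int, int, int, int]] = None,
) -> LineSegment:
    """Longest segment within the tilt tolerance (and the optional
    ``(x, y, w, h)`` region of interest). Raises :class:`ScaleBarError`
    when nothing survives the filters."""

    def in_roi(seg: LineSegment) -> bool:
        if roi is None:
            return True
        x, y, w, h = roi
        return all(
            x <= px < x + w and y <= py < y + h
            for px, py in ((seg.x1, seg.y1), (seg.x2, seg.y2))
        )

    candidates = [s for s in lines if abs(s.angle_deg) <= max_tilt_deg and in_roi(s)]
    if not candidates:
        raise ScaleBarError(
            f"no candidate segment with |tilt| <= {max_tilt_deg} deg"
            + (f" inside ROI {roi}" if roi else "")
        )
    return max(candidates, key=lambda s: s.length_px)


def refine_segment(
    edges: np.ndarray,
    seg: LineSegment,
    max_gap: int = 5,
    perp_tol: float = 2.0,
) -> LineSegment:
    """Snap a Hough segment to the extremes of its supporting edge pixels.

    The stochastic Hough extraction tends to shave a few pixels off the
    segment ends. This projects every edge pixel within ``perp_tol`` of
    the segment's infinite line onto the line direction and extends the
    segment over the maximal collinear run (bridging gaps up to
    ``max_gap``) that contains it.
    """
    dx, dy = seg.x2 - seg.x1, seg.y2 - seg.y1
    length = math.hypot(dx, dy)
    if length == 0:
        return seg
    u = np.array([dx, dy]) / length
    n = np.array([-u[1], u[0]])
    ys, xs = np.nonzero(np.asarray(edges).astype(bool))
    pts = np.stack([xs, ys], axis=1).astype(float)
    rel = pts - np.array([seg.x1, seg.y1])
    perp = rel @ n
    near = np.abs(perp) <= perp_tol
    if not near.any():
        return seg
    t = np.sort(rel[near] @ u)
    # Maximal run (gaps <= max_gap) overlapping the original [0, length].
    breaks = np.flatnonzero(np.diff(t) > max_gap)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(t) - 1]])
    for s, e in zip(starts, ends):
        if t[e] >= 0 and t[s] <= length:
            p1 = np.array([seg.x1, seg.y1]) + t[s] * u
            p2 = np.array([seg.x1, seg.y1]) + t[e] * u
            return LineSegment(x1=p1[0], y1=p1[1], x2=p2[0], y2=p2[1])
    return seg


def calibrate(bar_px: float, bar_mm: float, image: Union[str, Path] = "") -> ScaleCalibration:
    """mm-per-pixel factor from a measured bar length and its known physical length."""
    if bar_px <= 0:
        raise ValueError("bar_px must be positive")
    if bar_mm <= 0:
        raise ValueError("bar_mm must be positive")
    return ScaleCalibration(
        mm_per_px=bar_mm / bar_px,
        bar_length_px=float(bar_px),
        bar_length_mm=float(bar_mm),
        image=str(image),
    )


def to_mm(d_px: float, cal: ScaleCalibration) -> float:
    """Convert a pixel distance to millimetres under a calibration."""
    if d_px < 0:
        raise ValueError("distance must be >= 0")
    return d_px * cal.mm_per_px


def detect_scale_bar(
    image: np.ndarray,
    hough: HoughParams = HoughParams(),
    preprocess: PreprocessConfig = PreprocessConfig(),
    max_tilt_deg: float = 5.0,
    roi: Optional[Tuple[int, int, int, int]] = None,
) -> LineSegment:
    """Full single-image detection: preprocess -> Hough -> select -> refine."""
    edges = preprocess_for_lines(image, preprocess)
    seg = select_scale_bar(detect_lines(edges, hough), max_tilt_deg=max_tilt_deg, roi=roi)
    return refine_segment(edges, seg, max_gap=hough.max_line_gap)


def calibrate_directory(
    image_paths: Sequence[Union[str, Path]],
    bar_mm: float,
    hough: HoughParams = HoughParams(),
    preprocess: PreprocessConfig = PreprocessConfig(),
    max_tilt_deg: float = 5.0,
    roi: Optional[Tuple[int, int, int, int]] = None,
) -> pd.DataFrame:
    """Batch calibration: one row per image with columns
    ``image, bar_px, mm_per_px, status``. Per-image failures are recorded
    and the batch continues."""
    from finmark.shape_model.model import load_gray  # avoid circular import at top

    rows = []
    for path in image_paths:
        path = Path(path)
        try:
            seg = detect_scale_bar(
                load_gray(path), hough, preprocess, max_tilt_deg=max_tilt_deg, roi=roi
            )
            cal = calibrate(seg.length_px, bar_mm, image=path.name)
            rows.append(
                {
                    "image": path.name,
                    "bar_px": cal.bar_length_px,
                    "mm_per_px": cal.mm_per_px,
                    "status": "ok",
                }
            )
        except (ScaleBarError, FileNotFoundError, ValueError) as exc:
            logger.warning("scale bar failed for %s: %s", path.name, exc)
            rows.append(
                {"image": path.name, "bar_px": np.nan, "mm_per_px": np.nan,
                 "status": "scalebar_failed"}
            )
    return pd.DataFrame(rows, columns=["image", "bar_px", "mm_per_px", "status"])
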