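"""Accuracy arithmetic: diagonal-normalized deviation and observer comparison.

A pixel deviation is expressed as a percentage of the image diagonal
(sqrt(width^2 + height^2) — the largest error possible in the frame),
which makes errors comparable across image geometries and datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from finmark.annotations import LandmarkDataset

__all__ = [
    "DeviationReport",
    "normalized_deviation",
    "percent_to_pixels",
    "compare_landmark_sets",
    "error_gap",
]


def _diagonal(width: int, height: int) -> float:
    if width <= 0 or height <= 0:
        raise ValueError(f"width and height must be positive, got {width}x{height}")
    return math.hypot(width, height)


def normalized_deviation(d_px: float, width: int, height: int) -> float:
    """Pixel deviation as a percentage of the image diagonal."""
    if d_px < 0:
        raise ValueError("deviation must be >= 0")
    return 100.0 * d_px / _diagonal(width, height)


def percent_to_pixels(pct: float, width: int, height: int) -> int:
    """Percent-of-diagonal back to pixels, rounded to the nearest integer
    (half away from zero)."""
    if pct < 0:
        raise ValueError("percentage must be >= 0")
    return int(math.floor(pct / 100.0 * _diagonal(width, height) + 0.5))


@dataclass
class DeviationReport:
    """Per-landmark and overall deviation summary for one comparison."""

    per_landmark_mean_px: List[float]
    per_landmark_mean_pct: List[float]
    overall_mean_px: float
    overall_mean_pct: float
    n_images: int

    def to_dict(self) -> dict:
        return {
            "per_landmark_mean_px": self.per_landmark_mean_px,
            "per_landmark_mean_pct": self.per_landmark_mean_pct,
            "overall_mean_px": self.overall_mean_px,
            "overall_mean_pct": self.overall_mean_pct,
            "n_images": self.n_images,
        }


def compare_landmark_sets(
    a: LandmarkDataset,
    b: LandmarkDataset,
    width: Optional[int] = None,
    height: Optional[int] = None,
) -> DeviationReport:
    """Per-landmark mean Euclidean deviation between two annotation sets
    covering the same image files (e.g. model vs. truth, or the same
    observer on different occasions). Symmetric in its arguments.

    Normalization geometry: pass ``width``/``height`` when the datasets
    were evaluated at one known size; otherwise the per-image recorded
    frame sizes are used.
    """
    paths_a = set(a.file_paths())
    paths_b = set(b.file_paths())
    if paths_a != paths_b:
        diff = sorted(paths_a.symmetric_difference(paths_b))
        raise ValueError(f"datasets cover different images; symmetric difference: {diff}")
    if a.n_landmarks != b.n_landmarks:
        raise ValueError(
            f"landmark count mismatch: {a.n_landmarks} vs {b.n_landmarks}"
        )
    by_path = {img.file_path: img for img in b}
    n_lm = a.n_landmarks
    dist_sums = np.zeros(n_lm)
    pct_sums = np.zeros(n_lm)
    for img_a in a:
        img_b = by_path[img_a.file_path]
        d = np.linalg.norm(img_a.shape_array() - img_b.shape_array(), axis=1)
        dist_sums += d
        if width is not None and height is not None:
            w, h = width, height
        elif img_a.width is not None and img_a.height is not None:
            w, h = img_a.width, img_a.height
        else:
            raise ValueError(
                f"no geometry for {img_a.file_path}: pass width/height or record "
                "frame sizes in the XML"
            )
        pct_sums += np.array([normalized_deviation(float(di), w, h) for di in d])
    n = len(a)
    per_px = (dist_sums / n).tolist()
    per_pct = (pct_sums / n).tolist()
    return DeviationReport(
        per_landmark_mean_px=per_px,
        per_landmark_mean_pct=per_pct,
        overall_mean_px=float(np.mean(per_px)),
        overall_mean_pct=float(np.mean(per_pct)),
        n_images=n,
    )


def error_gap(
    model_report: DeviationReport, observer_report: DeviationReport
) -> List[float]:
    """Elementwise per-landmark percent difference: model minus observer.

    Positive entries mean the model is worse than the human baseline.
    """
    m = model_report.per_landmark_mean_pct
    o = observer_report.per_landmark_mean_pct
    if len(m) != len(o):
        raise ValueError(f"landmark schema mismatch: {len(m)} vs {len(o)}")
    return [mi - oi for mi, oi in zip(m, o)]
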