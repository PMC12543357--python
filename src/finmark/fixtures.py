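"""Deterministic generator of fish-like images with exact landmark ground truth.

Each fixture draws an ellipse body plus a notched triangular caudal fin on
a homogeneous background, with controllable exposure, blur, body size and
fin-shape variation. Landmarks are placed analytically on the drawn
geometry before rendering, so ground truth carries zero annotation error;
all measured deviation downstream is attributable to the predictor.

Landmark schema (2 or 4 points):
  0  anterior body vertex (snout tip)
  1  body-fin junction (hypural joint; posterior end of standard length)
  2  fin fork notch (fork length endpoint)            [4-landmark schema]
  3  dorsal apex of the body ellipse                  [4-landmark schema]
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import polygon as draw_polygon

from finmark.annotations import (
    ImageAnnotation,
    Landmark,
    LandmarkDataset,
    write_landmark_xml,
)

__all__ = ["FixtureParams", "PROFILES", "generate_fish_image", "generate_dataset"]


@dataclass(frozen=True)
class FixtureParams:
    """Knobs of the fixture generator; defaults give a clean, standardized set."""

    width: int = 400
    height: int = 300
    body_length_px: Tuple[int, int] = (160, 220)
    translation_jitter: float = 0.05  # fraction of frame, each axis
    brightness_jitter: float = 0.0  # fractional background-level jitter
    blur_sigma: Tuple[float, float] = (0.0, 0.0)
    caudal_irregularity: float = 0.0  # probability of an unspread fin
    background_level: int = 230
    body_level: int = 70
    noise_sigma: float = 2.0
    with_scale_bar: bool = False
    bar_px: int = 120
    bar_mm: float = 10.0
    n_landmarks: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_landmarks not in (2, 4):
            raise ValueError("n_landmarks must be 2 or 4")
        if self.body_length_px[0] > self.body_length_px[1]:
            raise ValueError("body_length_px range must be (low, high)")


# Presets mirroring the documented degradation axes: exposure extremes,
# blur with small bodies, and irregular unspread caudal fins.
PROFILES: dict[str, dict] = {
    "clean": {},
    "overexposed": {"background_level": 250, "body_level": 140, "brightness_jitter": 0.02},
    "underexposed": {"background_level": 90, "body_level": 35, "brightness_jitter": 0.05},
    "blurred": {"blur_sigma": (1.5, 3.0), "body_length_px": (110, 170)},
    "irregular": {"caudal_irregularity": 1.0},
}


def params_for_profile(profile: str, **overrides) -> FixtureParams:
    if profile not in PROFILES:
        raise ValueError(f"unknown profile '{profile}'; choose from {sorted(PROFILES)}")
    return replace(FixtureParams(**PROFILES[profile]), **overrides)


def _fixture_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, index]))


def generate_fish_image(
    params: FixtureParams, index: int
) -> Tuple[np.ndarray, list[Landmark]]:
    """Render fixture ``index`` and its exact landmarks.

    Deterministic given ``(params.seed, index)``.
    """
    rng = _fixture_rng(params.seed, index)
    w, h = params.width, params.height

    body_len = int(rng.integers(params.body_length_px[0], params.body_length_px[1] + 1))
    a = body_len // 2  # semi-major axis
    b = max(4, int(round(a * 0.32)))  # semi-minor axis
    fin_len = max(6, int(round(a * 0.42)))
    fin_half_h = max(4, int(round(b * 0.9)))
    notch = max(2, int(round(fin_len * 0.4)))

    cx0, cy0 = int(round(w * 0.45)), h // 2
    tx = int(round(rng.uniform(-1, 1) * params.translation_jitter * w))
    ty = int(round(rng.uniform(-1, 1) * params.translation_jitter * h))
    cx, cy = cx0 + tx, cy0 + ty

    if cx - a < 1 or cx + a + fin_len >= w - 1 or cy - b < 1 or cy + b >= h - 1:
        raise ValueError(
            f"fixture body (length {body_len}px + fin {fin_len}px) does not fit "
            f"the {w}x{h} frame at centre ({cx}, {cy})"
        )

    snout = (cx - a, cy)
    hypural = (cx + a, cy)
    fork = (hypural[0] + fin_len - notch, cy)
    dorsal = (cx, cy - b)

    bg = float(params.background_level)
    if params.brightness_jitter > 0:
        bg *= 1.0 + rng.uniform(-1, 1) * params.brightness_jitter
    img = np.full((h, w), bg, dtype=float)

    # Caudal fin: notched triangle rooted at the hypural joint.
    spread = fin_half_h
    skew = 0
    if params.caudal_irregularity > 0 and rng.random() < params.caudal_irregularity:
        spread = max(2, int(round(fin_half_h * rng.uniform(0.25, 0.55))))
        skew = int(rng.integers(-fin_half_h // 2, fin_half_h // 2 + 1))
    fin_poly_r = np.array(
        [hypural[1], hypural[1] - spread + skew, fork[1] + skew, hypural[1] + spread + skew]
    )
    fin_poly_c = np.array([hypural[0], hypural[0] + fin_len, fork[0], hypural[0] + fin_len])
    rr, cc = draw_polygon(fin_poly_r, fin_poly_c, shape=img.shape)
    # Fin is rendered lighter than the body: the body-fin junction is the
    # low-contrast landmark, matching the easy/hard landmark asymmetry.
    fin_level = params.body_level + 0.55 * (bg - params.body_level)
    img[rr, cc] = fin_level

    rr, cc = draw_ellipse(cy, cx, b, a, shape=img.shape)
    img[rr, cc] = params.body_level

    if params.with_scale_bar:
        bar_y = int(round(h * 0.9))
        bar_x0 = int(round(w * 0.1))
        img[bar_y : bar_y + 4, bar_x0 : bar_x0 + params.bar_px] = 20.0

    sigma = float(rng.uniform(*params.blur_sigma))
    if sigma > 0:
        img = gaussian_filter(img, sigma=sigma)
    if params.noise_sigma > 0:
        img = img + rng.normal(0.0, params.noise_sigma, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    points = [snout, hypural] if params.n_landmarks == 2 else [snout, hypural, fork, dorsal]
    landmarks = [Landmark(index=i, x=int(x), y=int(y)) for i, (x, y) in enumerate(points)]
    return img, landmarks


def generate_dataset(
    n: int,
    params: FixtureParams,
    out_dir: Path | str,
    overwrite: bool = False,
    xml_name: str = "landmarks.xml",
) -> Tuple[Path, LandmarkDataset]:
    """Write ``n`` fixture images plus one ground-truth XML into ``out_dir``.

    File paths inside the XML are relative to ``out_dir`` so the directory
    is relocatable. Refuses to write into an existing non-empty directory
    unless ``overwrite`` is set.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"{out_dir} exists and is not empty (use overwrite=True)")
    out_dir.mkdir(parents=True, exist_ok=True)

    annotations = []
    for i in range(n):
        img, lms = generate_fish_image(params, i)
        name = f"fish_{i:04d}.png"
        Image.fromarray(img).save(out_dir / name)
        annotations.append(
            ImageAnnotation(
                file_path=name,
                landmarks=tuple(lms),
                width=params.width,
                height=params.height,
            )
        )
    dataset = LandmarkDataset(annotations)
    write_landmark_xml(dataset, out_dir / xml_name)
    return out_dir, dataset
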