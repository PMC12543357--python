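"""Batch prediction and CSV export of landmarks and inter-landmark lengths."""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from PIL import Image

from finmark.annotations import (
    ImageAnnotation,
    LandmarkDataset,
    render_overlay,
    write_landmark_xml,
)
from finmark.scalebar import ScaleCalibration
from finmark.shape_model import PredictorModel, predict_landmarks
from finmark.shape_model.model import load_gray

logger = logging.getLogger(__name__)

__all__ = ["export_csv", "pipeline_predict", "IMAGE_SUFFIXES"]

IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg")

#: Named landmark pair used for standard length in the 2-landmark schema:
#: snout tip (0) to body-fin junction (1).
STANDARD_LENGTH_PAIR: Tuple[int, int, str] = (0, 1, "standard_length")


def export_csv(
    predictions: LandmarkDataset,
    pairs: Sequence[Tuple[int, int, str]],
    out_path: Union[str, Path],
    calibrations: Optional[Dict[str, ScaleCalibration]] = None,
    failures: Sequence[str] = (),
) -> pd.DataFrame:
    """Write one measurement row per image.

    Columns: ``image``, per-landmark ``lm<k>_x``/``lm<k>_y``, one
    ``<name>_px`` per named pair (plus ``<name>_mm`` when calibrations are
    supplied), and ``status`` (``ok`` / ``scalebar_failed`` /
    ``predict_failed``). Pixel distances are always emitted; a missing
    calibration only downgrades the row's status.
    """
    n_lm = predictions.n_landmarks
    for i, j, name in pairs:
        if not (0 <= i < n_lm and 0 <= j < n_lm):
            raise ValueError(f"pair '{name}' indices ({i}, {j}) out of range for "
                             f"{n_lm} landmarks")
    want_mm = calibrations is not None

    columns = ["image"]
    for k in range(n_lm):
        columns += [f"lm{k}_x", f"lm{k}_y"]
    for _, _, name in pairs:
        columns.append(f"{name}_px")
        if want_mm:
            columns.append(f"{name}_mm")
    columns.append("status")

    rows: List[dict] = []
    for ann in predictions:
        row: dict = {"image": ann.file_path}
        for lm in ann.landmarks:
            row[f"lm{lm.index}_x"] = lm.x
            row[f"lm{lm.index}_y"] = lm.y
        status = "ok"
        cal = calibrations.get(ann.file_path) if want_mm else None
        if want_mm and cal is None:
            cal = calibrations.get(Path(ann.file_path).name)
        for i, j, name in pairs:
            a, b = ann.landmarks[i], ann.landmarks[j]
            d = math.hypot(a.x - b.x, a.y - b.y)
            row[f"{name}_px"] = d
            if want_mm:
                if cal is not None:
                    row[f"{name}_mm"] = d * cal.mm_per_px
                else:
                    row[f"{name}_mm"] = np.nan
                    status = "scalebar_failed"
        row["status"] = status
        rows.append(row)
    for path in failures:
        rows.append({"image": path, "status": "predict_failed"})

    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(out_path, index=False)
    logger.info("wrote %d measurement rows to %s", len(df), out_path)
    return df


def pipeline_predict(
    model: PredictorModel,
    image_dir: Union[str, Path],
    out_xml: Optional[Union[str, Path]] = None,
    overlay_dir: Optional[Union[str, Path]] = None,
    marker_radius: int = 4,
) -> Tuple[LandmarkDataset, List[str]]:
    """Predict landmarks on every image in a directory.

    Returns the prediction dataset plus the list of files that failed;
    per-image failures are logged and the batch completes. Optionally
    writes the predictions as landmark XML and overlay PNGs for visual
    confirmation.
    """
    image_dir = Path(image_dir)
    paths = sorted(
        p for p in image_dir.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES
    )
    if not paths:
        raise ValueError(f"no images ({'/'.join(IMAGE_SUFFIXES)}) in {image_dir}")
    if overlay_dir is not None:
        overlay_dir = Path(overlay_dir)
        overlay_dir.mkdir(parents=True, exist_ok=True)

    annotations: List[ImageAnnotation] = []
    failures: List[str] = []
    for path in paths:
        try:
            gray = load_gray(path)
            lms = predict_landmarks(model, gray)
        except Exception as exc:  # noqa: BLE001 - batch mode must not crash
            logger.warning("prediction failed for %s: %s", path.name, exc)
            failures.append(path.name)
            continue
        annotations.append(
            ImageAnnotation(
                file_path=path.name,
                landmarks=tuple(lms),
                width=gray.shape[1],
                height=gray.shape[0],
            )
        )
        if overlay_dir is not None:
            overlay = render_overlay(gray, lms, radius=marker_radius)
            Image.fromarray(overlay).save(overlay_dir / f"{path.stem}_overlay.png")
    predictions = LandmarkDataset(annotations)
    if out_xml is not None:
        write_landmark_xml(predictions, out_xml)
    return predictions, failures
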