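"""Model-level API: training, prediction, evaluation, and serialization."""

from __future__ import annotations

import hashlib
import json
import pickle
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Union

import numpy as np
from PIL import Image

from finmark.annotations import Landmark, LandmarkDataset
from finmark.shape_model.cascade import FittedCascade, predict_shape, train_cascade
from finmark.shape_model.params import Hyperparameters

__all__ = [
    "PredictorModel",
    "train_predictor",
    "predict_landmarks",
    "mean_deviation",
    "save_model",
    "load_model",
    "load_gray",
    "dataset_hash",
]


def load_gray(path: Union[str, Path]) -> np.ndarray:
    """Load an image file as a 2-D uint8 grayscale array."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"image not found: {p}")
    with Image.open(p) as img:
        return np.asarray(img.convert("L"), dtype=np.uint8)


def _as_gray(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim == 3:
        # Luminance weights; matches PIL's "L" conversion closely enough
        # for feature extraction.
        arr = (0.299 * arr[..., 0] + 0.587 * arr[..., 1] + 0.114 * arr[..., 2])
    return arr.astype(np.uint8)


def dataset_hash(dataset: LandmarkDataset) -> str:
    """Stable content hash of file paths and landmark coordinates."""
    h = hashlib.sha256()
    for img in dataset:
        h.update(img.file_path.encode())
        for lm in img.landmarks:
            h.update(f"{lm.index},{lm.x},{lm.y};".encode())
    return h.hexdigest()


@dataclass
class PredictorModel:
    """A trained shape predictor plus its provenance."""

    n_landmarks: int
    hyperparameters: Hyperparameters
    cascade: FittedCascade
    training_seed: int
    training_hash: str
    provenance: Optional[dict] = None


def _resolve(file_path: str, image_root: Optional[Union[str, Path]]) -> Path:
    p = Path(file_path)
    if image_root is not None and not p.is_absolute():
        return Path(image_root) / p
    return p


def train_predictor(
    train: LandmarkDataset,
    hp: Hyperparameters,
    seed: int,
    image_root: Optional[Union[str, Path]] = None,
) -> PredictorModel:
    """Train a shape predictor on an annotated dataset.

    Deterministic given ``(train, hp, seed)``. Raises on an empty dataset,
    a dataset with zero landmarks, or an unreadable image (the error names
    the file).
    """
    if len(train) == 0:
        raise ValueError("training dataset is empty")
    if train.n_landmarks == 0:
        raise ValueError("training dataset has zero landmarks")
    images: List[np.ndarray] = []
    boxes = np.empty((len(train), 4))
    shapes = np.empty((len(train), train.n_landmarks, 2))
    for i, ann in enumerate(train):
        gray = load_gray(_resolve(ann.file_path, image_root))
        images.append(gray)
        if ann.box is not None:
            boxes[i] = (ann.box.left, ann.box.top, ann.box.width, ann.box.height)
        else:
            boxes[i] = (0, 0, gray.shape[1], gray.shape[0])
        shapes[i] = ann.shape_array()
    cascade = train_cascade(images, shapes, boxes, hp, seed)
    return PredictorModel(
        n_landmarks=train.n_landmarks,
        hyperparameters=hp,
        cascade=cascade,
        training_seed=seed,
        training_hash=dataset_hash(train),
    )


def predict_landmarks(model: PredictorModel, image: np.ndarray) -> List[Landmark]:
    """Predict landmarks on one image; coordinates are clamped to the frame."""
    gray = _as_gray(image)
    if gray.size == 0:
        raise ValueError("empty image")
    px = predict_shape(model.cascade, gray)
    h, w = gray.shape
    out = []
    for i, (x, y) in enumerate(px):
        xi = int(min(max(round(float(x)), 0), w - 1))
        yi = int(min(max(round(float(y)), 0), h - 1))
        out.append(Landmark(index=i, x=xi, y=yi))
    return out


def mean_deviation(
    model: PredictorModel,
    eval_set: LandmarkDataset,
    image_root: Optional[Union[str, Path]] = None,
) -> float:
    """Mean Euclidean pixel distance between predicted and true landmarks,
    averaged over every (image, landmark) pair of ``eval_set``."""
    if len(eval_set) == 0:
        raise ValueError("evaluation dataset is empty")
    if eval_set.n_landmarks != model.n_landmarks:
        raise ValueError(
            f"landmark count mismatch: model has {model.n_landmarks}, "
            f"dataset has {eval_set.n_landmarks}"
        )
    total = 0.0
    count = 0
    for ann in eval_set:
        gray = load_gray(_resolve(ann.file_path, image_root))
        pred = predict_shape(model.cascade, gray)
        truth = ann.shape_array()
        total += float(np.linalg.norm(pred - truth, axis=1).sum())
        count += model.n_landmarks
    return total / count


def save_model(model: PredictorModel, path: Union[str, Path]) -> None:
    """Serialize to one binary file plus a JSON sidecar (``<path>.json``)
    recording hyperparameters, seed, landmark count, and training-set hash."""
    path = Path(path)
    with open(path, "wb") as fh:
        pickle.dump(model, fh, protocol=pickle.HIGHEST_PROTOCOL)
    sidecar = {
        "n_landmarks": model.n_landmarks,
        "hyperparameters": model.hyperparameters.to_dict(),
        "training_seed": model.training_seed,
        "training_hash": model.training_hash,
    }
    if model.provenance:
        sidecar["provenance"] = model.provenance
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_model(path: Union[str, Path]) -> PredictorModel:
    with open(path, "rb") as fh:
        model = pickle.load(fh)
    if not isinstance(model, PredictorModel):
        raise ValueError(f"{path} does not contain a PredictorModel")
    return model
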