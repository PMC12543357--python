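"""Landmark annotation I/O in the image/box/part XML dialect, plus overlay rendering.

Manual ground truth, training sets, and model predictions all share this
one on-disk representation.  Coordinates follow the screen convention:
origin (0, 0) at the upper-left corner, x grows rightward, y grows
downward, integer pixel-centre addressing.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence, Tuple, Union

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Landmark",
    "Box",
    "ImageAnnotation",
    "LandmarkDataset",
    "AnnotationParseError",
    "SchemaError",
    "read_landmark_xml",
    "write_landmark_xml",
    "render_overlay",
]


class AnnotationParseError(ValueError):
    """Raised when a landmark XML file is malformed."""


class SchemaError(ValueError):
    """Raised when a dataset violates the homogeneous-landmark-count schema."""


@dataclass(frozen=True)
class Landmark:
    """One anatomical point: ordinal identity plus integer pixel coordinates."""

    index: int
    x: int
    y: int

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError(f"landmark index must be >= 0, got {self.index}")
        if self.x < 0 or self.y < 0:
            raise ValueError(f"landmark coordinates must be >= 0, got ({self.x}, {self.y})")

    @property
    def name(self) -> str:
        """Zero-padded part name used in the XML (width 2 minimum)."""
        return f"{self.index:0{max(2, len(str(self.index)))}d}"

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle in pixels (left, top, width, height)."""

    left: int
    top: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("box width and height must be positive")

    def contains(self, x: float, y: float) -> bool:
        return (
            self.left <= x < self.left + self.width
            and self.top <= y < self.top + self.height
        )


@dataclass
class ImageAnnotation:
    """One image entry: file path, optional frame size, box, ordered landmarks."""

    file_path: str
    landmarks: Tuple[Landmark, ...] = ()
    width: Optional[int] = None
    height: Optional[int] = None
    box: Optional[Box] = None

    def __post_init__(self) -> None:
        self.landmarks = tuple(self.landmarks)
        indices = [lm.index for lm in self.landmarks]
        if indices != list(range(len(indices))):
            raise SchemaError(
                f"{self.file_path}: landmark indices must be unique and contiguous "
                f"from 0, got {indices}"
            )
        if self.box is None and self.width is not None and self.height is not None:
            # Default box = full frame; the pipeline has no detection stage.
            self.box = Box(0, 0, self.width, self.height)
        self._validate_geometry()

    def _validate_geometry(self) -> None:
        if self.width is not None and self.height is not None:
            for lm in self.landmarks:
                if lm.x >= self.width or lm.y >= self.height:
                    raise SchemaError(
                        f"{self.file_path}: landmark {lm.index} at ({lm.x}, {lm.y}) "
                        f"outside {self.width}x{self.height} frame"
                    )
            if self.box is not None:
                if (
                    self.box.left < 0
                    or self.box.top < 0
                    or self.box.left + self.box.width > self.width
                    or self.box.top + self.box.height > self.height
                ):
                    raise SchemaError(f"{self.file_path}: box extends outside the frame")
        if self.box is not None:
            for lm in self.landmarks:
                if not self.box.contains(lm.x, lm.y):
                    raise SchemaError(
                        f"{self.file_path}: landmark {lm.index} at ({lm.x}, {lm.y}) "
                        f"outside box {self.box}"
                    )

    @property
    def n_landmarks(self) -> int:
        return len(self.landmarks)

    def shape_array(self) -> np.ndarray:
        """Landmarks as an (n, 2) float array in ordinal order."""
        return np.array([[lm.x, lm.y] for lm in self.landmarks], dtype=float).reshape(-1, 2)


@dataclass
class LandmarkDataset:
    """Homogeneous collection of annotated images (equal landmark count each)."""

    images: list[ImageAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts = {img.file_path: img.n_landmarks for img in self.images}
        if len(counts) != len(self.images):
            seen: set[str] = set()
            dupes = sorted(
                {p for img in self.images if (p := img.file_path) in seen or seen.add(p)}
            )
            raise SchemaError(f"duplicate image file paths: {dupes}")
        if self.images:
            n = self.images[0].n_landmarks
            offending = sorted(p for p, c in counts.items() if c != n)
            if offending:
                raise SchemaError(
                    f"heterogeneous landmark counts (expected {n}): {offending}"
                )

    @property
    def n_landmarks(self) -> int:
        return self.images[0].n_landmarks if self.images else 0

    def __len__(self) -> int:
        return len(self.images)

    def __iter__(self) -> Iterator[ImageAnnotation]:
        return iter(self.images)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LandmarkDataset):
            return NotImplemented
        return self.images == other.images

    def subset(self, indices: Sequence[int]) -> "LandmarkDataset":
        return LandmarkDataset([self.images[i] for i in indices])

    def file_paths(self) -> list[str]:
        return [img.file_path for img in self.images]


def _require_attr(elem: ET.Element, attr: str, path: Union[str, Path]) -> str:
    value = elem.get(attr)
    if value is None:
        raise AnnotationParseError(
            f"{path}: <{elem.tag}> element missing required attribute '{attr}'"
        )
    return value


def read_landmark_xml(path: Union[str, Path]) -> LandmarkDataset:
    """Read a landmark XML file in the image/box/part dialect.

    Preserves image order and landmark ordinal order (part names sort
    lexicographically == ordinally because they are zero-padded).
    Raises :class:`AnnotationParseError` on malformed XML and
    :class:`SchemaError` on heterogeneous landmark counts.
    """
    path = Path(path)
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise AnnotationParseError(f"{path}: malformed XML ({exc})") from exc
    root = tree.getroot()
    if root.tag != "dataset":
        raise AnnotationParseError(f"{path}: root element is <{root.tag}>, expected <dataset>")
    images_elem = root.find("images")
    if images_elem is None:
        raise AnnotationParseError(f"{path}: missing <images> element")

    images: list[ImageAnnotation] = []
    for image_elem in images_elem.findall("image"):
        file_path = _require_attr(image_elem, "file", path)
        width = image_elem.get("width")
        height = image_elem.get("height")
        box_elem = image_elem.find("box")
        box = None
        parts: list[Landmark] = []
        if box_elem is not None:
            try:
                box = Box(
                    left=int(_require_attr(box_elem, "left", path)),
                    top=int(_require_attr(box_elem, "top", path)),
                    width=int(_require_attr(box_elem, "width", path)),
                    height=int(_require_attr(box_elem, "height", path)),
                )
            except ValueError as exc:
                raise AnnotationParseError(f"{path}: bad <box> for {file_path}: {exc}") from exc
            named = []
            for part in box_elem.findall("part"):
                name = _require_attr(part, "name", path)
                try:
                    named.append(
                        (name, int(_require_attr(part, "x", path)), int(_require_attr(part, "y", path)))
                    )
                except ValueError as exc:
                    raise AnnotationParseError(
                        f"{path}: non-integer coordinate in <part name='{name}'> of {file_path}"
                    ) from exc
            named.sort(key=lambda t: t[0])
            parts = [Landmark(index=i, x=x, y=y) for i, (_, x, y) in enumerate(named)]
        images.append(
            ImageAnnotation(
                file_path=file_path,
                landmarks=tuple(parts),
                width=int(width) if width is not None else None,
                height=int(height) if height is not None else None,
                box=box,
            )
        )
    return LandmarkDataset(images)


def write_landmark_xml(dataset: LandmarkDataset, path: Union[str, Path]) -> None:
    """Write a dataset as one XML document; re-reading yields an equal dataset."""
    root = ET.Element("dataset")
    ET.SubElement(root, "name").text = "finmark landmark dataset"
    images_elem = ET.SubElement(root, "images")
    for img in dataset.images:
        attrs = {"file": img.file_path}
        if img.width is not None:
            attrs["width"] = str(img.width)
        if img.height is not None:
            attrs["height"] = str(img.height)
        image_elem = ET.SubElement(images_elem, "image", attrs)
        box = img.box
        if box is None and img.width is not None and img.height is not None:
            box = Box(0, 0, img.width, img.height)
        if box is not None or img.landmarks:
            if box is None:
                # No frame size recorded: synthesize a box covering the landmarks.
                max_x = max((lm.x for lm in img.landmarks), default=0)
                max_y = max((lm.y for lm in img.landmarks), default=0)
                box = Box(0, 0, max_x + 1, max_y + 1)
            box_elem = ET.SubElement(
                image_elem,
                "box",
                {
                    "top": str(box.top),
                    "left": str(box.left),
                    "width": str(box.width),
                    "height": str(box.height),
                },
            )
            for lm in img.landmarks:
                ET.SubElement(
                    box_elem, "part", {"name": lm.name, "x": str(lm.x), "y": str(lm.y)}
                )
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode", xml_declaration=True)


def render_overlay(
    image: np.ndarray,
    landmarks: Sequence[Landmark],
    radius: int = 4,
    color: Union[int, Tuple[int, int, int]] = (255, 0, 0),
) -> np.ndarray:
    """Return a copy of ``image`` with a filled disc centred on each landmark.

    Grayscale input is promoted to RGB so coloured markers are visible.
    Out-of-frame landmarks are clamped to the frame with a logged warning
    (batch rendering must never crash on a stray prediction).
    """
    out = np.asarray(image).copy()
    if out.ndim == 2:
        out = np.stack([out] * 3, axis=-1)
    h, w = out.shape[:2]
    if isinstance(color, int):
        color = (color, color, color)
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    disc = (xx**2 + yy**2) <= radius**2
    for lm in landmarks:
        cx, cy = lm.x, lm.y
        if not (0 <= cx < w and 0 <= cy < h):
            logger.warning(
                "landmark %d at (%d, %d) outside %dx%d frame; clamping", lm.index, cx, cy, w, h
            )
            cx = min(max(cx, 0), w - 1)
            cy = min(max(cy, 0), h - 1)
        y0, y1 = cy - radius, cy + radius + 1
        x0, x1 = cx - radius, cx + radius + 1
        dy0, dx0 = max(0, -y0), max(0, -x0)
        y0, x0 = max(0, y0), max(0, x0)
        y1, x1 = min(h, y1), min(w, x1)
        patch = disc[dy0 : dy0 + (y1 - y0), dx0 : dx0 + (x1 - x0)]
        out[y0:y1, x0:x1][patch] = color
    return out
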