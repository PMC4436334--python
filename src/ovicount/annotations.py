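"""Dot annotations and rectangular regions of interest.

Each egg is labelled by a single pixel at its centre ("dot annotation"),
either as a binary mask image (the point-tool export convention: any
nonzero pixel marks one egg) or as a two-column ``row,col`` CSV.  ROIs are
axis-aligned, half-open rectangles ``[row, row+height) x [col, col+width)``
in 0-based row-major coordinates; the same convention is used everywhere
else in the package.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Tuple

import imageio.v3 as iio
import numpy as np

Dot = Tuple[int, int]


@dataclass(frozen=True)
class ROI:
    """Half-open rectangle ``[row, row+height) x [col, col+width)``."""

    row: int
    col: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError(f"ROI must cover at least one pixel, got {self}")
        if self.row < 0 or self.col < 0:
            raise ValueError(f"ROI origin must be non-negative, got {self}")

    @property
    def area(self) -> int:
        return self.height * self.width

    def contains(self, row: int, col: int) -> bool:
        return (self.row <= row < self.row + self.height
                and self.col <= col < self.col + self.width)

    def validate_for_shape(self, shape: Tuple[int, int]) -> None:
        h, w = shape[:2]
        if self.row + self.height > h or self.col + self.width > w:
            raise ValueError(f"{self} does not fit inside image of shape {(h, w)}")

    def slices(self) -> Tuple[slice, slice]:
        return (slice(self.row, self.row + self.height),
                slice(self.col, self.col + self.width))

    @staticmethod
    def whole_image(shape: Tuple[int, int]) -> "ROI":
        return ROI(0, 0, int(shape[0]), int(shape[1]))


@dataclass
class DotAnnotation:
    """Ordered list of (row, col) egg-centre pixels for one image.

    Duplicates are allowed: two eggs whose centres round to the same pixel
    are two dots.  Mask images cannot express that case; the CSV dialect can.
    """

    image_id: str
    dots: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.dots)

    def __iter__(self):
        return iter(self.dots)

    def validate_for_shape(self, shape: Tuple[int, int]) -> None:
        h, w = shape[:2]
        for d in self.dots:
            r, c = d
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError(
                    f"dot {d!r} of annotation {self.image_id!r} lies outside "
                    f"image of shape {(h, w)}")


def read_dot_mask(mask, image_id: str = "") -> DotAnnotation:
    """Decode a point-export mask: one dot per strictly positive pixel.

    ``mask`` may be a 2-D array or a path to a single-channel PNG/TIFF.
    Dots are returned in row-major scan order.  An all-zero mask is a valid
    empty annotation.
    """
    if isinstance(mask, (str, os.PathLike)):
        if not image_id:
            image_id = Path(mask).stem
        mask = iio.imread(mask)
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"dot mask must be 2-D, got shape {mask.shape}")
    rows, cols = np.nonzero(mask > 0)
    dots = [(int(r), int(c)) for r, c in zip(rows, cols)]
    return DotAnnotation(image_id=image_id, dots=dots)


def rasterize_dots(ann: DotAnnotation, shape: Tuple[int, int]) -> np.ndarray:
    """Inverse of :func:`read_dot_mask` for annotations with <=1 dot/pixel."""
    ann.validate_for_shape(shape)
    mask = np.zeros(shape[:2], dtype=np.uint8)
    for r, c in ann.dots:
        mask[r, c] = 255
    return mask


def read_dots_csv(path, image_id: str = "") -> DotAnnotation:
    """Read a ``row,col`` CSV (header required) into an annotation."""
    path = Path(path)
    if not image_id:
        image_id = path.stem.removesuffix("_dots")
    dots: list = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header[:2]] != ["row", "col"]:
            raise ValueError(f"{path}: expected header 'row,col', got {header!r}")
        for lineno, rec in enumerate(reader, start=2):
            if not rec or (len(rec) == 1 and not rec[0].strip()):
                continue
            try:
                r, c = int(rec[0]), int(rec[1])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed row at line {lineno}: {rec!r}") from exc
            dots.append((r, c))
    return DotAnnotation(image_id=image_id, dots=dots)


def write_dots_csv(ann: DotAnnotation, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["row", "col"])
        for r, c in ann.dots:
            writer.writerow([r, c])


def dots_in_roi(ann: DotAnnotation, roi: ROI) -> DotAnnotation:
    """Subset of dots falling inside the half-open rectangle.

    The count of the result is the "actual count" (AC) for that region,
    used when fitting the bias-correction line.
    """
    kept = [d for d in ann.dots if roi.contains(*d)]
    return DotAnnotation(image_id=ann.image_id, dots=kept)


# -- file pairing -----------------------------------------------------------

MASK_SUFFIX = "_dots.png"
CSV_SUFFIX = "_dots.csv"


def annotation_path_for(image_path, suffix: str = CSV_SUFFIX) -> Path:
    """Companion annotation path: ``<stem><suffix>`` next to the image."""
    image_path = Path(image_path)
    return image_path.with_name(image_path.stem + suffix)


def load_annotation_for(image_path, annotations_dir=None) -> DotAnnotation:
    """Locate and read the companion annotation (CSV preferred, then mask)."""
    image_path = Path(image_path)
    stem = image_path.stem
    dirs = [Path(annotations_dir)] if annotations_dir is not None else []
    dirs.append(image_path.parent)
    for d in dirs:
        csv_path = d / (stem + CSV_SUFFIX)
        if csv_path.exists():
            return read_dots_csv(csv_path, image_id=stem)
        mask_path = d / (stem + MASK_SUFFIX)
        if mask_path.exists():
            return read_dot_mask(mask_path, image_id=stem)
    raise FileNotFoundError(
        f"no annotation ({stem}{CSV_SUFFIX} or {stem}{MASK_SUFFIX}) found for {image_path}")


def read_rois_csv(path) -> dict:
    """Read per-image ROIs from a CSV with columns image,row,col,height,width."""
    out: dict = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"image", "row", "col", "height", "width"}
        if reader.fieldnames is None or not required.issubset(set(reader.fieldnames)):
            raise ValueError(f"{path}: ROI file needs columns {sorted(required)}")
        for lineno, rec in enumerate(reader, start=2):
            try:
                roi = ROI(int(rec["row"]), int(rec["col"]),
                          int(rec["height"]), int(rec["width"]))
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path}: malformed ROI at line {lineno}") from exc
            out.setdefault(rec["image"], []).append(roi)
    return out
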