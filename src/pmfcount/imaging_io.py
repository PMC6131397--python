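"""Slide and annotation I/O.

Slides are single-plane TIFF images (LZW-compressed or not), read into
:class:`SlideImage` grids with resolution metadata. Ground-truth follicle
clicks travel as CSV rows (``slide_id,x,y,follicle_class``) with 0-based
pixel coordinates in the full-resolution slide frame: ``x`` is the column
(rightward), ``y`` the row (downward). Detection output is written as PNG
crops plus an annotated overview image.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile
from PIL import Image, ImageDraw

from .errors import AnnotationParseError, FormatError, ValidationError

#: The four Pedersen-derived follicle stages carried by annotations.
FOLLICLE_CLASSES = ("primordial", "primary", "secondary", "antral")

#: ITU-R BT.601 luminance weights used for color removal.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class SlideImage:
    """A whole-slide image with resolution metadata.

    ``scale_factor`` is the ratio of the current resolution to the native
    one (1.0 = native); ``microns_per_pixel`` always describes the current
    pixel grid.
    """

    pixels: np.ndarray
    microns_per_pixel: float
    slide_id: str
    scale_factor: float = 1.0

    def __post_init__(self):
        if self.microns_per_pixel <= 0:
            raise ValidationError("microns_per_pixel must be positive")
        if not (0 < self.scale_factor <= 1):
            raise ValidationError("scale_factor must be in (0, 1]")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class Annotation:
    """A ground-truth follicle click in full-resolution slide coordinates."""

    slide_id: str
    x: int
    y: int
    follicle_class: str

    def __post_init__(self):
        if self.x < 0 or self.y < 0:
            raise ValidationError(
                f"negative coordinate ({self.x}, {self.y}) for slide {self.slide_id}"
            )
        if self.follicle_class not in FOLLICLE_CLASSES:
            raise ValidationError(
                f"unknown follicle class {self.follicle_class!r}; "
                f"expected one of {FOLLICLE_CLASSES}"
            )


@dataclass
class DetectionReport:
    """Bookkeeping for detection artifacts written to disk."""

    detections: list = field(default_factory=list)
    crops_written: int = 0
    overview_written: bool = False


def to_grayscale(pixels: np.ndarray) -> np.ndarray:
    """Collapse a 3-channel image to one luminance value per pixel."""
    if pixels.ndim == 2:
        return pixels
    if pixels.ndim == 3 and pixels.shape[2] in (3, 4):
        rgb = pixels[..., :3].astype(np.float64)
        gray = rgb @ np.asarray(LUMA_WEIGHTS)
        return np.clip(np.rint(gray), 0, 255).astype(np.uint8)
    raise FormatError(f"unsupported pixel layout with shape {pixels.shape}")


def _downsample(pixels: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean downsample by an integer factor (trailing remainder cropped)."""
    if factor == 1:
        return pixels
    h, w = pixels.shape[:2]
    h2, w2 = h // factor, w // factor
    if h2 == 0 or w2 == 0:
        raise ValidationError(f"downsample factor {factor} exceeds image size {h}x{w}")
    cropped = pixels[: h2 * factor, : w2 * factor].astype(np.float64)
    blocks = cropped.reshape(h2, factor, w2, factor).mean(axis=(1, 3))
    return np.clip(np.rint(blocks), 0, 255).astype(pixels.dtype)


def read_slide(
    path,
    downsample_factor: int = 1,
    *,
    microns_per_pixel: float = 1.0,
    slide_id: str | None = None,
    color_removal: bool = True,
) -> SlideImage:
    """Read a single-plane TIFF slide, optionally downsampling.

    The returned image has ``scale_factor = 1/downsample_factor`` and its
    ``microns_per_pixel`` scaled accordingly. 3-channel input is converted
    to grayscale when ``color_removal`` is enabled.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"slide file not found: {path}")
    if downsample_factor < 1:
        raise ValidationError("downsample_factor must be a positive integer")
    try:
        pixels = tifffile.imread(str(path))
    except Exception as exc:  # tifffile raises assorted codec errors
        raise FormatError(f"cannot decode TIFF {path.name}: {exc}") from exc
    if pixels.ndim not in (2, 3):
        raise FormatError(f"expected a single-plane TIFF, got shape {pixels.shape}")
    if color_removal and pixels.ndim == 3:
        pixels = to_grayscale(pixels)
    pixels = _downsample(pixels, downsample_factor)
    return SlideImage(
        pixels=pixels,
        microns_per_pixel=microns_per_pixel * downsample_factor,
        slide_id=slide_id if slide_id is not None else path.stem,
        scale_factor=1.0 / downsample_factor,
    )


def write_slide(path, slide: SlideImage, compression: str | None = None) -> None:
    """Write a slide as TIFF; ``compression='lzw'`` enables LZW."""
    tifffile.imwrite(str(path), slide.pixels, compression=compression)


_ANNOTATION_HEADER = ["slide_id", "x", "y", "follicle_class"]


def read_annotations(path) -> list[Annotation]:
    """Read follicle click annotations from CSV, preserving file order.

    Raises :class:`AnnotationParseError` with the offending 1-based line
    number on malformed rows, unknown classes or negative coordinates.
    """
    path = Path(path)
    annotations: list[Annotation] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != _ANNOTATION_HEADER:
            raise AnnotationParseError(
                f"expected header {','.join(_ANNOTATION_HEADER)}", line=1
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 4:
                raise AnnotationParseError(
                    f"expected 4 fields, got {len(row)}", line=lineno
                )
            slide_id, xs, ys, cls = (f.strip() for f in row)
            try:
                x, y = int(xs), int(ys)
            except ValueError:
                raise AnnotationParseError(
                    f"non-integer coordinate {xs!r},{ys!r}", line=lineno
                ) from None
            try:
                annotations.append(Annotation(slide_id, x, y, cls))
            except ValidationError as exc:
                raise AnnotationParseError(str(exc), line=lineno) from None
    return annotations


def write_annotations(path, annotations: Iterable[Annotation]) -> None:
    """Write annotations to CSV in the interchange schema."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_ANNOTATION_HEADER)
        for ann in annotations:
            writer.writerow([ann.slide_id, ann.x, ann.y, ann.follicle_class])


def _to_uint8(pixels: np.ndarray) -> np.ndarray:
    if pixels.dtype == np.uint8:
        return pixels
    return np.clip(np.rint(pixels), 0, 255).astype(np.uint8)


def write_detection_report(
    detections: Sequence,
    section,
    out_dir,
    *,
    save_crops: bool = True,
) -> DetectionReport:
    """Write one PNG crop per detection plus an annotated overview image.

    The overview shows the section with a square outline per detection
    frame; crops at the section border are clamped to the image bounds.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pixels = _to_uint8(section.pixels)
    h, w = pixels.shape

    crops_written = 0
    if save_crops:
        for i, det in enumerate(detections):
            f = det.frame
            x0, y0 = max(0, f.x), max(0, f.y)
            x1, y1 = min(w, f.x + f.size), min(h, f.y + f.size)
            crop = pixels[y0:y1, x0:x1]
            Image.fromarray(crop).save(
                out_dir / f"{section.slide_id}_s{section.section_id}_det{i:04d}.png"
            )
            crops_written += 1

    overview = Image.fromarray(pixels).convert("RGB")
    draw = ImageDraw.Draw(overview)
    for det in detections:
        f = det.frame
        draw.rectangle(
            [f.x, f.y, min(w - 1, f.x + f.size - 1), min(h - 1, f.y + f.size - 1)],
            outline=(255, 0, 0),
            width=2,
        )
    overview_path = out_dir / f"{section.slide_id}_s{section.section_id}_overview.png"
    overview.save(overview_path)

    return DetectionReport(
        detections=list(detections),
        crops_written=crops_written,
        overview_written=True,
    )
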