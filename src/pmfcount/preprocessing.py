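"""Section isolation: binarize the slide, find tissue contours, crop.

A histology slide holds several ovarian sections on a bright background.
Contour detection runs on a further-downsampled binary mask for speed, one
bounding box per outer contour above a minimum area; boxes are expanded by
a margin, merged when overlapping and cropped from the working-resolution
slide. Annotation coordinates (stored at full resolution) are rescaled on
the fly when mapped into a section crop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .errors import ConfigurationError, ValidationError
from .imaging_io import Annotation, SlideImage

logger = logging.getLogger(__name__)

#: Sentinel returned by :func:`to_section_coords` for clicks outside a crop.
OUTSIDE = "outside"

DEFAULT_EXTRA_DOWNSAMPLE = 4
DEFAULT_MIN_AREA_FRAC = 0.005  # of total slide area
DEFAULT_MARGIN_FRAC = 0.02  # of box diagonal


@dataclass
class SectionBox:
    """Axis-aligned bounding box of one tissue section (working resolution)."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self):
        if self.w <= 0 or self.h <= 0:
            raise ValidationError("section box must have positive width and height")

    @property
    def area(self) -> int:
        return self.w * self.h

    def overlaps(self, other: "SectionBox") -> bool:
        return (
            self.x < other.x + other.w
            and other.x < self.x + self.w
            and self.y < other.y + other.h
            and other.y < self.y + self.h
        )

    def union(self, other: "SectionBox") -> "SectionBox":
        x0 = min(self.x, other.x)
        y0 = min(self.y, other.y)
        x1 = max(self.x + self.w, other.x + other.w)
        y1 = max(self.y + self.h, other.y + other.h)
        return SectionBox(x0, y0, x1 - x0, y1 - y0)


@dataclass
class SectionImage:
    """One isolated section crop with its offset in the slide frame."""

    pixels: np.ndarray
    offset_x: int
    offset_y: int
    section_id: int
    slide_id: str

    def __post_init__(self):
        if self.offset_x < 0 or self.offset_y < 0:
            raise ValidationError("section offsets must be non-negative")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def binarize(
    image: SlideImage | np.ndarray,
    method: str = "otsu",
    fixed_threshold: float | None = None,
) -> np.ndarray:
    """Binarize a grayscale slide; tissue (darker than background) maps to 1.

    ``otsu`` picks the threshold maximizing between-class variance;
    ``fixed`` uses ``fixed_threshold``. A constant image yields an all-zero
    mask (no tissue darker than background).
    """
    pixels = image.pixels if isinstance(image, SlideImage) else image
    if pixels.ndim != 2:
        raise ValidationError("binarize expects a grayscale image")
    if method == "otsu":
        if pixels.min() == pixels.max():
            return np.zeros(pixels.shape, dtype=bool)
        thresh = threshold_otsu(pixels)
    elif method == "fixed":
        if fixed_threshold is None:
            raise ConfigurationError("fixed binarization requires fixed_threshold")
        thresh = fixed_threshold
    else:
        raise ConfigurationError(f"unknown binarization method {method!r}")
    return pixels < thresh


def _coarsen(mask: np.ndarray, factor: int) -> np.ndarray:
    """Any-pooling downsample: a coarse cell is tissue if any fine pixel is."""
    if factor == 1:
        return mask
    h, w = mask.shape
    h2, w2 = -(-h // factor), -(-w // factor)
    padded = np.zeros((h2 * factor, w2 * factor), dtype=bool)
    padded[:h, :w] = mask
    return padded.reshape(h2, factor, w2, factor).any(axis=(1, 3))


def find_section_boxes(
    mask: np.ndarray,
    min_area: float | None = None,
    margin: float | None = None,
    extra_downsample: int = DEFAULT_EXTRA_DOWNSAMPLE,
) -> list[SectionBox]:
    """Bounding boxes of outer tissue contours in a binary mask.

    Contours are found on a further-downsampled copy of the mask (border
    following on connected components), filtered by ``min_area`` (px² at
    mask resolution, default 0.5% of the mask area), expanded by ``margin``
    px (default 2% of each box diagonal), clamped to bounds, merged when
    overlapping, and sorted top-to-bottom then left-to-right.
    """
    if mask.dtype != bool:
        mask = mask.astype(bool)
    h, w = mask.shape
    if min_area is None:
        min_area = DEFAULT_MIN_AREA_FRAC * h * w

    coarse = _coarsen(mask, extra_downsample)
    f = extra_downsample
    boxes: list[SectionBox] = []
    for region in regionprops(label(coarse, connectivity=2)):
        if region.area * f * f < min_area:
            continue
        r0, c0, r1, c1 = region.bbox  # half-open, coarse grid
        box = SectionBox(
            x=c0 * f,
            y=r0 * f,
            w=min(c1 * f, w) - c0 * f,
            h=min(r1 * f, h) - r0 * f,
        )
        m = margin if margin is not None else DEFAULT_MARGIN_FRAC * np.hypot(box.w, box.h)
        m = int(round(m))
        x0, y0 = max(0, box.x - m), max(0, box.y - m)
        x1, y1 = min(w, box.x + box.w + m), min(h, box.y + box.h + m)
        boxes.append(SectionBox(x0, y0, x1 - x0, y1 - y0))

    boxes = _merge_overlapping(boxes)
    boxes.sort(key=lambda b: (b.y, b.x))
    return boxes


def _merge_overlapping(boxes: list[SectionBox]) -> list[SectionBox]:
    """Merge pairwise-overlapping boxes into union boxes until stable."""
    merged = list(boxes)
    changed = True
    while changed:
        changed = False
        out: list[SectionBox] = []
        for box in merged:
            for i, other in enumerate(out):
                if box.overlaps(other):
                    out[i] = other.union(box)
                    changed = True
                    break
            else:
                out.append(box)
        merged = out
    return merged


def crop_sections(slide: SlideImage, boxes: Sequence[SectionBox]) -> list[SectionImage]:
    """Crop each box out of the slide; section_id is the box rank."""
    h, w = slide.pixels.shape[:2]
    sections = []
    for i, box in enumerate(boxes):
        if box.x < 0 or box.y < 0 or box.x + box.w > w or box.y + box.h > h:
            raise ValidationError(f"box {i} ({box}) lies outside the {w}x{h} slide")
        sections.append(
            SectionImage(
                pixels=slide.pixels[box.y : box.y + box.h, box.x : box.x + box.w],
                offset_x=box.x,
                offset_y=box.y,
                section_id=i,
                slide_id=slide.slide_id,
            )
        )
    return sections


def isolate_sections(
    slide: SlideImage,
    *,
    method: str = "otsu",
    fixed_threshold: float | None = None,
    min_area: float | None = None,
    margin: float | None = None,
    extra_downsample: int = DEFAULT_EXTRA_DOWNSAMPLE,
) -> list[SectionImage]:
    """Convenience composition: binarize -> find boxes -> crop."""
    mask = binarize(slide, method=method, fixed_threshold=fixed_threshold)
    boxes = find_section_boxes(
        mask, min_area=min_area, margin=margin, extra_downsample=extra_downsample
    )
    return crop_sections(slide, boxes)


def to_section_coords(
    ann: Annotation, section: SectionImage, scale_factor: float = 1.0
):
    """Map a full-resolution click into a section crop's pixel frame.

    Returns ``(x, y)`` in section coordinates when the click falls inside
    the crop, the sentinel :data:`OUTSIDE` otherwise. ``scale_factor`` is
    the slide's working resolution relative to full resolution.
    """
    if ann.slide_id != section.slide_id:
        raise ValidationError(
            f"annotation slide {ann.slide_id!r} != section slide {section.slide_id!r}"
        )
    x = int(round(ann.x * scale_factor)) - section.offset_x
    y = int(round(ann.y * scale_factor)) - section.offset_y
    if 0 <= x < section.width and 0 <= y < section.height:
        return (x, y)
    return OUTSIDE


def check_annotation_coverage(
    annotations: Iterable[Annotation],
    sections: Sequence[SectionImage],
    scale_factor: float = 1.0,
) -> list[Annotation]:
    """Return annotations that fall in no section crop, logging a warning.

    Section isolation must never crop out a real follicle; any orphan
    annotation indicates the contour step lost tissue.
    """
    orphans = []
    for ann in annotations:
        hit = any(
            ann.slide_id == sec.slide_id
            and to_section_coords(ann, sec, scale_factor) is not OUTSIDE
            for sec in sections
        )
        if not hit:
            orphans.append(ann)
    if orphans:
        logger.warning(
            "%d annotation(s) fall outside every section crop: %s",
            len(orphans),
            [(a.slide_id, a.x, a.y) for a in orphans],
        )
    return orphans
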