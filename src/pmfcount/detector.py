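"""Sliding-window follicle detection with non-maximum suppression.

A square window the size of the training frame scans each section with
half-overlapping strides (so no follicle is missed at a window edge), each
window is scored by the patch classifier, scores are thresholded, and
greedy non-maximum suppression keeps only the highest-probability frame
among mutually adjacent positives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cnn_classifier import ClassifierModel, predict_proba
from .errors import ConfigurationError, ValidationError
from .preprocessing import SectionImage

DEFAULT_THRESHOLD = 0.15


@dataclass(frozen=True)
class Frame:
    """A square window, half-open [x, x+size) x [y, y+size), section frame."""

    x: int
    y: int
    size: int

    def contains(self, px: float, py: float) -> bool:
        return self.x <= px < self.x + self.size and self.y <= py < self.y + self.size

    def overlaps(self, other: "Frame") -> bool:
        return (
            self.x < other.x + other.size
            and other.x < self.x + self.size
            and self.y < other.y + other.size
            and other.y < self.y + self.size
        )

    def iou(self, other: "Frame") -> float:
        ix = max(0, min(self.x + self.size, other.x + other.size) - max(self.x, other.x))
        iy = max(0, min(self.y + self.size, other.y + other.size) - max(self.y, other.y))
        inter = ix * iy
        union = self.size ** 2 + other.size ** 2 - inter
        return inter / union if union else 0.0


@dataclass(frozen=True)
class Detection:
    """A window frame with its predicted follicle probability."""

    frame: Frame
    probability: float


@dataclass
class DetectionParams:
    """Sliding-window and suppression parameters.

    ``adjacency_rule`` is ``"any_overlap"`` (frames sharing at least one
    pixel are adjacent) or ``("iou_above", t)``.
    """

    window: int = 48
    overlap_fraction: float = 0.5
    threshold: float = DEFAULT_THRESHOLD
    adjacency_rule: object = "any_overlap"
    chunk_size: int = 256

    def __post_init__(self):
        if not (0 < self.overlap_fraction < 1):
            raise ConfigurationError("overlap_fraction must be in (0, 1)")
        if not (0 <= self.threshold <= 1):
            raise ConfigurationError("threshold must be in [0, 1]")
        if self.stride < 1:
            raise ConfigurationError("stride rounds to zero; window too small")

    @property
    def stride(self) -> int:
        return max(0, round(self.window * (1 - self.overlap_fraction)))


@dataclass
class DetectionRun:
    """Output of :func:`detect`: retained detections plus window bookkeeping."""

    detections: list[Detection]
    total_windows: int
    above_threshold: int = 0


def _starts(extent: int, window: int, stride: int) -> list[int]:
    starts = list(range(0, extent - window + 1, stride))
    if starts[-1] != extent - window:
        starts.append(extent - window)
    return starts


def enumerate_windows(width: int, height: int, params: DetectionParams) -> list[Frame]:
    """Row-major grid of half-overlapping windows covering every pixel.

    A final row/column is added flush with the right/bottom edge when the
    stride grid does not reach it.
    """
    if params.window > min(width, height):
        raise ValidationError(
            f"window {params.window} exceeds image {width}x{height}"
        )
    xs = _starts(width, params.window, params.stride)
    ys = _starts(height, params.window, params.stride)
    return [Frame(x, y, params.window) for y in ys for x in xs]


def score_windows(
    model: ClassifierModel, section: SectionImage, frames: Sequence[Frame],
    chunk_size: int = 256,
) -> list[Detection]:
    """One Detection per frame, order preserved; probabilities from the model."""
    if not frames:
        return []
    pixels = section.pixels
    h, w = pixels.shape
    crops = []
    for f in frames:
        if f.x < 0 or f.y < 0 or f.x + f.size > w or f.y + f.size > h:
            raise ValidationError(f"frame {f} outside section {w}x{h}")
        crops.append(pixels[f.y : f.y + f.size, f.x : f.x + f.size])
    probs = predict_proba(model, np.stack(crops), chunk_size=chunk_size)
    return [Detection(f, float(p)) for f, p in zip(frames, probs)]


def apply_threshold(detections: Sequence[Detection], threshold: float) -> list[Detection]:
    """Keep detections with probability >= threshold, order preserved."""
    return [d for d in detections if d.probability >= threshold]


def _adjacent(a: Detection, b: Detection, rule) -> bool:
    if rule == "any_overlap":
        return a.frame.overlaps(b.frame)
    if isinstance(rule, tuple) and rule[0] == "iou_above":
        return a.frame.iou(b.frame) >= rule[1]
    raise ConfigurationError(f"unknown adjacency rule {rule!r}")


def non_max_suppression(
    detections: Sequence[Detection], adjacency_rule="any_overlap"
) -> list[Detection]:
    """Greedy suppression: keep the best frame of each adjacent cluster.

    Repeatedly selects the highest-probability remaining detection (ties
    broken by (y, x) of the frame), emits it, and discards every remaining
    detection adjacent to it. The result is sorted by descending
    probability.
    """
    remaining = sorted(
        detections, key=lambda d: (-d.probability, d.frame.y, d.frame.x)
    )
    kept: list[Detection] = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        remaining = [d for d in remaining if not _adjacent(best, d, adjacency_rule)]
    return kept


def detect(
    model: ClassifierModel, section: SectionImage, params: DetectionParams
) -> DetectionRun:
    """Enumerate -> score -> threshold -> NMS over one section.

    ``total_windows`` records the raw window count for the evaluation
    bookkeeping (the denominator of the true-negative accounting).
    """
    frames = enumerate_windows(section.width, section.height, params)
    scored = score_windows(model, section, frames, chunk_size=params.chunk_size)
    positive = apply_threshold(scored, params.threshold)
    kept = non_max_suppression(positive, params.adjacency_rule)
    return DetectionRun(
        detections=kept, total_windows=len(frames), above_threshold=len(positive)
    )
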