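"""Patch dataset construction for the binary follicle classifier.

Positives are fixed-size square frames centered on primordial-follicle
clicks; negatives are frames sampled away from every annotated follicle of
any class. Positives are augmented with the dihedral group of the square
plus small random translations; the final training set is balanced to a
configured negative:positive ratio and split by ovary, never by patch, so
no tissue leaks between train and test.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from PIL import Image

from .errors import SamplingError, ValidationError
from .imaging_io import Annotation
from .preprocessing import OUTSIDE, SectionImage, to_section_coords

LABEL_FOLLICLE = "follicle"
LABEL_BACKGROUND = "background"

DEFAULT_FRAME_SIZE = 48
DEFAULT_NEG_POS_RATIO = 1.0

#: The 7 non-identity symmetries of the square, as augment_patch ops.
DIHEDRAL_OPS = (
    "rot90",
    "rot180",
    "rot270",
    "flip_h",
    "flip_v",
    "rot90+flip_h",
    "rot90+flip_v",
)


@dataclass
class LabeledPatch:
    """A fixed-size square grayscale frame with a binary follicle label.

    ``source`` records provenance as ``(slide_id, section_id, x, y)`` where
    (x, y) is the patch center in section coordinates.
    """

    pixels: np.ndarray
    label: str
    source: tuple
    augmentation_tag: str = ""

    def __post_init__(self):
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValidationError(f"patch must be square, got {self.pixels.shape}")
        if self.label not in (LABEL_FOLLICLE, LABEL_BACKGROUND):
            raise ValidationError(f"unknown patch label {self.label!r}")

    @property
    def frame_size(self) -> int:
        return self.pixels.shape[0]


@dataclass
class PatchDataset:
    """A set of labeled patches with its class counts and sampling seed."""

    patches: list[LabeledPatch]
    positives: int
    negatives: int
    seed: int = 0

    @classmethod
    def from_patches(cls, patches: Sequence[LabeledPatch], seed: int = 0):
        pos = sum(1 for p in patches if p.label == LABEL_FOLLICLE)
        return cls(list(patches), positives=pos, negatives=len(patches) - pos, seed=seed)

    def __len__(self) -> int:
        return len(self.patches)


def _pad_value(section: SectionImage) -> float:
    # border patches are padded with the bright-background median intensity
    return float(np.median(section.pixels))


def _crop_padded(section: SectionImage, x0: int, y0: int, size: int) -> np.ndarray:
    """Crop a half-open [x0,x0+size)x[y0,y0+size) window, padding out-of-bounds."""
    h, w = section.pixels.shape
    out = np.full((size, size), _pad_value(section), dtype=section.pixels.dtype)
    sx0, sy0 = max(0, x0), max(0, y0)
    sx1, sy1 = min(w, x0 + size), min(h, y0 + size)
    if sx0 < sx1 and sy0 < sy1:
        out[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = section.pixels[sy0:sy1, sx0:sx1]
    return out


def extract_positive_patches(
    section: SectionImage,
    annotations: Iterable[Annotation],
    frame_size: int = DEFAULT_FRAME_SIZE,
    classes: frozenset | set = frozenset({"primordial"}),
    scale_factor: float = 1.0,
) -> list[LabeledPatch]:
    """One follicle-labeled patch per in-section annotation of a selected class.

    Patches are centered on the click (top-left = click − frame_size/2);
    border patches are padded with the section's median intensity so every
    frame has the configured size.
    """
    if frame_size % 2 != 0:
        raise ValidationError("frame_size must be even")
    if frame_size > min(section.width, section.height):
        raise ValidationError(
            f"frame_size {frame_size} exceeds section {section.width}x{section.height}"
        )
    half = frame_size // 2
    patches = []
    for ann in annotations:
        if ann.follicle_class not in classes or ann.slide_id != section.slide_id:
            continue
        pt = to_section_coords(ann, section, scale_factor)
        if pt is OUTSIDE:
            continue
        x, y = pt
        patches.append(
            LabeledPatch(
                pixels=_crop_padded(section, x - half, y - half, frame_size),
                label=LABEL_FOLLICLE,
                source=(section.slide_id, section.section_id, x, y),
            )
        )
    return patches


def sample_negative_patches(
    section: SectionImage,
    annotations: Sequence,
    frame_size: int = DEFAULT_FRAME_SIZE,
    n: int = 0,
    min_dist: float | None = None,
    seed: int = 0,
    max_tries: int | None = None,
    scale_factor: float = 1.0,
) -> list[LabeledPatch]:
    """Sample ``n`` background patches whose centers keep clear of follicles.

    Centers are drawn uniformly (seeded) among positions where the frame
    fits inside the section, rejecting any closer than ``min_dist``
    (default: one frame size) to an annotation of *any* follicle class.
    Raises :class:`SamplingError` reporting the achieved count when the
    feasible region is exhausted.
    """
    if n < 0:
        raise ValidationError("n must be non-negative")
    if n == 0:
        return []
    if min_dist is None:
        min_dist = float(frame_size)
    half = frame_size // 2
    lo_x, hi_x = half, section.width - (frame_size - half)
    lo_y, hi_y = half, section.height - (frame_size - half)
    if hi_x < lo_x or hi_y < lo_y:
        raise SamplingError(
            f"section {section.width}x{section.height} too small for frame {frame_size}",
            achieved=0,
        )

    points = []
    for ann in annotations:
        if isinstance(ann, Annotation):
            pt = to_section_coords(ann, section, scale_factor)
            if pt is not OUTSIDE:
                points.append(pt)
        else:
            points.append(tuple(ann))
    pts = np.asarray(points, dtype=float) if points else np.empty((0, 2))

    rng = np.random.default_rng(seed)
    if max_tries is None:
        max_tries = 1000 * n
    patches: list[LabeledPatch] = []
    tries = 0
    while len(patches) < n and tries < max_tries:
        tries += 1
        x = int(rng.integers(lo_x, hi_x + 1))
        y = int(rng.integers(lo_y, hi_y + 1))
        if len(pts) and np.min(np.hypot(pts[:, 0] - x, pts[:, 1] - y)) < min_dist:
            continue
        patches.append(
            LabeledPatch(
                pixels=_crop_padded(section, x - half, y - half, frame_size),
                label=LABEL_BACKGROUND,
                source=(section.slide_id, section.section_id, x, y),
            )
        )
    if len(patches) < n:
        raise SamplingError(
            f"could only place {len(patches)}/{n} negative patches in "
            f"{max_tries} tries",
            achieved=len(patches),
        )
    return patches


def _apply_dihedral(pixels: np.ndarray, op: str) -> np.ndarray:
    if op == "rot90":
        return np.rot90(pixels, 1)
    if op == "rot180":
        return np.rot90(pixels, 2)
    if op == "rot270":
        return np.rot90(pixels, 3)
    if op == "flip_h":
        return np.fliplr(pixels)
    if op == "flip_v":
        return np.flipud(pixels)
    if "+" in op:
        first, second = op.split("+", 1)
        return _apply_dihedral(_apply_dihedral(pixels, first), second)
    raise ValidationError(f"unknown augmentation op {op!r}")


def augment_patch(
    patch: LabeledPatch,
    op,
    section: SectionImage | None = None,
    max_shift: int | None = None,
) -> LabeledPatch:
    """Apply one geometric augmentation, preserving label and frame size.

    ``op`` is a dihedral op name (``rot90``, ``rot180``, ``rot270``,
    ``flip_h``, ``flip_v``, or a ``+``-composition) or a tuple
    ``("translate", dx, dy)``. Translation re-crops from the parent section
    when one is supplied, otherwise shifts and pads with the patch median.
    """
    size = patch.frame_size
    if isinstance(op, tuple) and op[0] == "translate":
        _, dx, dy = op
        limit = max_shift if max_shift is not None else max(1, size // 10)
        if abs(dx) > limit or abs(dy) > limit:
            raise ValidationError(
                f"translation ({dx},{dy}) exceeds max shift {limit}"
            )
        half = size // 2
        sx, sy = patch.source[2], patch.source[3]
        if section is not None:
            pixels = _crop_padded(section, sx + dx - half, sy + dy - half, size)
        else:
            pad = float(np.median(patch.pixels))
            pixels = np.full((size, size), pad, dtype=patch.pixels.dtype)
            src = patch.pixels[
                max(0, dy) : size + min(0, dy), max(0, dx) : size + min(0, dx)
            ]
            pixels[max(0, -dy) : max(0, -dy) + src.shape[0],
                   max(0, -dx) : max(0, -dx) + src.shape[1]] = src
        tag = f"translate({dx},{dy})"
    else:
        pixels = _apply_dihedral(patch.pixels, op)
        tag = str(op)
    prev = patch.augmentation_tag
    return replace(
        patch,
        pixels=np.ascontiguousarray(pixels),
        augmentation_tag=f"{prev}+{tag}" if prev else tag,
    )


def augment_positives(
    patches: Sequence[LabeledPatch],
    sections: Mapping[tuple, SectionImage] | None = None,
    seed: int = 0,
    n_translations: int = 2,
    max_shift_frac: float = 0.1,
) -> list[LabeledPatch]:
    """Expand each positive into original + 7 dihedral variants + seeded shifts.

    ``sections`` maps ``(slide_id, section_id)`` to the parent section so
    translated patches re-crop real tissue instead of padding.
    """
    rng = np.random.default_rng(seed)
    out: list[LabeledPatch] = []
    for patch in patches:
        out.append(patch)
        for op in DIHEDRAL_OPS:
            out.append(augment_patch(patch, op))
        limit = max(1, int(patch.frame_size * max_shift_frac))
        section = None
        if sections is not None:
            section = sections.get(tuple(patch.source[:2]))
        for _ in range(n_translations):
            dx = int(rng.integers(-limit, limit + 1))
            dy = int(rng.integers(-limit, limit + 1))
            out.append(augment_patch(patch, ("translate", dx, dy), section, limit))
    return out


def balance_and_split(
    positives: Sequence[LabeledPatch],
    negatives: Sequence[LabeledPatch],
    neg_pos_ratio: float = DEFAULT_NEG_POS_RATIO,
    holdout_ovary_ids: set | frozenset = frozenset(),
    seed: int = 0,
    ovary_of: Mapping[str, str] | None = None,
) -> tuple[PatchDataset, PatchDataset]:
    """Split patches by ovary and balance training negatives.

    ``ovary_of`` maps slide_id -> ovary id (identity when omitted). The test
    set holds every patch from the holdout ovaries; training negatives are
    subsampled (seeded, without replacement) to ``ceil(ratio * positives)``.
    """

    def ovary(patch: LabeledPatch) -> str:
        sid = patch.source[0]
        return ovary_of[sid] if ovary_of is not None else sid

    all_ovaries = {ovary(p) for p in list(positives) + list(negatives)}
    missing = set(holdout_ovary_ids) - all_ovaries
    if missing:
        raise ValidationError(f"holdout ovary ids not present in data: {sorted(missing)}")

    train_pos = [p for p in positives if ovary(p) not in holdout_ovary_ids]
    train_neg = [p for p in negatives if ovary(p) not in holdout_ovary_ids]
    test = [p for p in list(positives) + list(negatives) if ovary(p) in holdout_ovary_ids]

    if not train_pos:
        raise ValidationError("training set has no positive patches after holdout")

    n_neg = math.ceil(neg_pos_ratio * len(train_pos))
    rng = np.random.default_rng(seed)
    if n_neg < len(train_neg):
        idx = rng.choice(len(train_neg), size=n_neg, replace=False)
        train_neg = [train_neg[i] for i in sorted(idx)]

    train = PatchDataset.from_patches(train_pos + train_neg, seed=seed)
    test_ds = PatchDataset.from_patches(test, seed=seed)
    return train, test_ds


def save_dataset(dataset: PatchDataset, out_dir, split: str = "train") -> Path:
    """Serialize a dataset as PNG patches plus a CSV manifest; returns manifest path."""
    out_dir = Path(out_dir)
    (out_dir / "patches").mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    new = not manifest.exists()
    with open(manifest, "a", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        if new:
            writer.writerow(
                ["path", "label", "slide_id", "section_id", "x", "y",
                 "augmentation_tag", "split"]
            )
        for i, patch in enumerate(dataset.patches):
            name = f"{split}_{i:06d}.png"
            arr = patch.pixels
            if arr.dtype != np.uint8:
                arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
            Image.fromarray(arr).save(out_dir / "patches" / name)
            writer.writerow(
                [f"patches/{name}", patch.label, *patch.source,
                 patch.augmentation_tag, split]
            )
    return manifest


def load_dataset(out_dir, split: str | None = None) -> PatchDataset:
    """Load a dataset previously written by :func:`save_dataset`."""
    out_dir = Path(out_dir)
    patches = []
    with open(out_dir / "manifest.csv", newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            if split is not None and row["split"] != split:
                continue
            pixels = np.array(Image.open(out_dir / row["path"]))
            patches.append(
                LabeledPatch(
                    pixels=pixels,
                    label=row["label"],
                    source=(row["slide_id"], int(row["section_id"]),
                            int(row["x"]), int(row["y"])),
                    augmentation_tag=row["augmentation_tag"],
                )
            )
    return PatchDataset.from_patches(patches)
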