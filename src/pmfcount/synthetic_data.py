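"""Seeded synthetic slides with known ground truth.

Emulates a digitized ovary slide: a bright background carrying several
darker, textured elliptical tissue sections. Each section holds planted
"primordial follicle" objects — a pale oocyte disc with a single dark
nucleolus dot, surrounded by a ring of small elongated dark nuclei
(flattened granulosa cells) — plus distractor objects (solid dark blobs,
pale discs with only a partial granulosa ring, bare pale discs). No
distractor shows the complete template (full ring + interior dot), so the
planted ground truth is unambiguous. All randomness flows from one seed;
regeneration is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import GenerationError, ValidationError
from .imaging_io import Annotation, SlideImage, write_annotations, write_slide

# 8-bit appearance constants: contrast, not color, drives detectability.
BACKGROUND_INTENSITY = 230
STROMA_INTENSITY = 150
NUCLEI_INTENSITY = 60
OOCYTE_INTENSITY = 205


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic slide generator.

    Defaults are desk-scale: 1024x1024 slides with 4 sections, each holding
    5-15 follicles (diameters 18-30 px) and 10-30 distractors, trainable in
    minutes on one CPU. Real slides hold 7-8 sections; tests exercise that
    layout with a larger canvas.
    """

    slide_w: int = 1024
    slide_h: int = 1024
    n_sections: int = 4
    follicles_per_section: tuple[int, int] = (5, 15)
    follicle_diameter: tuple[int, int] = (18, 30)
    distractors_per_section: tuple[int, int] = (10, 30)
    noise_sd: float = 4.0
    seed: int = 0
    # semi-axis ranges of the section ellipses, px
    section_ax_a: tuple[int, int] = (180, 220)
    section_ax_b: tuple[int, int] = (130, 160)
    allow_pairs: bool = False
    pair_distance: int = 20
    microns_per_pixel: float = 1.0
    max_tries: int = 5000

    def __post_init__(self):
        for name in ("follicles_per_section", "follicle_diameter",
                     "distractors_per_section", "section_ax_a", "section_ax_b"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValidationError(f"empty or negative range for {name}: ({lo},{hi})")
        if self.n_sections < 0 or self.slide_w <= 0 or self.slide_h <= 0:
            raise ValidationError("invalid slide geometry")


def _disc(canvas, cx, cy, r, value):
    h, w = canvas.shape
    y0, y1 = max(0, int(cy - r)), min(h, int(cy + r + 1))
    x0, x1 = max(0, int(cx - r)), min(w, int(cx + r + 1))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    canvas[y0:y1, x0:x1][(xx - cx) ** 2 + (yy - cy) ** 2 <= r * r] = value


def _ellipse_mask(shape, cx, cy, a, b, theta=0.0):
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _small_ellipse(canvas, cx, cy, a, b, theta, value):
    rmax = int(np.ceil(max(a, b))) + 1
    h, w = canvas.shape
    y0, y1 = max(0, int(cy) - rmax), min(h, int(cy) + rmax + 1)
    x0, x1 = max(0, int(cx) - rmax), min(w, int(cx) + rmax + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    canvas[y0:y1, x0:x1][(u / a) ** 2 + (v / b) ** 2 <= 1.0] = value


def _draw_granulosa_ring(canvas, rng, cx, cy, radius, coverage=1.0):
    """Ring of small elongated dark nuclei around (cx, cy).

    ``coverage`` < 1 draws only an arc (used for partial-ring distractors).
    """
    n = max(6, int(2 * np.pi * radius / 7))
    phase = rng.uniform(0, 2 * np.pi)
    span = 2 * np.pi * coverage
    for i in range(int(np.ceil(n * coverage))):
        angle = phase + span * i / max(1, n * coverage)
        gx = cx + radius * np.cos(angle)
        gy = cy + radius * np.sin(angle)
        # tangential orientation: flattened cells hug the oocyte
        _small_ellipse(canvas, gx, gy, 3.4, 1.6, angle + np.pi / 2,
                       NUCLEI_INTENSITY + rng.integers(-10, 11))


def _draw_follicle(canvas, rng, cx, cy, diameter):
    r = diameter / 2.0
    _disc(canvas, cx, cy, r, OOCYTE_INTENSITY + rng.integers(-8, 9))
    _draw_granulosa_ring(canvas, rng, cx, cy, r + 2.5, coverage=1.0)
    # nucleolus: the single dark interior dot that licenses a count
    _disc(canvas, cx, cy, max(1.5, r / 6.0), NUCLEI_INTENSITY)


def _draw_distractor(canvas, rng, cx, cy, kind, diameter):
    r = diameter / 2.0
    if kind == "blob":
        _disc(canvas, cx, cy, max(3.0, r * 0.6), NUCLEI_INTENSITY + rng.integers(0, 25))
    elif kind == "partial_ring":
        # pale disc with an incomplete granulosa arc and no nucleolus
        _disc(canvas, cx, cy, r, OOCYTE_INTENSITY + rng.integers(-8, 9))
        _draw_granulosa_ring(canvas, rng, cx, cy, r + 2.5,
                             coverage=rng.uniform(0.3, 0.55))
    elif kind == "bare_disc":
        _disc(canvas, cx, cy, r, OOCYTE_INTENSITY + rng.integers(-8, 9))
    else:  # pragma: no cover - internal kinds only
        raise ValidationError(f"unknown distractor kind {kind!r}")


def _place_sections(spec: SyntheticSpec, rng) -> list[tuple]:
    """Place section ellipses on a jittered grid so they never overlap.

    Serial sections on a real slide sit in rows; a grid with per-cell
    jitter reproduces that while guaranteeing disjoint bounding boxes.
    """
    if spec.n_sections == 0:
        return []
    gap = 24
    cols = int(np.ceil(np.sqrt(spec.n_sections)))
    rows = int(np.ceil(spec.n_sections / cols))
    cell_w = spec.slide_w // cols
    cell_h = spec.slide_h // rows
    a_hi = min(spec.section_ax_a[1], cell_w // 2 - gap)
    b_hi = min(spec.section_ax_b[1], cell_h // 2 - gap)
    if a_hi < spec.section_ax_a[0] or b_hi < spec.section_ax_b[0]:
        raise GenerationError(
            f"{spec.n_sections} sections with semi-axes >= "
            f"({spec.section_ax_a[0]},{spec.section_ax_b[0]}) do not fit a "
            f"{spec.slide_w}x{spec.slide_h} slide"
        )
    placed = []
    for i in range(spec.n_sections):
        r, c = divmod(i, cols)
        a = int(rng.integers(spec.section_ax_a[0], a_hi + 1))
        b = int(rng.integers(spec.section_ax_b[0], b_hi + 1))
        slack_x = cell_w // 2 - gap - a
        slack_y = cell_h // 2 - gap - b
        cx = c * cell_w + cell_w // 2 + int(rng.integers(-slack_x, slack_x + 1)) \
            if slack_x > 0 else c * cell_w + cell_w // 2
        cy = r * cell_h + cell_h // 2 + int(rng.integers(-slack_y, slack_y + 1)) \
            if slack_y > 0 else r * cell_h + cell_h // 2
        placed.append((cx, cy, a, b))
    return placed


def _sample_point_in_ellipse(rng, cx, cy, a, b, shrink=0.82):
    while True:
        u = rng.uniform(-1, 1)
        v = rng.uniform(-1, 1)
        if u * u + v * v <= 1.0:
            return cx + u * a * shrink, cy + v * b * shrink


def generate_slide(spec: SyntheticSpec) -> tuple[SlideImage, list[Annotation]]:
    """Generate one synthetic slide and its ground-truth annotations.

    Planted follicles within a section keep centers at least 1.5x the
    maximum diameter apart (unless ``allow_pairs`` plants some closer pairs
    to exercise the two-follicles-in-one-frame evaluation rule); distractors
    keep at least one maximum diameter from every other object.
    """
    rng = np.random.default_rng(spec.seed)
    canvas = np.full((spec.slide_h, spec.slide_w), float(BACKGROUND_INTENSITY))

    sections = _place_sections(spec, rng)
    annotations: list[Annotation] = []
    slide_id = f"synthetic_{spec.seed}"
    max_diam = spec.follicle_diameter[1]
    min_sep_ff = 1.5 * max_diam
    min_sep_other = float(max_diam)

    for cx, cy, a, b in sections:
        mask = _ellipse_mask(canvas.shape, cx, cy, a, b)
        stroma = STROMA_INTENSITY + rng.normal(0.0, 8.0, size=canvas.shape)
        canvas[mask] = stroma[mask]
        # sparse faint stromal nuclei for texture
        n_tex = int(mask.sum() / 900)
        for _ in range(n_tex):
            tx, ty = _sample_point_in_ellipse(rng, cx, cy, a, b, shrink=0.98)
            _small_ellipse(canvas, tx, ty, 2.0, 1.2, rng.uniform(0, np.pi),
                           STROMA_INTENSITY - 35 + rng.integers(-10, 11))

        placed_pts: list[tuple[float, float, bool]] = []  # (x, y, is_follicle)

        def try_place(is_follicle: bool, min_self_sep: float) -> tuple | None:
            for _ in range(spec.max_tries):
                px, py = _sample_point_in_ellipse(rng, cx, cy, a, b)
                ok = True
                for qx, qy, qf in placed_pts:
                    d = np.hypot(px - qx, py - qy)
                    need = min_self_sep if (is_follicle and qf) else min_sep_other
                    if d < need:
                        ok = False
                        break
                if ok:
                    return px, py
            return None

        k = int(rng.integers(spec.follicles_per_section[0],
                             spec.follicles_per_section[1] + 1))
        for _ in range(k):
            pt = try_place(True, min_sep_ff)
            if pt is None:
                raise GenerationError(
                    f"could not place {k} follicles in section at ({cx},{cy})"
                )
            diameter = int(rng.integers(spec.follicle_diameter[0],
                                        spec.follicle_diameter[1] + 1))
            _draw_follicle(canvas, rng, pt[0], pt[1], diameter)
            placed_pts.append((pt[0], pt[1], True))
            annotations.append(
                Annotation(slide_id, int(round(pt[0])), int(round(pt[1])), "primordial")
            )

        if spec.allow_pairs and k >= 2:
            # plant close pairs: a second follicle near an existing one,
            # nearer than half a typical frame
            n_pairs = max(1, k // 4)
            for i in range(n_pairs):
                qx, qy, _ = placed_pts[i]
                angle = rng.uniform(0, 2 * np.pi)
                px = qx + spec.pair_distance * np.cos(angle)
                py = qy + spec.pair_distance * np.sin(angle)
                diameter = spec.follicle_diameter[0]
                _draw_follicle(canvas, rng, px, py, diameter)
                placed_pts.append((px, py, True))
                annotations.append(
                    Annotation(slide_id, int(round(px)), int(round(py)), "primordial")
                )

        d = int(rng.integers(spec.distractors_per_section[0],
                             spec.distractors_per_section[1] + 1))
        kinds = ("blob", "partial_ring", "bare_disc")
        for j in range(d):
            pt = try_place(False, min_sep_other)
            if pt is None:
                break  # section saturated; fewer distractors is harmless
            diameter = int(rng.integers(spec.follicle_diameter[0],
                                        spec.follicle_diameter[1] + 1))
            _draw_distractor(canvas, rng, pt[0], pt[1], kinds[j % 3], diameter)
            placed_pts.append((pt[0], pt[1], False))

    if spec.noise_sd > 0:
        canvas = canvas + rng.normal(0.0, spec.noise_sd, size=canvas.shape)
    pixels = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    slide = SlideImage(
        pixels=pixels,
        microns_per_pixel=spec.microns_per_pixel,
        slide_id=slide_id,
        scale_factor=1.0,
    )
    return slide, annotations


def derive_seed(master_seed: int, index: int) -> int:
    """Deterministic per-slide seed below 2**31."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def generate_corpus(spec: SyntheticSpec, n_slides: int, out_dir) -> dict:
    """Write ``n_slides`` TIFF slides, one annotations CSV and a JSON manifest.

    Per-slide seeds derive deterministically from the master seed, so the
    corpus regenerates byte-identically.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"master_seed": spec.seed, "slides": []}
    all_annotations = []
    for i in range(n_slides):
        slide_seed = derive_seed(spec.seed, i)
        sub = SyntheticSpec(**{**spec.__dict__, "seed": slide_seed})
        slide, anns = generate_slide(sub)
        slide.slide_id = f"slide{i:03d}"
        anns = [Annotation(slide.slide_id, a.x, a.y, a.follicle_class) for a in anns]
        fname = f"{slide.slide_id}.tiff"
        write_slide(out_dir / fname, slide, compression="lzw")
        all_annotations.extend(anns)
        manifest["slides"].append(
            {"slide_id": slide.slide_id, "file": fname, "seed": slide_seed,
             "n_follicles": len(anns)}
        )
    write_annotations(out_dir / "annotations.csv", all_annotations)
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
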