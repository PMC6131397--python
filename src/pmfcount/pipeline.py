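"""End-to-end orchestration: synthesize -> preprocess -> dataset -> train ->
mine/retrain -> detect -> evaluate.

The run manifest records the resolved configuration, every derived seed,
stage-by-stage counts and the evaluation metrics, so any single stage can be
re-executed from it. With fixed seeds two runs produce byte-identical
reports.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import cnn_classifier as cnn
from .config import resolve_config, stage_seed
from .dataset_builder import (
    PatchDataset,
    augment_positives,
    balance_and_split,
    extract_positive_patches,
    sample_negative_patches,
)
from .detector import DetectionParams, detect
from .errors import DataError, StageError
from .evaluation import (
    EvalReport,
    MatchResult,
    apply_operator_correction,
    build_table1_report,
    match_detections,
    report_to_text,
    round_percent,
)
from .hard_negative_mining import mine_hard_negatives, retrain_with_hard_negatives
from .imaging_io import read_annotations, read_slide
from .preprocessing import (
    OUTSIDE,
    check_annotation_coverage,
    isolate_sections,
    to_section_coords,
)
from .synthetic_data import SyntheticSpec, derive_seed, generate_slide
from .imaging_io import Annotation

logger = logging.getLogger(__name__)


def _synthesize_role_slides(cfg: dict, master_seed: int):
    """Generate train/mine/test slides in memory with per-slide seeds."""
    s = cfg["synthesize"]
    roles = (
        ["train"] * s["n_train_slides"]
        + ["mine"] * s["n_mine_slides"]
        + ["test"] * s["n_test_slides"]
    )
    synth_seed = stage_seed(master_seed, "synthesize")
    slides = {"train": [], "mine": [], "test": []}
    for i, role in enumerate(roles):
        spec = SyntheticSpec(
            slide_w=s["slide_w"],
            slide_h=s["slide_h"],
            n_sections=s["n_sections"],
            follicles_per_section=tuple(s["follicles_per_section"]),
            follicle_diameter=tuple(s["follicle_diameter"]),
            distractors_per_section=tuple(s["distractors_per_section"]),
            noise_sd=s["noise_sd"],
            allow_pairs=s["allow_pairs"],
            section_ax_a=tuple(s["section_ax_a"]),
            section_ax_b=tuple(s["section_ax_b"]),
            seed=derive_seed(synth_seed, i),
        )
        slide, anns = generate_slide(spec)
        slide.slide_id = f"{role}{i:03d}"
        anns = [Annotation(slide.slide_id, a.x, a.y, a.follicle_class) for a in anns]
        slides[role].append((slide, anns))
    return slides


def _load_role_slides(cfg: dict):
    """Read train/mine/test slides and annotations from disk."""
    inp = cfg["input"]
    pre = cfg["preprocess"]
    slides_dir = Path(inp["slides_dir"] or ".")
    missing = []
    roles = {"train": inp["train_slides"], "mine": inp["mine_slides"],
             "test": inp["test_slides"]}
    for ids in roles.values():
        for sid in ids:
            if not (slides_dir / f"{sid}.tiff").exists():
                missing.append(str(slides_dir / f"{sid}.tiff"))
    ann_path = slides_dir / "annotations.csv"
    if not ann_path.exists():
        missing.append(str(ann_path))
    if missing:
        raise DataError(f"missing input files: {missing}")
    annotations = read_annotations(ann_path)
    slides = {"train": [], "mine": [], "test": []}
    for role, ids in roles.items():
        for sid in ids:
            slide = read_slide(
                slides_dir / f"{sid}.tiff",
                downsample_factor=pre["downsample_factor"],
                slide_id=sid,
            )
            anns = [a for a in annotations if a.slide_id == sid]
            slides[role].append((slide, anns))
    return slides


def _preprocess(slides: dict, cfg: dict):
    """Isolate sections for every slide; warn about orphan annotations."""
    pre = cfg["preprocess"]
    out = {}
    for role, pairs in slides.items():
        out[role] = []
        for slide, anns in pairs:
            sections = isolate_sections(
                slide,
                method=pre["binarize_method"],
                fixed_threshold=pre["fixed_threshold"],
                min_area=pre["min_area_frac"] * slide.width * slide.height,
                extra_downsample=pre["extra_downsample"],
            )
            check_annotation_coverage(anns, sections, slide.scale_factor)
            out[role].append((slide, sections, anns))
    return out


def _section_points(sections, anns, scale_factor=1.0):
    """Ground-truth primordial clicks per section, in section coordinates."""
    per_section = []
    for sec in sections:
        pts = []
        for ann in anns:
            if ann.follicle_class != "primordial":
                continue
            pt = to_section_coords(ann, sec, scale_factor)
            if pt is not OUTSIDE:
                pts.append(pt)
        per_section.append(pts)
    return per_section


def _build_training_set(preprocessed, cfg: dict, master_seed: int) -> PatchDataset:
    ds = cfg["dataset"]
    frame = ds["frame_size"]
    positives = []
    negatives = []
    sections_by_key = {}
    neg_index = 0
    for slide, sections, anns in preprocessed["train"]:
        for sec in sections:
            sections_by_key[(sec.slide_id, sec.section_id)] = sec
            pos = extract_positive_patches(
                sec, anns, frame_size=frame, scale_factor=slide.scale_factor
            )
            positives.extend(pos)
            n_neg = ds["negatives_per_positive"] * max(1, len(pos))
            negatives.extend(
                sample_negative_patches(
                    sec,
                    anns,
                    frame_size=frame,
                    n=n_neg,
                    min_dist=ds["min_dist"],
                    seed=stage_seed(master_seed, "negatives", neg_index),
                    scale_factor=slide.scale_factor,
                )
            )
            neg_index += 1
    if ds["augment"]:
        positives = augment_positives(
            positives,
            sections=sections_by_key,
            seed=stage_seed(master_seed, "augment"),
            n_translations=ds["n_translations"],
            max_shift_frac=ds["max_shift_frac"],
        )
    train_ds, _ = balance_and_split(
        positives,
        negatives,
        neg_pos_ratio=ds["neg_pos_ratio"],
        holdout_ovary_ids=frozenset(),
        seed=stage_seed(master_seed, "balance"),
    )
    return train_ds


def _evaluate_phase(model, preprocessed, cfg: dict, phase: str) -> EvalReport:
    params = DetectionParams(
        window=cfg["detection"]["window"],
        overlap_fraction=cfg["detection"]["overlap_fraction"],
        threshold=cfg["detection"]["threshold"],
        adjacency_rule=cfg["detection"]["adjacency_rule"],
        chunk_size=cfg["detection"]["chunk_size"],
    )
    total = MatchResult(0, 0, 0, 0, 0)
    n_real_total = 0
    for slide, sections, anns in preprocessed["test"]:
        n_real_total += sum(1 for a in anns if a.follicle_class == "primordial")
        per_section = _section_points(sections, anns, slide.scale_factor)
        n_in_sections = 0
        for sec, pts in zip(sections, per_section):
            run = detect(model, sec, params)
            total = total + match_detections(run.detections, pts, run.total_windows)
            n_in_sections += len(pts)
    # follicles cropped out by section isolation stay in the denominator
    total = MatchResult(
        tp_frames=total.tp_frames,
        fp_frames=total.fp_frames,
        found_follicles=total.found_follicles,
        real_follicles=n_real_total,
        total_windows=total.total_windows,
    )
    return EvalReport(phase=phase, match=total)


def run_pipeline(config: dict | None = None, out_dir=None) -> dict:
    """Execute the full pipeline; returns (and optionally writes) the manifest.

    Stages: synthesize (or load) -> preprocess -> build-dataset -> train ->
    [mine -> retrain] x rounds -> detect on the test slides -> evaluate.
    Any stage failure raises :class:`StageError` naming the stage.
    """
    cfg = resolve_config(config if isinstance(config, dict) else None) \
        if (config is None or isinstance(config, dict)) else config
    master_seed = cfg["seed"]
    manifest = {"config": cfg, "seeds": {"master": master_seed}, "stages": {}}

    def stage(name, fn, *args, **kwargs):
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(name, exc) from exc
        return result

    if cfg["synthesize"]["enabled"]:
        slides = stage("synthesize", _synthesize_role_slides, cfg, master_seed)
    else:
        slides = stage("preprocess", _load_role_slides, cfg)
    manifest["stages"]["slides"] = {
        role: [
            {"slide_id": s.slide_id, "n_annotations": len(a)} for s, a in pairs
        ]
        for role, pairs in slides.items()
    }

    preprocessed = stage("preprocess", _preprocess, slides, cfg)
    manifest["stages"]["sections"] = {
        role: [len(secs) for _, secs, _ in items]
        for role, items in preprocessed.items()
    }

    train_ds = stage("build-dataset", _build_training_set, preprocessed, cfg,
                     master_seed)
    manifest["stages"]["dataset"] = {
        "positives": train_ds.positives, "negatives": train_ds.negatives
    }
    logger.info("training set: %d positives, %d negatives",
                train_ds.positives, train_ds.negatives)

    arch = cnn.get_preset(cfg["model"]["preset"], input_size=cfg["dataset"]["frame_size"])
    train_cfg = cnn.TrainingConfig(
        batch_size=cfg["training"]["batch_size"],
        epochs=cfg["training"]["epochs"],
        rho=cfg["training"]["rho"],
        epsilon=cfg["training"]["epsilon"],
        seed=stage_seed(master_seed, "training"),
    )
    model = cnn.build_classifier(arch, seed=stage_seed(master_seed, "training", 1))
    model = stage("train", cnn.train, model, train_ds, train_cfg)
    manifest["stages"]["training"] = {
        "epochs": train_cfg.epochs,
        "final_loss": model.history["loss"][-1] if model.history["loss"] else None,
        "final_accuracy": model.history["accuracy"][-1]
        if model.history["accuracy"] else None,
    }

    params = DetectionParams(
        window=cfg["detection"]["window"],
        overlap_fraction=cfg["detection"]["overlap_fraction"],
        threshold=cfg["detection"]["threshold"],
        adjacency_rule=cfg["detection"]["adjacency_rule"],
        chunk_size=cfg["detection"]["chunk_size"],
    )

    reports = [stage("evaluate", _evaluate_phase, model, preprocessed, cfg,
                     "after_training")]

    for round_idx in range(cfg["hnm"]["rounds"]):
        mining_sections = []
        for slide, sections, anns in preprocessed["mine"]:
            per_section = _section_points(sections, anns, slide.scale_factor)
            mining_sections.extend(zip(sections, per_section))
        mined = stage("mine", mine_hard_negatives, model, mining_sections, params)
        manifest["stages"][f"hnm_round_{round_idx}"] = {
            "mined": len(mined.mined_patches)
        }
        retrain_cfg = cnn.TrainingConfig(
            batch_size=cfg["training"]["batch_size"],
            epochs=cfg["hnm"]["epochs"],
            rho=cfg["training"]["rho"],
            epsilon=cfg["training"]["epsilon"],
            seed=stage_seed(master_seed, "hnm", round_idx),
        )
        model = stage("retrain", retrain_with_hard_negatives, model, train_ds,
                      mined, retrain_cfg, cfg["dataset"]["neg_pos_ratio"])

    if cfg["hnm"]["rounds"] > 0:
        reports.append(stage("evaluate", _evaluate_phase, model, preprocessed, cfg,
                             "after_hnm"))

    m = cfg["evaluation"]["operator_confirmed"]
    if m:
        reports.append(stage("evaluate", apply_operator_correction, reports[-1], m))

    table = build_table1_report(reports)
    metrics = {}
    for report in reports:
        metrics[report.phase] = {
            "recall_pct": round_percent(report.recall),
            "precision_pct": round_percent(report.precision),
            "tp_frames": report.match.tp_frames,
            "fp_frames": report.match.fp_frames,
            "tn_windows": report.match.tn_windows,
            "total_windows": report.match.total_windows,
            "found_follicles": report.match.found_follicles,
            "real_follicles": report.match.real_follicles,
        }
    manifest["metrics"] = metrics
    manifest["report_text"] = report_to_text(table)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "report.csv")
        (out_dir / "report.txt").write_text(manifest["report_text"] + "\n",
                                            encoding="utf-8")
        with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        manifest["artifacts"] = {
            "report_csv": str(out_dir / "report.csv"),
            "report_txt": str(out_dir / "report.txt"),
            "manifest": str(out_dir / "manifest.json"),
        }
    return manifest
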