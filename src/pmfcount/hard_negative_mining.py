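"""Hard-negative mining: retrain on the detector's own false positives.

After a first round of training, the detector is run on a dedicated mining
slide set (disjoint from both the training and the test ovaries). Every
retained detection whose frame contains no ground-truth follicle click is a
false positive; those frames are forced into the training set as negative
examples, the negatives are rebalanced to the configured ratio, and
training continues from the existing weights. This sharpens precision at a
modest cost in recall.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cnn_classifier import ClassifierModel, TrainingConfig, train
from .dataset_builder import (
    LABEL_BACKGROUND,
    LABEL_FOLLICLE,
    LabeledPatch,
    PatchDataset,
)
from .detector import DetectionParams, detect
from .errors import ValidationError
from .preprocessing import SectionImage

logger = logging.getLogger(__name__)


@dataclass
class MiningResult:
    """False-positive frames collected from the mining set."""

    mined_patches: list[LabeledPatch] = field(default_factory=list)
    source_counts: dict = field(default_factory=dict)
    rounds: int = 1


def mine_hard_negatives(
    model: ClassifierModel,
    mining_sections: Sequence[tuple[SectionImage, Sequence[tuple]]],
    params: DetectionParams,
) -> MiningResult:
    """Collect every retained detection frame containing no follicle click.

    ``mining_sections`` pairs each section with its ground-truth points in
    section coordinates. Mined frames become background-labeled patches
    tagged ``hnm``.
    """
    if not mining_sections:
        raise ValidationError("mining set is empty")
    result = MiningResult()
    for section, points in mining_sections:
        run = detect(model, section, params)
        n_fp = 0
        for det in run.detections:
            if any(det.frame.contains(px, py) for px, py in points):
                continue
            f = det.frame
            patch = LabeledPatch(
                pixels=np.ascontiguousarray(
                    section.pixels[f.y : f.y + f.size, f.x : f.x + f.size]
                ),
                label=LABEL_BACKGROUND,
                source=(section.slide_id, section.section_id,
                        f.x + f.size // 2, f.y + f.size // 2),
                augmentation_tag="hnm",
            )
            result.mined_patches.append(patch)
            n_fp += 1
        key = (section.slide_id, section.section_id)
        result.source_counts[key] = n_fp
    logger.info("mined %d hard negatives from %d sections",
                len(result.mined_patches), len(mining_sections))
    return result


def compose_retraining_set(
    base_data: PatchDataset,
    mined: MiningResult,
    neg_pos_ratio: float = 1.0,
    seed: int = 0,
) -> PatchDataset:
    """Rebalanced training set with the mined negatives forced in.

    Keeps all positives and all mined negatives; original negatives fill
    the remaining budget ``ceil(ratio * positives)`` by a seeded subsample.
    When the mined negatives alone exceed the budget they are all kept and
    the original negatives are dropped (with a warning).
    """
    positives = [p for p in base_data.patches if p.label == LABEL_FOLLICLE]
    originals = [p for p in base_data.patches if p.label == LABEL_BACKGROUND]
    if not positives:
        raise ValidationError("base dataset has no positive patches")

    budget = math.ceil(neg_pos_ratio * len(positives))
    mined_patches = list(mined.mined_patches)
    remainder = budget - len(mined_patches)
    if remainder < 0:
        logger.warning(
            "mined negatives (%d) exceed the negative budget (%d); "
            "keeping all mined, dropping all original negatives",
            len(mined_patches), budget,
        )
        keep_originals: list[LabeledPatch] = []
    elif remainder < len(originals):
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(originals), size=remainder, replace=False)
        keep_originals = [originals[i] for i in sorted(idx)]
    else:
        keep_originals = originals

    return PatchDataset.from_patches(
        positives + mined_patches + keep_originals, seed=seed
    )


def retrain_with_hard_negatives(
    model: ClassifierModel,
    base_data: PatchDataset,
    mined: MiningResult,
    cfg: TrainingConfig,
    neg_pos_ratio: float = 1.0,
) -> ClassifierModel:
    """Continue training from the current weights on the rebalanced set."""
    data = compose_retraining_set(base_data, mined, neg_pos_ratio, seed=cfg.seed)
    return train(model, data, cfg)
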