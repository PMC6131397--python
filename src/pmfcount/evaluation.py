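"""Detection scoring: recall, precision and true-negative accounting.

A retained detection frame is a true positive (TP) when it contains at
least one ground-truth follicle click, a false positive (FP) otherwise.
Recall counts follicles, not frames: a frame holding two follicles counts
as two found follicles but one TP frame, and a follicle covered by several
TP frames counts once. True negatives are the scanned windows that were
neither TP nor FP. The operator-focus correction moves expert-confirmed
false positives into the true-positive tally and enlarges the ground truth
accordingly.

Percentages are rounded half-away-from-zero to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import pandas as pd

from .errors import UndefinedMetricError, ValidationError

PHASES = ("after_training", "after_hnm", "after_operator_focus")


def round_percent(fraction: float, decimals: int = 2) -> float:
    """100*fraction rounded half-away-from-zero to ``decimals`` places."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(fraction * 100)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class MatchResult:
    """Frame- and follicle-level counts from matching detections to truth."""

    tp_frames: int
    fp_frames: int
    found_follicles: int
    real_follicles: int
    total_windows: int

    @property
    def tn_windows(self) -> int:
        return self.total_windows - self.tp_frames - self.fp_frames

    def __add__(self, other: "MatchResult") -> "MatchResult":
        return MatchResult(
            tp_frames=self.tp_frames + other.tp_frames,
            fp_frames=self.fp_frames + other.fp_frames,
            found_follicles=self.found_follicles + other.found_follicles,
            real_follicles=self.real_follicles + other.real_follicles,
            total_windows=self.total_windows + other.total_windows,
        )


@dataclass
class EvalReport:
    """One column of the evaluation table, metrics recomputed from counts."""

    phase: str
    match: MatchResult
    confirmed_missed: int = 0

    def __post_init__(self):
        if self.phase not in PHASES:
            raise ValidationError(f"unknown phase {self.phase!r}")

    @property
    def recall(self) -> float:
        return compute_recall(self.match.found_follicles, self.match.real_follicles)

    @property
    def precision(self) -> float:
        return compute_precision(self.match.tp_frames, self.match.fp_frames)


def match_detections(
    detections: Sequence,
    ground_truth: Sequence[tuple],
    total_windows: int = 0,
) -> MatchResult:
    """Match retained detection frames to ground-truth points by containment.

    ``ground_truth`` is a sequence of (x, y) points in section coordinates.
    """
    tp = 0
    found = set()
    for det in detections:
        hits = [i for i, (px, py) in enumerate(ground_truth)
                if det.frame.contains(px, py)]
        if hits:
            tp += 1
            found.update(hits)
    return MatchResult(
        tp_frames=tp,
        fp_frames=len(detections) - tp,
        found_follicles=len(found),
        real_follicles=len(ground_truth),
        total_windows=total_windows,
    )


def compute_recall(found_follicles: int, real_follicles: int) -> float:
    """found/real as an exact fraction in [0, 1]."""
    if real_follicles <= 0:
        raise UndefinedMetricError("recall undefined: no real follicles")
    return found_follicles / real_follicles


def compute_precision(tp_frames: int, fp_frames: int) -> float:
    """tp/(tp+fp) as an exact fraction in [0, 1]."""
    if tp_frames + fp_frames <= 0:
        raise UndefinedMetricError("precision undefined: no positive frames")
    return tp_frames / (tp_frames + fp_frames)


def apply_operator_correction(report: EvalReport, confirmed_missed: int) -> EvalReport:
    """Reclassify expert-confirmed false positives as found follicles.

    Each confirmed frame becomes a TP and its follicle joins both the found
    and the real tallies, so recall becomes (found+m)/(real+m) and precision
    (tp+m)/(tp+fp).
    """
    if confirmed_missed < 0 or confirmed_missed > report.match.fp_frames:
        raise ValidationError(
            f"confirmed_missed {confirmed_missed} exceeds FP count "
            f"{report.match.fp_frames}"
        )
    m = report.match
    corrected = MatchResult(
        tp_frames=m.tp_frames + confirmed_missed,
        fp_frames=m.fp_frames - confirmed_missed,
        found_follicles=m.found_follicles + confirmed_missed,
        real_follicles=m.real_follicles + confirmed_missed,
        total_windows=m.total_windows,
    )
    return EvalReport(
        phase="after_operator_focus", match=corrected, confirmed_missed=confirmed_missed
    )


_PHASE_LABELS = {
    "after_training": "Phase I (after training)",
    "after_hnm": "Phase II (after training and HNM)",
    "after_operator_focus": "Phase III (after training, HNM and operator focus)",
}

_ROWS = (
    "Total number of images",
    "Number of false positive",
    "% of false positive",
    "Number of true negative",
    "% of true negative",
    "Precision (%)",
    "Recall (%)",
    "Number of detected follicles",
)


def build_table1_report(phases: Sequence[EvalReport]) -> pd.DataFrame:
    """Tabulate the evaluation phases, one column per phase.

    Percentages are recomputed from the counts of each phase; undefined
    metrics (zero denominators) appear as ``"undefined"``.
    """
    if not phases:
        raise ValidationError("need at least one phase")
    columns = {}
    for report in phases:
        m = report.match
        try:
            precision = f"{round_percent(report.precision):.2f}%"
        except UndefinedMetricError:
            precision = "undefined"
        try:
            recall = f"{round_percent(report.recall):.2f}%"
        except UndefinedMetricError:
            recall = "undefined"
        total = m.total_windows
        pct_fp = f"{round_percent(m.fp_frames / total):.2f}%" if total else "undefined"
        pct_tn = f"{round_percent(m.tn_windows / total):.2f}%" if total else "undefined"
        columns[_PHASE_LABELS[report.phase]] = [
            m.total_windows,
            m.fp_frames,
            pct_fp,
            m.tn_windows,
            pct_tn,
            precision,
            recall,
            m.found_follicles,
        ]
    return pd.DataFrame(columns, index=list(_ROWS))


def report_to_text(table: pd.DataFrame) -> str:
    """Aligned plain-text rendering of the evaluation table."""
    return table.to_string()
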