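import numpy as np
import pytest

from pmfcount.cnn_classifier import TrainingConfig, build_classifier, train
from pmfcount.detector import (
    Detection,
    DetectionParams,
    Frame,
    apply_threshold,
    detect,
    enumerate_windows,
    non_max_suppression,
    score_windows,
)
from pmfcount.errors import ValidationError
from pmfcount.preprocessing import SectionImage


class TestEnumerateWindows:
    def test_256_image_window_128_gives_nine_windows(self):
        frames = enumerate_windows(256, 256, DetectionParams(window=128))
        xs = sorted({f.x for f in frames})
        ys = sorted({f.y for f in frames})
        assert xs == [0, 64, 128]
        assert ys == [0, 64, 128]
        assert len(frames) == 9

    def test_exact_window_sized_image(self):
        frames = enumerate_windows(128, 128, DetectionParams(window=128))
        assert frames == [Frame(0, 0, 128)]

    def test_final_column_flush_with_edge(self):
        frames = enumerate_windows(300, 128, DetectionParams(window=128))
        xs = sorted({f.x for f in frames})
        assert xs == [0, 64, 128, 172]

    def test_window_larger_than_image(self):
        with pytest.raises(ValidationError):
            enumerate_windows(100, 100, DetectionParams(window=128))

    def test_full_coverage_and_interior_multiplicity(self):
        params = DetectionParams(window=48)
        w, h = 200, 150
        frames = enumerate_windows(w, h, params)
        counts = np.zeros((h, w), dtype=int)
        for f in frames:
            counts[f.y : f.y + f.size, f.x : f.x + f.size] += 1
        assert (counts >= 1).all()
        interior = counts[48:-48, 48:-48]
        assert (interior >= 4).all()


class TestScoreAndThreshold:
    def test_zero_frames(self, flat_section):
        model = build_classifier("tiny", seed=0)
        assert score_windows(model, flat_section, []) == []

    def test_detection_count_conserved(self, flat_section):
        model = build_classifier("tiny", seed=0)
        frames = enumerate_windows(flat_section.width, flat_section.height,
                                   DetectionParams(window=48))
        dets = score_windows(model, flat_section, frames)
        assert len(dets) == len(frames)
        assert [d.frame for d in dets] == frames

    def test_threshold_boundaries_and_monotonicity(self):
        dets = [Detection(Frame(i * 10, 0, 8), p)
                for i, p in enumerate([0.0, 0.2, 0.5, 0.9, 1.0])]
        assert apply_threshold(dets, 0.0) == dets
        assert [d.probability for d in apply_threshold(dets, 1.0)] == [1.0]
        kept = len(dets)
        for t in np.linspace(0, 1, 11):
            now = len(apply_threshold(dets, t))
            assert now <= kept
            kept = now


def _nms_oracle(detections, rule="any_overlap"):
    """Independent exhaustive-scan implementation of the greedy rule."""
    pool = list(detections)
    kept = []
    while pool:
        best = pool[0]
        for d in pool[1:]:
            better = d.probability > best.probability or (
                d.probability == best.probability
                and (d.frame.y, d.frame.x) < (best.frame.y, best.frame.x)
            )
            if better:
                best = d
        kept.append(best)
        survivors = []
        for d in pool:
            if d is best:
                continue
            a, b = best.frame, d.frame
            x_overlap = a.x < b.x + b.size and b.x < a.x + a.size
            y_overlap = a.y < b.y + b.size and b.y < a.y + a.size
            if not (x_overlap and y_overlap):
                survivors.append(d)
        pool = survivors
    return sorted(kept, key=lambda d: (-d.probability, d.frame.y, d.frame.x))


class TestNonMaxSuppression:
    def test_three_adjacent_frames_keep_middle(self):
        # half-overlapping run of three windows; middle has max probability
        dets = [
            Detection(Frame(0, 0, 64), 0.6),
            Detection(Frame(32, 0, 64), 0.9),
            Detection(Frame(64, 0, 64), 0.7),
        ]
        kept = non_max_suppression(dets)
        assert kept == [dets[1]]

    def test_single_detection_kept(self):
        d = Detection(Frame(5, 5, 32), 0.4)
        assert non_max_suppression([d]) == [d]

    def test_idempotence(self):
        rng = np.random.default_rng(0)
        dets = [
            Detection(Frame(int(rng.integers(0, 100)), int(rng.integers(0, 100)), 32),
                      float(rng.random()))
            for _ in range(20)
        ]
        once = non_max_suppression(dets)
        assert non_max_suppression(once) == once

    @pytest.mark.parametrize("trial", range(50))
    def test_matches_bruteforce_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(1, 13))
        dets = [
            Detection(
                Frame(int(rng.integers(0, 80)), int(rng.integers(0, 80)),
                      int(rng.choice([16, 32]))),
                round(float(rng.random()), 2),  # coarse probs force ties
            )
            for _ in range(n)
        ]
        assert non_max_suppression(dets) == _nms_oracle(dets)

    def test_output_is_independent_set_with_dominating_kept(self):
        rng = np.random.default_rng(9)
        dets = [
            Detection(Frame(int(rng.integers(0, 120)), int(rng.integers(0, 120)), 32),
                      float(rng.random()))
            for _ in range(30)
        ]
        kept = non_max_suppression(dets)
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                assert not a.frame.overlaps(b.frame)
        for d in dets:
            if d in kept:
                continue
            dominators = [k for k in kept
                          if k.frame.overlaps(d.frame) and k.probability >= d.probability]
            assert dominators

    def test_iou_rule(self):
        a = Detection(Frame(0, 0, 32), 0.9)
        b = Detection(Frame(30, 30, 32), 0.8)  # tiny corner overlap
        assert non_max_suppression([a, b], ("iou_above", 0.3)) == [a, b]
        assert non_max_suppression([a, b], "any_overlap") == [a]


@pytest.fixture(scope="module")
def toy_model(toy_patchset):
    model = build_classifier("tiny", seed=1)
    return train(model, toy_patchset, TrainingConfig(epochs=30, seed=0))


class TestDetect:
    def test_blank_section_yields_no_detections(self, toy_model):
        # toy positives are bright discs on dark; a pure dark section is blank
        section = SectionImage(np.full((150, 150), 10, np.uint8), 0, 0, 0, "blank")
        run = detect(toy_model, section, DetectionParams(window=48, threshold=0.5))
        assert run.detections == []

    def test_single_planted_object_detected_once(self, toy_model):
        pixels = np.full((150, 150), 10, np.uint8)
        yy, xx = np.mgrid[0:150, 0:150]
        pixels[(xx - 80) ** 2 + (yy - 70) ** 2 <= 100] = 230
        section = SectionImage(pixels, 0, 0, 0, "one")
        run = detect(toy_model, section, DetectionParams(window=48, threshold=0.15))
        assert len(run.detections) >= 1
        assert run.detections[0].frame.contains(80, 70)
        # NMS leaves no adjacent duplicates around the object
        containing = [d for d in run.detections if d.frame.contains(80, 70)]
        assert len(containing) == 1

    def test_window_count_matches_enumeration(self, toy_model, flat_section):
        params = DetectionParams(window=48)
        run = detect(toy_model, flat_section, params)
        frames = enumerate_windows(flat_section.width, flat_section.height, params)
        assert run.total_windows == len(frames)

    def test_chunking_does_not_change_detections(self, toy_model, small_slide):
        from pmfcount.preprocessing import isolate_sections

        slide, _ = small_slide
        section = isolate_sections(slide)[0]
        a = detect(toy_model, section, DetectionParams(window=48, chunk_size=7))
        b = detect(toy_model, section, DetectionParams(window=48, chunk_size=999))
        assert [d.frame for d in a.detections] == [d.frame for d in b.detections]
        assert np.allclose(
            [d.probability for d in a.detections],
            [d.probability for d in b.detections],
            rtol=0, atol=1e-12,
        )
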