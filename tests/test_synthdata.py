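"""Scene renderer, training-set generator, and detection-log simulator."""

import json

import numpy as np
import pytest

from cranioflow.labelspace import ENVIRONMENT, PHASES, TOOL_NAMES, Timeline, phase_tools
from cranioflow.synthdata import (
    GLYPHS,
    NoiseModel,
    SceneConfig,
    default_timeline,
    generate_surgery_video,
    generate_training_set,
    render_frame,
    simulate_detection_log,
    spread_counts,
)


class TestRenderFrame:
    def test_empty_scene_is_environment_only(self):
        image, vec = render_frame(set())
        assert image.shape == (64, 64, 3) and image.dtype == np.uint8
        assert vec.to_labels() == {ENVIRONMENT}

    def test_same_seed_is_bit_identical(self):
        a, _ = render_frame({"Motor"}, SceneConfig(seed=9), rng=42)
        b, _ = render_frame({"Motor"}, SceneConfig(seed=9), rng=42)
        np.testing.assert_array_equal(a, b)

    def test_label_vector_matches_requested_tools(self):
        _, vec = render_frame({"Scalpel", "Motor"})
        assert vec.to_labels() == {"Scalpel", "Motor", ENVIRONMENT}

    def test_unknown_tool_rejected(self):
        with pytest.raises(ValueError, match="drill"):
            render_frame({"drill"})

    def test_environment_bit_optional(self):
        _, vec = render_frame({"Motor"}, SceneConfig(environment_always=False))
        assert vec.to_labels() == {"Motor"}

    def test_mean_chroma_classifier_separates_tools_from_background(self):
        """Learnability oracle: a per-tool chromaticity pixel count tells each
        tool's frames apart from background frames with >= 95% accuracy."""
        cfg = SceneConfig(seed=11)
        rng = np.random.default_rng(11)

        def chroma(img):
            f = img.astype(float) + 1e-9
            return f / f.sum(axis=2, keepdims=True)

        def score(img, target):
            return (np.linalg.norm(chroma(img) - target, axis=2) < 0.07).sum()

        background = [render_frame(set(), cfg, rng)[0] for _ in range(120)]
        for tool, glyph in GLYPHS.items():
            target = np.asarray(glyph["color"], float)
            target = target / target.sum()
            pos = np.array(
                [score(render_frame({tool}, cfg, rng)[0], target) for _ in range(60)]
            )
            neg = np.array([score(img, target) for img in background])
            accuracy = ((pos >= 15).sum() + (neg < 15).sum()) / (len(pos) + len(neg))
            assert accuracy >= 0.95, f"{tool}: {accuracy:.3f}"


class TestTrainingSet:
    def test_default_preset_has_thirteen_folders(self, tiny_training_dir):
        folders = sorted(p.name for p in tiny_training_dir.iterdir() if p.is_dir())
        assert len(folders) == 13
        assert "Environment" in folders
        assert "Environment.hands" in folders

    def test_frame_counts(self, tiny_training_dir):
        files = list(tiny_training_dir.glob("*/*.png"))
        assert len(files) == 26  # 13 folders x 2 frames

    def test_manifest_records_counts(self, tiny_training_dir):
        manifest = json.loads((tiny_training_dir / "manifest.json").read_text())
        assert manifest["seed"] == 5
        assert sum(f["count"] for f in manifest["folders"].values()) == 26

    def test_identical_seed_reproduces_tree_byte_for_byte(self, tmp_path):
        combos = [frozenset({"Motor", ENVIRONMENT})]
        a = generate_training_set(combos, 2, SceneConfig(seed=4), tmp_path / "a", seed=4)
        b = generate_training_set(combos, 2, SceneConfig(seed=4), tmp_path / "b", seed=4)
        for pa, pb in zip(sorted(a.glob("*/*.png")), sorted(b.glob("*/*.png"))):
            assert pa.read_bytes() == pb.read_bytes()

    def test_scaled_total_splits_near_evenly(self):
        counts = spread_counts(10_000, 13)
        assert sum(counts) == 10_000
        assert max(counts) - min(counts) <= 1

    def test_empty_combination_list_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            generate_training_set([], 1, out_dir=tmp_path)


class TestSurgeryVideo:
    def test_one_frame_per_phase(self):
        tl = Timeline([(p.id, i, i) for i, p in enumerate(PHASES)])
        frames, labels, truth = generate_surgery_video(tl, SceneConfig(seed=2))
        assert len(frames) == 11
        assert len({lv.bits for lv in labels}) == 11
        assert truth is tl

    def test_frame_labels_follow_covering_phase(self, short_timeline):
        tl = default_timeline(33)
        _, labels, _ = generate_surgery_video(tl, SceneConfig(seed=2))
        for t, lv in enumerate(labels):
            expected = phase_tools(tl.phase_at(t)) | {ENVIRONMENT}
            assert lv.to_labels() == expected

    def test_default_timeline_full_scale(self):
        tl = default_timeline()
        assert tl.n_frames == 4920
        assert tl.frame_rate == 15
        assert [s[0] for s in tl.segments] == [p.id for p in PHASES]


class TestSimulatedLog:
    def test_zero_noise_matches_ground_truth(self, short_timeline, clean_log):
        for rec in clean_log.records:
            expected = phase_tools(short_timeline.phase_at(rec.frame)) | {ENVIRONMENT}
            assert rec.detected == expected

    def test_full_flip_inverts_every_detection(self, short_timeline):
        log = simulate_detection_log(short_timeline, NoiseModel(flip_rate=1.0), seed=1)
        for rec in log.records:
            truth = phase_tools(short_timeline.phase_at(rec.frame)) | {ENVIRONMENT}
            assert rec.detected == set(TOOL_NAMES) - truth

    def test_probabilities_straddle_threshold(self, clean_log):
        rec = clean_log.records[0]
        assert set(rec.probabilities) <= {0.1, 0.9}
        assert rec.detected == {n for n, p in zip(TOOL_NAMES, rec.probabilities) if p == 0.9}

    def test_empirical_flip_frequency_matches_rate(self):
        tl = default_timeline(10_000)
        rate = 0.1
        log = simulate_detection_log(tl, NoiseModel(flip_rate=rate), seed=3)
        flips = np.zeros(len(TOOL_NAMES))
        for rec in log.records:
            truth = phase_tools(tl.phase_at(rec.frame)) | {ENVIRONMENT}
            for i, name in enumerate(TOOL_NAMES):
                flips[i] += (name in rec.detected) != (name in truth)
        freq = flips / len(log.records)
        assert np.all(np.abs(freq - rate) < 0.02)

    def test_dropout_empties_frames(self, short_timeline):
        log = simulate_detection_log(
            short_timeline, NoiseModel(dropout_rate=1.0), seed=1
        )
        assert all(rec.detected == frozenset() for rec in log.records)

    def test_same_seed_reproduces_log_exactly(self, short_timeline):
        noise = NoiseModel(flip_rate=0.1, jitter=5, dropout_rate=0.02)
        a = simulate_detection_log(short_timeline, noise, seed=9)
        b = simulate_detection_log(short_timeline, noise, seed=9)
        assert a.records == b.records

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            NoiseModel(flip_rate=1.5)
        with pytest.raises(ValueError):
            NoiseModel(jitter=-1)
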