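"""Spectral gates, decision-tree precedence, network training and the full
timeline composition."""

import numpy as np
import pytest

from skategears import (CoursePlan, CourseSegment, CycleRecord, PipelineConfig,
                        TEMPLATES, Thresholds, TrajectorySeries, add_noise,
                        classify_cycle, gate_tuck, generate_course,
                        generate_trial, stft_bands, train_nnc)
from skategears.classifier import (MERGE_MAP, NNCModel, classify_timeline)

FS = 50.0


def _vel(sig_side, sig_vert=None):
    n = len(sig_side)
    v = np.zeros((n, 3))
    v[:, 1] = sig_side
    if sig_vert is not None:
        v[:, 2] = sig_vert
    return v


class TestStftBands:
    def test_zero_velocity_gives_zero_bands(self):
        t = np.arange(400) / FS
        s = stft_bands(t, np.zeros((400, 3)), FS)
        assert np.allclose(s.band_side, 0.0)
        assert np.allclose(s.band_vert, 0.0)
        assert s.times.size == 400 - 256 + 1

    def test_band_sum_linear_in_amplitude(self):
        t = np.arange(600) / FS
        tone = np.sin(2 * np.pi * 0.75 * t)
        s1 = stft_bands(t, _vel(tone), FS)
        s2 = stft_bands(t, _vel(2 * tone), FS)
        assert np.allclose(s2.band_side, 2 * s1.band_side, rtol=1e-9)

    def test_out_of_band_tone_leaks_little(self):
        t = np.arange(600) / FS
        in_band = stft_bands(t, _vel(np.sin(2 * np.pi * 0.75 * t)), FS)
        out_band = stft_bands(t, _vel(np.sin(2 * np.pi * 2.0 * t)), FS)
        assert (np.median(out_band.band_side)
                < 0.05 * np.median(in_band.band_side))

    def test_matches_direct_framewise_fft(self):
        """Independent oracle: explicit per-frame Hanning window + rFFT."""
        rng = np.random.default_rng(0)
        t = np.arange(300) / FS
        x = rng.normal(size=300)
        s = stft_bands(t, _vel(x), FS)
        w = np.hanning(257)[:-1]  # periodic Hanning, 256 samples
        freqs = np.fft.rfftfreq(512, 1 / FS)
        bins = (freqs >= 0.5) & (freqs <= 1.0)
        ref = np.array([np.sum(np.abs(np.fft.rfft(w * x[i:i + 256], 512))[bins])
                        for i in range(300 - 256 + 1)])
        assert np.allclose(s.band_side, ref, atol=1e-9)

    def test_window_shorter_than_block_warns(self):
        t = np.arange(100) / FS
        with pytest.warns(UserWarning, match="shorter than"):
            assert stft_bands(t, np.zeros((100, 3)), FS) is None


class TestGateTuck:
    def test_zero_band_is_all_tuck(self):
        t = np.arange(400) / FS
        s = stft_bands(t, np.zeros((400, 3)), FS)
        iv = gate_tuck(s, Thresholds(), block_span=(t[0], t[-1]))
        assert iv == [(t[0], t[-1])]

    def test_band_equal_to_threshold_is_not_tuck(self):
        from skategears.classifier import SpectralSummary
        thr = Thresholds()
        s = SpectralSummary(times=np.arange(5.0),
                            band_side=np.full(5, thr.t_tuck),
                            band_vert=np.zeros(5))
        assert gate_tuck(s, thr) == []

    def test_tuck_segment_between_skating_segments(self):
        plan = CoursePlan(segments=[
            CourseSegment(25.0, "G3", 3.5),
            CourseSegment(15.0, "Tuck", 7.0),
            CourseSegment(25.0, "G3", 3.5)])
        traj, _ = generate_course(plan, seed=0)
        res = classify_timeline(add_noise(traj, 0.03, seed=1))
        assert len(res.tuck_intervals) == 1
        (a, b), half_window = res.tuck_intervals[0], 2.56
        assert 25.0 - half_window <= a <= 25.0 + half_window
        assert 40.0 - half_window <= b <= 40.0 + half_window


def _record(heading_rate=0.0, band_vert=500.0):
    return CycleRecord(t_start=0.0, t_end=1.4, duration=1.4, length=4.0,
                       heading_change=heading_rate * 1.4,
                       heading_rate=heading_rate, band_vert=band_vert)


class TestDecisionTree:
    def test_turn_rule_overrides_spectra(self, trained_model):
        rec = _record(heading_rate=20.0, band_vert=50.0)
        assert classify_cycle(rec, None, Thresholds(), trained_model) == "Turn"

    def test_g5_rule_below_vertical_threshold(self, trained_model):
        rec = _record(heading_rate=2.0, band_vert=50.0)
        assert classify_cycle(rec, None, Thresholds(), trained_model) == "G5"

    def test_precedence_turn_before_g5_before_nnc(self, small_corpus,
                                                  trained_model):
        feats, labels = small_corpus
        feat = feats[0]
        thr = Thresholds()
        # satisfies both Turn and G5 conditions: Turn wins
        assert classify_cycle(_record(20.0, 50.0), feat, thr,
                              trained_model) == "Turn"
        # satisfies only G5: G5 wins over the NNC
        assert classify_cycle(_record(2.0, 50.0), feat, thr,
                              trained_model) == "G5"
        # satisfies neither: NNC decides, merged
        lab = classify_cycle(_record(2.0, 500.0), feat, thr, trained_model)
        assert lab in {"G2", "G3", "G4"}

    def test_without_model_nnc_cycles_are_unclassified(self):
        assert classify_cycle(_record(2.0, 500.0), None,
                              Thresholds(), None) == "unclassified"

    def test_merge_map_is_surjective_onto_main_gears(self):
        assert set(MERGE_MAP.values()) == {"G2", "G3", "G4"}


class TestTrainNnc:
    def _toy(self, n=40, n_classes=2, seed=0):
        rng = np.random.default_rng(seed)
        centers = rng.normal(size=(n_classes, 26)) * 10
        X = np.vstack([c + rng.normal(0, 0.1, size=(n, 26))
                       for c in centers])
        y = np.repeat([f"C{i}" for i in range(n_classes)], n)
        return X, y

    def test_separable_toy_reaches_perfect_validation(self):
        X, y = self._toy()
        model = train_nnc(X, y, seed=0)
        assert model.metadata["validation_accuracy"] == 1.0
        assert model.metadata["train_accuracy"] == 1.0

    def test_same_data_and_seed_give_identical_weights(self):
        X, y = self._toy(n_classes=3)
        m1 = train_nnc(X, y, seed=5)
        m2 = train_nnc(X, y, seed=5)
        assert np.array_equal(m1.w1, m2.w1)
        assert np.array_equal(m1.w2, m2.w2)

    def test_class_with_single_example_rejected(self):
        X, y = self._toy()
        y = y.copy()
        y[0] = "rare"
        X, y = X[: 2 * 40], y[: 2 * 40]
        with pytest.raises(ValueError, match="fewer than 2"):
            train_nnc(X, y, seed=0)

    def test_softmax_outputs_sum_to_one(self, trained_model, small_corpus):
        feats, _ = small_corpus
        probs = trained_model.predict_proba(feats[:20])
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(probs >= 0)

    def test_json_round_trip_preserves_predictions(self, trained_model,
                                                   small_corpus, tmp_path):
        feats, _ = small_corpus
        path = tmp_path / "model.json"
        trained_model.to_json(path)
        loaded = NNCModel.from_json(path)
        assert np.array_equal(trained_model.predict(feats),
                              loaded.predict(feats))


class TestClassifyTimeline:
    def test_pure_g4_trial_is_all_g4(self, trained_model):
        traj, _ = generate_trial(TEMPLATES["G4L"], 60.0, 4.0, seed=3)
        res = classify_timeline(add_noise(traj, 0.03, seed=4), trained_model)
        labels = {r.label for r in res.records}
        assert labels == {"G4"}
        assert res.report["n_cycles"] >= 40

    def test_mirror_invariance_of_merged_labels(self, trained_model):
        out = {}
        for name in ("G4L", "G4R"):
            traj, _ = generate_trial(TEMPLATES[name], 40.0, 4.0, seed=3)
            res = classify_timeline(add_noise(traj, 0.03, seed=4),
                                    trained_model)
            out[name] = [r.label for r in res.records]
        assert set(out["G4L"]) == set(out["G4R"]) == {"G4"}

    def test_all_float_input_yields_empty_cycle_table(self):
        t = np.arange(2000) / FS
        pos = np.column_stack([np.zeros_like(t), 3.0 * t, np.zeros_like(t)])
        traj = TrajectorySeries(t, pos, np.zeros(t.size, dtype=bool))
        res = classify_timeline(traj)
        assert res.records == []
        assert res.report["fraction_excluded"] == 1.0
        assert res.excluded_intervals == [(0.0, pytest.approx(t[-1]))]

    def test_course_sequence_matches_plan_order(self, trained_model):
        plan = CoursePlan(segments=[
            CourseSegment(25.0, "G3", 3.5),
            CourseSegment(15.0, "Tuck", 7.0, incline=-5.0),
            CourseSegment(15.0, "Turn", 4.0, heading_rate=20.0),
            CourseSegment(25.0, "G3", 3.5)])
        traj, _ = generate_course(plan, seed=5)
        res = classify_timeline(add_noise(traj, 0.03, seed=6), trained_model)
        # collapse consecutive duplicates; ignore boundary-window cycles
        seq = []
        for r in res.records:
            if not seq or seq[-1] != r.label:
                seq.append(r.label)
        assert seq == ["G3", "Turn", "G3"]
        assert len(res.tuck_intervals) == 1

    def test_float_window_excludes_overlapping_cycles(self, trained_model):
        plan = CoursePlan(segments=[CourseSegment(60.0, "G3", 3.5)],
                          outage_windows=[(25.0, 30.0)])
        traj, _ = generate_course(plan, seed=7)
        res = classify_timeline(add_noise(traj, 0.03, seed=8), trained_model)
        for r in res.records:
            assert r.t_end <= 25.0 + 1e-6 or r.t_start >= 30.0 - 1e-6
        assert any(a <= 25.0 <= b or a <= 30.0 <= b
                   for a, b in res.excluded_intervals)

    def test_deterministic_given_inputs(self, trained_model):
        traj, _ = generate_trial(TEMPLATES["G3"], 40.0, 3.5, seed=9)
        noisy = add_noise(traj, 0.03, seed=10)
        r1 = classify_timeline(noisy, trained_model)
        r2 = classify_timeline(noisy, trained_model)
        assert r1.cycle_frame().equals(r2.cycle_frame())
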