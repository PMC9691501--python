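"""Winner-take-all extraction, matching, ROC scoring and clutter metrics."""

import numpy as np
import pytest

from bivision.evaluation import (ROCCurve, auroc, cycles_per_degree, match,
                                 mcpp, mfm, roc, winner_take_all)


class TestWinnerTakeAll:
    def test_single_spike(self):
        m = np.zeros((16, 16))
        m[5, 7] = 1.0
        dets = winner_take_all(m)
        assert dets.shape == (1, 3)
        assert tuple(dets[0, :2]) == (5, 7)

    def test_two_equal_spikes_in_one_kernel_keep_first(self):
        m = np.zeros((16, 16))
        m[5, 5] = m[5, 8] = 1.0
        dets = winner_take_all(m)
        assert len(dets) == 1
        assert tuple(dets[0, :2]) == (5, 5)

    def test_constant_map_yields_nothing(self):
        assert len(winner_take_all(np.full((12, 12), 3.0))) == 0

    def test_min_polarity_finds_minima_with_positive_scores(self):
        m = np.zeros((16, 16))
        m[4, 4] = -2.0
        dets = winner_take_all(m, polarity="min")
        assert tuple(dets[0, :2]) == (4, 4)
        assert dets[0, 2] == 2.0

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            winner_take_all(np.zeros((8, 8)), kernel=6)

    def test_separated_spikes_all_survive(self):
        m = np.zeros((24, 24))
        for pos in ((3, 3), (3, 18), (18, 3), (18, 18)):
            m[pos] = 1.0
        assert len(winner_take_all(m)) == 4


class TestMatch:
    def _d(self, row, col, score):
        return np.array([[row, col, score]])

    def test_trailing_edge_shift_gives_tp(self):
        truth = np.array([[10.0, 20.0]])
        out = match(self._d(10, 21, 1.0), truth, frame=0, shift_px=(0, 1))
        assert out[0].is_tp

    def test_outside_window_is_fp(self):
        truth = np.array([[10.0, 20.0]])
        out = match(self._d(10, 24, 1.0), truth, frame=0, shift_px=(0, 1))
        assert not out[0].is_tp

    def test_one_target_claims_one_detection(self):
        truth = np.array([[10.0, 20.0]])
        dets = np.array([[10, 21, 2.0], [11, 21, 1.0]])
        out = match(dets, truth, frame=0, shift_px=(0, 1))
        labels = sorted((d.score, d.is_tp) for d in out)
        assert labels == [(1.0, False), (2.0, True)]

    def test_greedy_assigns_highest_score_first(self):
        truth = np.array([[10.0, 20.0]])
        dets = np.array([[10, 21, 1.0], [10, 22, 5.0]])
        out = match(dets, truth, frame=0, shift_px=(0, 1))
        by_score = {d.score: d.is_tp for d in out}
        assert by_score[5.0] and not by_score[1.0]

    def test_horizontal_wrap(self):
        truth = np.array([[5.0, 0.0]])
        out = match(self._d(5, 63, 1.0), truth, frame=0, shift_px=(0, 0),
                    frame_width=64)
        assert out[0].is_tp


class TestROCAndAUROC:
    def test_perfect_detector(self):
        from bivision.evaluation import Detection
        labelled = [Detection(frame=0, row=0, col=i, score=1.0, is_tp=True)
                    for i in range(5)]
        curve = roc(labelled, n_frames=1, targets_per_frame=5)
        assert curve.tpr[-1] == 1.0 and curve.fp[-1] == 0.0
        assert auroc(curve) == pytest.approx(1.0)

    def test_no_detections_scores_zero(self):
        curve = roc([], n_frames=10, targets_per_frame=5)
        assert auroc(curve) == 0.0

    def test_linear_ramp_integrates_to_half(self):
        # TPR rising linearly from 0 to 1 over FP 0..20
        fp = np.linspace(0, 20, 21)
        curve = ROCCurve(thresholds=np.linspace(1, 0, 21),
                         tp=fp.copy(), fp=fp, tpr=fp / 20.0,
                         n_frames=1, targets_per_frame=1)
        assert auroc(curve, fp_max=20) == pytest.approx(0.5, abs=1e-12)

    def test_per_frame_averaging(self):
        from bivision.evaluation import Detection
        labelled = [Detection(frame=f, row=0, col=0, score=1.0, is_tp=False)
                    for f in range(4)]
        curve = roc(labelled, n_frames=4, targets_per_frame=5)
        assert curve.fp[-1] == pytest.approx(1.0)   # 4 FPs over 4 frames

    def test_adding_a_tp_never_decreases_auroc(self):
        from bivision.evaluation import Detection
        base = [Detection(frame=0, row=0, col=i, score=1.0 - 0.1 * i,
                          is_tp=(i % 2 == 0)) for i in range(8)]
        extra = base + [Detection(frame=0, row=5, col=5, score=0.05,
                                  is_tp=True)]
        c0 = roc(base, n_frames=1, targets_per_frame=10)
        c1 = roc(extra, n_frames=1, targets_per_frame=10)
        assert auroc(c1) >= auroc(c0)

    def test_invalid_fp_max_rejected(self):
        curve = roc([], n_frames=1, targets_per_frame=1)
        with pytest.raises(ValueError):
            auroc(curve, fp_max=0)


class TestClutterMetrics:
    def test_mcpp_constant_frame_is_zero(self):
        assert mcpp(np.full((16, 16), 5.0)) == pytest.approx(0.0, abs=1e-9)

    def test_mcpp_scale_invariant(self, rng):
        frame = rng.random((20, 20)) + 0.5
        assert mcpp(frame * 7.0) == pytest.approx(mcpp(frame), rel=1e-9)

    def test_mcpp_matches_bruteforce_on_checkerboard(self):
        frame = np.indices((12, 12)).sum(axis=0) % 2 * 1.0 + 0.5
        # brute force with the same wrap/replicate boundary handling
        h, w = frame.shape
        vals = np.empty_like(frame)
        for r in range(h):
            for c in range(w):
                rows = np.clip(np.arange(r - 1, r + 2), 0, h - 1)
                cols = np.arange(c - 1, c + 2) % w
                patch = frame[np.ix_(rows, cols)]
                vals[r, c] = patch.std() / patch.mean()
        assert mcpp(frame) == pytest.approx(vals.mean(), rel=1e-9)

    def test_mcpp_rejects_zero_frame(self):
        with pytest.raises(ValueError):
            mcpp(np.zeros((8, 8)))

    def test_band_edge_conversion(self):
        assert cycles_per_degree(2.0, 0.36) == pytest.approx(1.389, abs=1e-3)
        assert cycles_per_degree(2.7, 0.36) == pytest.approx(1.029, abs=0.02)

    def test_mfm_constant_frame_is_zero(self):
        assert mfm(np.full((32, 64), 4.0)) == pytest.approx(0.0, abs=1e-12)

    def test_mfm_band_selectivity(self):
        x = np.arange(64)
        in_band = np.tile(np.sin(2 * np.pi * x / 2.5), (32, 1))   # 2.5 px/cyc
        out_band = np.tile(np.sin(2 * np.pi * x / 16.0), (32, 1))
        assert mfm(in_band + 2) > mfm(out_band + 2)

    def test_mfm_cpd_band_requires_scale(self):
        with pytest.raises(ValueError):
            mfm(np.ones((16, 16)), band_cpd=(1.044, 1.389))
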