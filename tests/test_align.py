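"""Linear and piecewise alignment, warp algebra, smooth baseline."""

import itertools

import numpy as np
import pytest

from cequant.align import (AlignmentError, LinearTransform, WarpTransform,
                           align_all, align_between_batches,
                           align_within_batch, apply_alignment, fit_linear,
                           fit_piecewise, piecewise_scores, piecewise_windows,
                           subtract_smooth_baseline, warp_profile)
from cequant.preprocess import ConfigError


def gaussian(n, center, sigma=8.0, amp=1.0):
    x = np.arange(n, dtype=float)
    return amp * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def band_profile(n=4000, spacing=80, rng=None):
    rng = rng or np.random.default_rng(0)
    p = np.zeros(n)
    for c in range(300, n - 300, spacing):
        p += gaussian(n, c, 8.0, float(rng.gamma(2.0, 1.0)))
    return p


class TestWarpProfile:
    def test_identity_exact(self):
        p = band_profile()
        np.testing.assert_array_equal(warp_profile(p, LinearTransform()), p)

    def test_shift_inverse_composition(self):
        p = band_profile()
        fwd = warp_profile(p, LinearTransform(10.0, 1.0))
        back = warp_profile(fwd, LinearTransform(-10.0, 1.0))
        core = slice(50, -50)
        assert np.max(np.abs(back[core] - p[core])) < 1e-9

    def test_scale_relocates_peak(self):
        n = 4000
        p = gaussian(n, 700.0, 6.0)
        out = warp_profile(p, LinearTransform(shift=100.0, scale=2.0))
        assert abs(int(np.argmax(out)) - (2 * 700 + 100)) <= 1

    def test_non_monotone_anchors_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            WarpTransform(LinearTransform(), ((100.0, 100.0), (90.0, 200.0)))

    def test_warp_is_monotone(self):
        """Anchors strictly increase, so band ordering is preserved."""
        t = WarpTransform(LinearTransform(),
                          ((100.0, 110.0), (500.0, 490.0), (900.0, 905.0)))
        p = band_profile(1200, spacing=100)
        out = apply_alignment(p, t)
        peaks_in = np.sort([c for c in range(300, 900, 100)])
        peaks_out = []
        for c in peaks_in:
            w = out[c - 40:c + 40]
            peaks_out.append(c - 40 + int(np.argmax(w)))
        assert all(np.diff(peaks_out) > 0)


class TestLinearTransform:
    def test_compose_matches_sequential_warps(self):
        p = band_profile()
        t1 = LinearTransform(12.0, 1.01)
        t2 = LinearTransform(-7.0, 0.995)
        seq = warp_profile(warp_profile(p, t1), t2)
        comp = warp_profile(p, t1.compose(t2))
        core = slice(400, -400)
        assert np.max(np.abs(seq[core] - comp[core])) < 2e-2 * p.max()

    def test_invert_round_trip(self):
        t = LinearTransform(33.0, 1.004)
        ti = t.invert()
        tt = t.compose(ti)
        assert abs(tt.shift) < 1e-9 and abs(tt.scale - 1) < 1e-12


class TestFitLinear:
    def test_self_alignment_exact_identity(self):
        p = band_profile()
        t = fit_linear(p, p)
        assert t.shift == 0.0 and t.scale == 1.0 and t.score == 1.0

    def test_planted_shift_recovered(self):
        p = band_profile()
        p2 = warp_profile(p, LinearTransform(25.0, 1.0))
        t = fit_linear(p2, p)
        assert abs(t.shift - 25.0) <= 1.0
        assert abs(t.scale - 1.0) <= 0.001

    def test_planted_shift_and_scale_recovered(self):
        p = band_profile(6000, spacing=75)
        t_true = LinearTransform(-42.0, 1.013)
        p2 = warp_profile(p, t_true)
        t = fit_linear(p2, p)
        assert abs(t.shift - t_true.shift) <= 2.0
        assert abs(t.scale - t_true.scale) <= 5e-4

    def test_constant_reference_error(self):
        with pytest.raises(AlignmentError):
            fit_linear(band_profile(), np.full(4000, 3.0))

    def test_constant_profile_error(self):
        with pytest.raises(AlignmentError):
            fit_linear(np.zeros(4000), band_profile())


class TestBatchAlignment:
    def test_single_lane_batch_identity(self, small_traces):
        traces, _ = small_traces
        single = traces.copy()
        single.signal = single.signal[:, :1]
        single.reference = single.reference[:, :1]
        single.lanes = single.lanes[:1]
        out = align_within_batch(single)
        assert out[0].is_identity and out[0].score == 1.0

    def test_identical_lanes_identity_by_tiebreak(self):
        from cequant.preprocess import (LaneInfo, RegionOfInterest, TraceSet,
                                        replace_roi)
        p = band_profile()
        ts = TraceSet(np.stack([p, p], axis=1), np.stack([p, p], axis=1),
                      [LaneInfo("a", "b0", 0), LaneInfo("b", "b0", 1)])
        ts = replace_roi(ts, RegionOfInterest(0, p.size))
        out = align_within_batch(ts)
        assert all(t.is_identity for t in out)

    def test_planted_within_batch_recovery(self, small_traces):
        traces, truth = small_traces
        out = align_within_batch(traces)
        for j in (1, 2):
            planted = truth.transforms[j].linear
            assert abs(out[j].shift - planted.shift) <= 5.0
            assert abs(out[j].scale - planted.scale) <= 2e-3

    def test_between_batches_single_batch_identity(self, small_traces):
        traces, _ = small_traces
        within = align_within_batch(traces)
        composed = align_between_batches(traces, within)
        for a, b in zip(within, composed):
            assert a == b

    def test_lane_error_carries_lane_id(self, small_traces):
        traces, _ = small_traces
        bad = traces.copy()
        bad.reference[:, 1] = 0.0
        bad.signal[:, 1] = 0.0
        with pytest.raises(AlignmentError, match="b0_lane1"):
            align_within_batch(bad)


class TestSmoothBaseline:
    def test_zero_profile_stays_zero(self):
        np.testing.assert_array_equal(
            subtract_smooth_baseline(np.zeros(3000)), np.zeros(3000))

    def test_slow_drift_removed_bands_kept(self, rng):
        n = 8000
        x = np.arange(n)
        bands = band_profile(n, spacing=90, rng=rng)
        drift = 3.0 * np.sin(2 * np.pi * x / (3 * n))
        out = subtract_smooth_baseline(bands + drift, 501)
        # residual drift: compare band-free floor against zero
        floor = np.percentile(np.abs(out[(bands < 1e-3)][300:-300]), 90)
        assert floor < 0.3 * 3.0
        for c in range(300, n - 300, 90):
            assert out[c] == pytest.approx(bands[c], rel=0.05, abs=0.2)

    def test_sparse_bands_unchanged(self):
        p = band_profile(6000, spacing=400)
        out = subtract_smooth_baseline(p, 501)
        assert np.max(np.abs(out - p)) < 0.01 * p.max()

    def test_window_validation(self):
        with pytest.raises(ConfigError):
            subtract_smooth_baseline(np.ones(100), 4)
        with pytest.raises(ConfigError):
            subtract_smooth_baseline(np.ones(100), 201)


def dp_oracle(scores, offsets, penalty):
    """Exhaustive enumeration over all offset paths (tiny instances)."""
    n_windows, n_states = scores.shape
    best = None
    for path in itertools.product(range(n_states), repeat=n_windows):
        total = sum(scores[w, i] for w, i in enumerate(path))
        total -= penalty * sum(
            abs(offsets[path[w + 1]] - offsets[path[w]])
            for w in range(n_windows - 1))
        tie = 1e-12 * sum(abs(offsets[i]) for i in path)
        key = total - tie
        if best is None or key > best[0] + 1e-15:
            best = (key, [offsets[i] for i in path], total)
    return best


class TestFitPiecewise:
    def test_self_alignment_zero_offsets(self):
        p = band_profile()
        roi = slice(250, 3750)  # every window holds bands
        warp, centers, fine, scores, path = fit_piecewise(
            p, p, window=100, max_offset=20, roi=roi, return_details=True)
        assert np.all(path == 0)
        n_windows = len(piecewise_windows(250, 3750, 100))
        assert warp.linear.score == pytest.approx(n_windows, abs=1e-6)

    def test_dp_equals_exhaustive_enumeration(self, rng):
        for _ in range(50):
            n = 80
            profile = rng.normal(0, 1, n)
            reference = rng.normal(0, 1, n)
            warp, centers, fine, scores_out, path = fit_piecewise(
                profile, reference, window=20, max_offset=2,
                penalty=0.01, roi=slice(0, 80), return_details=True)
            bounds = piecewise_windows(0, 80, 20)
            offsets = np.arange(-2, 3)
            scores = piecewise_scores(profile, reference, bounds, offsets)
            _, oracle_path, oracle_total = dp_oracle(scores, offsets, 0.01)
            dp_total = sum(scores[w, list(offsets).index(d)]
                           for w, d in enumerate(path))
            dp_total -= 0.01 * np.abs(np.diff(path)).sum()
            assert dp_total == pytest.approx(oracle_total, abs=1e-9)
            assert list(path) == oracle_path

    def test_huge_penalty_forces_constant_path(self, rng):
        profile = band_profile(2000, spacing=90, rng=rng)
        reference = np.roll(profile, 3)
        _, _, _, _, path = fit_piecewise(profile, reference, window=100,
                                         max_offset=10, penalty=1e6,
                                         return_details=True)
        assert len(set(path.tolist())) == 1

    def test_max_offset_validation(self):
        with pytest.raises(ConfigError):
            fit_piecewise(np.ones(500), np.ones(500), window=50,
                          max_offset=30)


class TestAlignAll:
    def test_lane_permutation_only_changes_bookkeeping(self, small_experiment):
        from cequant import select_channels
        from cequant.preprocess import (detect_roi, replace_roi,
                                        subtract_constant_baseline)
        batchset, truth = small_experiment
        ts = select_channels(batchset, 0, 1)
        ts = replace_roi(ts, detect_roi(ts))
        ts = subtract_constant_baseline(ts)
        aligned, _, _ = align_all(ts)

        swapped = ts.copy()
        swapped.signal = swapped.signal[:, [0, 2, 1]]
        swapped.reference = swapped.reference[:, [0, 2, 1]]
        swapped.lanes = [swapped.lanes[i] for i in (0, 2, 1)]
        aligned2, _, _ = align_all(swapped)
        np.testing.assert_allclose(aligned2.signal[:, 2],
                                   aligned.signal[:, 1], atol=1e-9)
        np.testing.assert_allclose(aligned2.signal[:, 1],
                                   aligned.signal[:, 2], atol=1e-9)

    def test_report_serializes(self, small_traces):
        traces, _ = small_traces
        _, warps, report = align_all(traces)
        text = report.to_tsv()
        header = text.splitlines()[0].split("\t")
        assert header == ["lane", "batch", "shift", "scale", "score",
                          "mean_abs_offset"]
        assert len(text.strip().splitlines()) == traces.n_lanes + 1

    def test_warp_anchors_monotone(self, small_traces):
        traces, _ = small_traces
        _, warps, _ = align_all(traces)
        for w in warps:
            if w.anchors:
                src = [a[0] for a in w.anchors]
                tgt = [a[1] for a in w.anchors]
                assert np.all(np.diff(src) > 0) and np.all(np.diff(tgt) > 0)
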