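"""Reactivity priors, automated band annotation and manual adjustment."""

import numpy as np
import pytest

from cequant.annotate import (AnnotationError, BandAnnotation, Modifier,
                              SequenceError, adjust_annotation, auto_annotate,
                              reactivity_mask)
from cequant.preprocess import LaneInfo, RegionOfInterest, TraceSet, replace_roi


class TestReactivityMask:
    @pytest.mark.parametrize("modifier,expected", [
        ("DMS", [0.1, 1.0, 1.0, 0.1]),
        ("CMCT", [1.0, 0.1, 0.1, 1.0]),
        ("SHAPE", [1.0, 1.0, 1.0, 1.0]),
        ("ddTTP", [0.0, 1.0, 0.0, 0.0]),
        ("ddATP", [0.0, 0.0, 0.0, 1.0]),
        ("ddCTP", [1.0, 0.0, 0.0, 0.0]),
        ("ddGTP", [0.0, 0.0, 1.0, 0.0]),
        ("nomod", [0.5, 0.5, 0.5, 0.5]),
        ("other", [0.5, 0.5, 0.5, 0.5]),
    ])
    def test_mask_table(self, modifier, expected):
        np.testing.assert_array_equal(reactivity_mask("GACU", modifier),
                                      expected)

    def test_thymine_treated_as_uracil(self):
        np.testing.assert_array_equal(reactivity_mask("GACT", "ddATP"),
                                      reactivity_mask("GACU", "ddATP"))

    def test_invalid_character_position_reported(self):
        with pytest.raises(SequenceError, match="position 2"):
            reactivity_mask("GAXU", "SHAPE")

    def test_unknown_modifier(self):
        with pytest.raises(ValueError, match="unknown modifier"):
            Modifier.parse("EDTA")


def ladder_traces(centers, n, heights_per_lane, roi=None):
    """Aligned TraceSet with Gaussian bands at given centers per lane."""
    x = np.arange(n, dtype=float)
    lanes = []
    sig = np.zeros((n, len(heights_per_lane)))
    for j, heights in enumerate(heights_per_lane):
        for c, h in zip(centers, heights):
            sig[:, j] += h * np.exp(-0.5 * ((x - c) / 6.0) ** 2)
        lanes.append(LaneInfo(f"c{j}", "b0", j))
    ts = TraceSet(sig, sig.copy(), lanes)
    return replace_roi(ts, roi or RegionOfInterest(0, n))


class TestAutoAnnotate:
    def test_uniform_noiseless_centers_recovered(self, rng):
        L = 50
        centers = 200 + 40.0 * np.arange(L)
        seq = "".join(rng.choice(list("ACGU"), L))
        heights = [np.ones(L)]
        ts = ladder_traces(centers, 2400, heights)
        ann = auto_annotate(ts, seq, ["SHAPE"])
        assert len(ann.positions) == L
        np.testing.assert_allclose(ann.positions, centers, atol=1.0)

    def test_positions_strictly_increase(self, rng):
        L = 30
        centers = np.sort(rng.uniform(300, 2100, L))
        centers = 300 + np.cumsum(rng.uniform(40, 80, L))
        seq = "".join(rng.choice(list("ACGU"), L))
        ts = ladder_traces(centers, int(centers[-1]) + 300,
                           [rng.gamma(1.5, 1.0, L) + 0.05])
        ann = auto_annotate(ts, seq, ["SHAPE"])
        assert np.all(np.diff(ann.positions) > 0)
        assert len(ann.positions) == L

    def test_jittered_spacing_mostly_recovered(self):
        hits = total = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            L = 40
            spacing = rng.uniform(40 * 0.85, 40 * 1.15, L)
            centers = 300 + np.cumsum(spacing)
            seq = "".join(rng.choice(list("ACGU"), L))
            heights = rng.gamma(1.5, 1.0, L) + 0.05
            n = int(centers[-1]) + 300
            ts = ladder_traces(centers, n, [heights])
            noisy = ts.copy()
            noisy.signal += rng.normal(0, 0.1, noisy.signal.shape)
            ann = auto_annotate(noisy, seq, ["SHAPE"])
            hits += int(np.sum(np.abs(ann.positions - centers) <= 20.0))
            total += L
        assert hits / total >= 0.95

    def test_scale_invariance(self, rng):
        L = 25
        centers = 200 + 50.0 * np.arange(L)
        seq = "".join(rng.choice(list("ACGU"), L))
        heights = [rng.gamma(1.5, 1.0, L), rng.gamma(1.5, 1.0, L)]
        ts = ladder_traces(centers, 1700, heights)
        ann1 = auto_annotate(ts, seq, ["SHAPE", "DMS"])
        ts2 = ts.copy()
        ts2.signal[:, 0] *= 7.0
        ts2.signal[:, 1] *= 0.3
        ann2 = auto_annotate(ts2, seq, ["SHAPE", "DMS"])
        np.testing.assert_allclose(ann1.positions, ann2.positions, atol=1e-9)

    def test_zero_mask_lane_is_inert(self, rng):
        L = 20
        centers = 200 + 50.0 * np.arange(L)
        seq = "A" * L  # ddATP marks U only -> all-zero mask for this lane
        heights = [np.ones(L), rng.gamma(1.0, 1.0, L)]
        ts = ladder_traces(centers, 1400, heights)
        ann_both = auto_annotate(ts, seq, ["SHAPE", "ddATP"])
        solo = ts.copy()
        solo.signal = solo.signal[:, :1]
        solo.reference = solo.reference[:, :1]
        solo.lanes = solo.lanes[:1]
        ann_solo = auto_annotate(solo, seq, ["SHAPE"])
        np.testing.assert_allclose(ann_both.positions, ann_solo.positions,
                                   atol=1e-9)

    def test_ladder_only_lane_exact(self):
        """A noiseless ddNTP ladder pins its residues to planted centers."""
        L = 24
        centers = 200 + 45.0 * np.arange(L)
        seq = "AU" * (L // 2)
        mask = reactivity_mask(seq, "ddTTP")
        ts = ladder_traces(centers, 1500, [mask])
        ann = auto_annotate(ts, seq, ["ddTTP"])
        marked = np.flatnonzero(mask == 1.0)
        np.testing.assert_allclose(ann.positions[marked], centers[marked],
                                   atol=0.5)

    def test_reverse_orientation_flips_residue_map(self, rng):
        L = 24
        centers = 200 + 45.0 * np.arange(L)
        seq = "AU" * (L // 2)
        ts = ladder_traces(centers, 1500, [np.ones(L)])
        fwd = auto_annotate(ts, seq, ["SHAPE"])
        rev = auto_annotate(ts, seq, ["SHAPE"], orientation="reverse")
        np.testing.assert_allclose(rev.positions, fwd.positions, atol=1e-9)
        assert rev.annotated_residues == tuple(reversed(
            fwd.annotated_residues))

    def test_modifier_count_mismatch(self, rng):
        ts = ladder_traces(200 + 40.0 * np.arange(10), 700, [np.ones(10)])
        with pytest.raises(AnnotationError, match="modifiers"):
            auto_annotate(ts, "ACGUACGUAC", ["SHAPE", "DMS"])

    def test_too_many_residues_for_roi(self):
        ts = ladder_traces([300.0, 350.0], 800,
                           [np.ones(2)], roi=RegionOfInterest(280, 420))
        with pytest.raises(AnnotationError, match="widen the ROI"):
            auto_annotate(ts, "ACGU" * 30, ["SHAPE"])


class TestAdjustAnnotation:
    def _ann(self):
        return BandAnnotation("ACGUA", np.array([100.0, 380.0, 400.0, 440.0,
                                                 500.0]), tuple(range(5)))

    def test_move_single_residue(self):
        out = adjust_annotation(self._ann(), 2, 410.0)
        assert out.positions[2] == 410.0
        assert list(out.positions[[0, 1, 3, 4]]) == [100.0, 380.0, 440.0,
                                                     500.0]

    def test_collision_rejected_with_neighbor(self):
        with pytest.raises(AnnotationError, match="440"):
            adjust_annotation(self._ann(), 2, 445.0)

    def test_adjust_is_involution(self):
        ann = self._ann()
        out = adjust_annotation(adjust_annotation(ann, 2, 410.0), 2, 400.0)
        np.testing.assert_array_equal(out.positions, ann.positions)
        assert out.annotated_residues == ann.annotated_residues

    def test_unannotated_residue_rejected(self):
        with pytest.raises(AnnotationError):
            adjust_annotation(self._ann(), 9, 450.0)


class TestAnnotationSerialization:
    def test_tsv_round_trip(self):
        ann = BandAnnotation("ACGU", np.array([10.5, 20.25, 31.0, 44.125]),
                             (0, 1, 2, 3), offset=89)
        text = ann.to_tsv()
        back = BandAnnotation.from_tsv(text, "ACGU", offset=89)
        np.testing.assert_allclose(back.positions, ann.positions, atol=1e-3)
        assert back.annotated_residues == ann.annotated_residues
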