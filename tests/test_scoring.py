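"""Per-nucleus lipid scores, gating, and per-well aggregation."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fats.core import AnalysisError, BinaryMask, ParameterError, PixelGrid
from fats.nuclei import NucleusRegion
from fats.scoring import (
    GateParams,
    LipidScore,
    aggregate_well,
    compare_to_control,
    derive_gate_threshold,
    gate_scores,
    score_nucleus,
    whole_image_intensity,
)


def make_nucleus(bbox, label=1):
    r0, c0, r1, c1 = bbox
    coords = np.array(
        [(r, c) for r in range(r0, r1) for c in range(c0, c1)]
    )
    return NucleusRegion(
        label=label,
        pixel_mask=coords,
        area_px=len(coords),
        area_um2=float(len(coords)),
        bbox=bbox,
        aspect_ratio=1.0,
        centroid=((r0 + r1) / 2, (c0 + c1) / 2),
        status="kept",
    )


def lipid_pair(values, mask, pitch=1.0):
    return (
        PixelGrid(np.asarray(values, dtype=np.uint8), pitch),
        BinaryMask(np.asarray(mask, dtype=np.uint8) * 255, pitch),
    )


class TestScoreNucleus:
    def test_no_foreground_scores_zero(self):
        lipid, mask = lipid_pair(np.full((10, 10), 90), np.zeros((10, 10)))
        s = score_nucleus(make_nucleus((2, 2, 8, 8)), lipid, mask, GateParams())
        assert (s.p_t, s.i_s, s.s) == (0.0, 0.0, 0.0)

    def test_fully_foreground_uniform_intensity(self):
        lipid, mask = lipid_pair(np.full((10, 10), 140), np.ones((10, 10)))
        s = score_nucleus(
            make_nucleus((0, 0, 10, 10)), lipid, mask, GateParams(search_radius_um=0)
        )
        assert (s.p_t, s.i_s, s.s) == (1.0, 140.0, 140.0)

    def test_quarter_coverage_hand_computed(self):
        # 10x10 search region, 25 foreground pixels of mean intensity 200
        values = np.zeros((10, 10))
        mask = np.zeros((10, 10))
        values[:5, :5] = 200
        mask[:5, :5] = 1
        lipid, lipid_mask = lipid_pair(values, mask)
        s = score_nucleus(
            make_nucleus((0, 0, 10, 10)), lipid, lipid_mask,
            GateParams(search_radius_um=0),
        )
        assert s.p_t == pytest.approx(0.25)
        assert s.i_s == pytest.approx(200.0)
        assert s.s == pytest.approx(50.0)

    def test_brute_force_pixel_loop_oracle(self, rng):
        values = rng.integers(0, 256, (30, 30), dtype=np.uint8)
        fg = rng.random((30, 30)) < 0.3
        lipid, mask = lipid_pair(values, fg)
        nucleus = make_nucleus((8, 10, 14, 18))
        params = GateParams(search_radius_um=3.0)  # pad 3 px at pitch 1
        s = score_nucleus(nucleus, lipid, mask, params)
        # independent loop over the dilated box
        r0, c0, r1, c1 = 5, 7, 17, 21
        tot = fgc = inten = 0
        for i in range(r0, r1):
            for j in range(c0, c1):
                tot += 1
                if fg[i, j]:
                    fgc += 1
                    inten += int(values[i, j])
        assert s.p_t == pytest.approx(fgc / tot)
        assert s.i_s == pytest.approx(inten / fgc)
        assert s.s == pytest.approx((fgc / tot) * (inten / fgc))

    def test_search_region_clipped_at_borders(self):
        lipid, mask = lipid_pair(np.full((6, 6), 10), np.ones((6, 6)))
        s = score_nucleus(
            make_nucleus((0, 0, 3, 3)), lipid, mask, GateParams(search_radius_um=50)
        )
        assert s.p_t == 1.0  # region clipped to the whole image

    def test_sum_intensity_mode(self):
        values = np.zeros((4, 4))
        values[0, 0] = 100
        mask = np.zeros((4, 4))
        mask[0, 0] = 1
        lipid, lipid_mask = lipid_pair(values, mask)
        s = score_nucleus(
            make_nucleus((0, 0, 4, 4)), lipid, lipid_mask,
            GateParams(search_radius_um=0, intensity_mode="sum"),
        )
        assert s.i_s == 100.0
        assert s.s == pytest.approx(100.0 / 16)

    def test_refuses_excluded_region(self):
        lipid, mask = lipid_pair(np.zeros((5, 5)), np.zeros((5, 5)))
        bad = dataclasses.replace(make_nucleus((0, 0, 3, 3)), status="too_small")
        with pytest.raises(AnalysisError):
            score_nucleus(bad, lipid, mask, GateParams())


class TestGating:
    def scores(self, values):
        return [LipidScore(i, 0.5, 2 * v, v) for i, v in enumerate(values)]

    def test_all_zero_none_differentiated(self):
        gated = gate_scores(self.scores([0, 0, 0]), GateParams(gate_threshold=1))
        assert sum(s.differentiated for s in gated) == 0

    def test_strictly_exceeds_semantics(self):
        gated = gate_scores(self.scores([0, 5, 10]), GateParams(gate_threshold=5))
        assert [s.differentiated for s in gated] == [False, False, True]

    def test_negative_gate_rejected(self):
        with pytest.raises(ParameterError):
            GateParams(gate_threshold=-1)

    def test_gate_monotonicity(self, rng):
        scores = self.scores(rng.uniform(0, 100, 50))
        counts = [
            sum(s.differentiated for s in gate_scores(scores, GateParams(g)))
            for g in np.linspace(0, 100, 21)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_derived_gate_is_mean_plus_two_sd(self):
        control = self.scores([1.0, 2.0, 3.0, 4.0])
        s = np.array([1.0, 2.0, 3.0, 4.0])
        assert derive_gate_threshold(control) == pytest.approx(
            s.mean() + 2 * s.std()
        )


class TestAggregation:
    def gated(self, values, gate):
        return gate_scores(
            [LipidScore(i, 0.1, v, v) for i, v in enumerate(values)],
            GateParams(gate_threshold=gate),
        )

    def test_single_field_fraction(self):
        well = aggregate_well("A01", [self.gated([0, 0, 0, 10], 5)])
        assert well.adipogenic_score == pytest.approx(25.0)
        assert well.n_nuclei == 4

    def test_pooling_is_not_percentage_averaging(self):
        f1 = self.gated([10] * 10 + [0] * 40, 5)  # 10/50
        f2 = self.gated([10] * 20 + [0] * 30, 5)  # 20/50
        well = aggregate_well("A01", [f1, f2])
        assert well.adipogenic_score == pytest.approx(30.0)

    def test_pooling_identity_across_field_boundaries(self):
        scores = self.gated(list(range(20)), 7)
        merged = aggregate_well("w", [scores])
        chunked = aggregate_well("w", [scores[:3], scores[3:11], scores[11:]])
        assert merged.adipogenic_score == chunked.adipogenic_score
        assert merged.mean_lipid_score == chunked.mean_lipid_score
        np.testing.assert_array_equal(
            merged.histogram_counts, chunked.histogram_counts
        )

    def test_constant_scores_single_occupied_bin(self):
        well = aggregate_well("w", [self.gated([7.0] * 12, 5)])
        assert well.mean_lipid_score == pytest.approx(7.0)
        assert (well.histogram_counts > 0).sum() == 1
        assert well.histogram_counts.sum() == well.n_nuclei

    def test_empty_well_flagged_invalid_not_zero(self):
        well = aggregate_well("w", [[]])
        assert not well.valid
        assert well.adipogenic_score is None
        assert well.mean_lipid_score is None


class TestCompareToControl:
    def well(self, wid, score):
        gated = self.make(score)
        return aggregate_well(wid, [gated])

    def make(self, score_pct):
        n = 100
        k = int(round(score_pct))
        return gate_scores(
            [LipidScore(i, 0.1, 10.0 if i < k else 0.0, 10.0 if i < k else 0.0)
             for i in range(n)],
            GateParams(gate_threshold=5.0),
        )

    def test_delta_against_control_mean(self):
        wells = [self.well("C1", 30), self.well("T1", 65)]
        table = compare_to_control(wells, ["C1"])
        t1 = table[table.well_id == "T1"].iloc[0]
        assert t1.delta_pp == pytest.approx(35.0)

    def test_two_controls_averaged(self):
        wells = [self.well("C1", 20), self.well("C2", 40), self.well("T", 30)]
        table = compare_to_control(wells, ["C1", "C2"])
        assert table[table.well_id == "T"].iloc[0].delta_pp == pytest.approx(0.0)

    def test_sorted_descending(self):
        wells = [self.well("C", 10), self.well("A", 50), self.well("B", 30)]
        table = compare_to_control(wells, ["C"])
        assert list(table.well_id) == ["A", "B", "C"]

    def test_missing_controls_rejected(self):
        with pytest.raises(AnalysisError):
            compare_to_control([self.well("T", 30)], ["C9"])


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 250), min_size=5, max_size=40), st.floats(0, 250))
def test_intensity_scaling_never_decreases_scores(values, gate):
    """Brightening every droplet can only raise s and the adipogenic score."""
    base = [LipidScore(i, 0.4, v, 0.4 * v) for i, v in enumerate(values)]
    brighter = [LipidScore(i, 0.4, 1.3 * v, 0.4 * 1.3 * v) for i, v in enumerate(values)]
    params = GateParams(gate_threshold=gate)
    w1 = aggregate_well("w", [gate_scores(base, params)])
    w2 = aggregate_well("w", [gate_scores(brighter, params)])
    assert all(b.s >= a.s for a, b in zip(w1.scores, w2.scores))
    assert w2.mean_lipid_score >= w1.mean_lipid_score
    assert w2.adipogenic_score >= w1.adipogenic_score


def test_whole_image_intensity_is_plain_mean():
    img = PixelGrid(np.arange(16, dtype=np.uint8).reshape(4, 4), 1.0)
    assert whole_image_intensity(img) == pytest.approx(np.arange(16).mean())
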