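"""Threshold segmentation, compartment means, VPE, laterality and staging."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from lsfg import (CompleteOcclusion, LIDefinition, Parameter, PerfusionStage,
                  ValidationError, classify_perfusion_stage,
                  compute_region_metrics, compute_vpe, flag_abnormal,
                  full_image_roi, laterality_index_normal,
                  laterality_index_occlusion, perfusion_index,
                  segment_by_threshold, standard_range)
from conftest import brute_force_region_means, make_map, make_region_metrics

THRESHOLD = 15.0

finite_maps = hnp.arrays(
    dtype=float, shape=hnp.array_shapes(min_dims=2, max_dims=2,
                                        min_side=2, max_side=12),
    elements=st.floats(0.0, 60.0, allow_nan=False))


class TestSegmentation:
    def test_inclusive_threshold_example(self):
        m = make_map([[16.0, 14.0], [15.0, 3.0]])
        seg = segment_by_threshold(m, full_image_roi(2, 2), THRESHOLD)
        np.testing.assert_array_equal(seg.vascular_mask,
                                      [[True, False], [True, False]])

    def test_all_below_threshold_gives_empty_mask(self):
        m = make_map(np.full((3, 3), 2.0))
        seg = segment_by_threshold(m, full_image_roi(3, 3), THRESHOLD)
        assert not seg.vascular_mask.any()

    def test_random_map_matches_brute_force(self):
        rng = np.random.default_rng(8)
        values = rng.uniform(0, 40, size=(8, 8))
        m = make_map(values)
        seg = segment_by_threshold(m, full_image_roi(8, 8), THRESHOLD)
        expected = np.array([[values[r, c] >= THRESHOLD for c in range(8)]
                             for r in range(8)])
        np.testing.assert_array_equal(seg.vascular_mask, expected)


class TestRegionMetrics:
    def test_hand_example(self):
        m = make_map([[20.0, 10.0], [30.0, 6.0]])
        rm = compute_region_metrics(
            m, segment_by_threshold(m, full_image_roi(2, 2), THRESHOLD))
        assert (rm.mv, rm.mt, rm.ma, rm.mv_mt, rm.arbs) == \
            (25.0, 8.0, 16.5, 17.0, 50.0)

    def test_single_compartment_keeps_mt_undefined(self):
        m = make_map(np.full((2, 2), 20.0))
        rm = compute_region_metrics(
            m, segment_by_threshold(m, full_image_roi(2, 2), THRESHOLD))
        assert rm.mv == 20.0 and rm.ma == 20.0 and rm.arbs == 100.0
        assert rm.mt is None and rm.mv_mt is None

    def test_no_perfusion_map_reports_mv_zero(self):
        m = make_map(np.zeros((3, 3)))
        rm = compute_region_metrics(
            m, segment_by_threshold(m, full_image_roi(3, 3), THRESHOLD))
        assert rm.mv is None and rm.mv_reported == 0.0
        assert rm.mt == 0.0 and rm.ma == 0.0 and rm.arbs == 0.0
        assert compute_vpe(rm) == 0.0
        assert classify_perfusion_stage(rm) is PerfusionStage.NONE

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(finite_maps)
    def test_mixture_identity_and_ordering(self, values):
        m = make_map(values)
        rm = compute_region_metrics(
            m, segment_by_threshold(m, full_image_roi(*values.shape),
                                    THRESHOLD))
        w = rm.arbs / 100.0
        mv = rm.mv if rm.mv is not None else 0.0
        mt = rm.mt if rm.mt is not None else 0.0
        assert rm.ma == pytest.approx(w * mv + (1 - w) * mt, abs=1e-9)
        assert 0.0 <= rm.arbs <= 100.0
        if rm.mv is not None and rm.mt is not None:
            assert rm.mt < THRESHOLD <= rm.mv
            assert rm.mv_mt > 0
            assert rm.mt <= rm.ma <= rm.mv

    def test_arbs_monotone_in_threshold(self):
        rng = np.random.default_rng(9)
        m = make_map(rng.uniform(0, 40, size=(10, 10)))
        roi = full_image_roi(10, 10)
        arbs = [compute_region_metrics(
            m, segment_by_threshold(m, roi, t)).arbs
            for t in (5.0, 10.0, 15.0, 20.0, 30.0)]
        assert all(a >= b for a, b in zip(arbs, arbs[1:]))


class TestVPE:
    @pytest.mark.parametrize("mv, arbs, expected", [
        (28.1, 31.0, 871.1),   # normal perfusion exemplar
        (19.8, 3.0, 59.4),     # weak perfusion exemplar
        (15.6, 0.0, 0.0),      # diminishing perfusion: no vessel area
        (0.0, 0.0, 0.0),       # no perfusion at all
    ])
    def test_reference_exemplars(self, mv, arbs, expected):
        rm = make_region_metrics(mv, arbs)
        assert compute_vpe(rm) == pytest.approx(expected, rel=1e-12)

    def test_strictly_increasing_in_each_factor(self):
        base = compute_vpe(make_region_metrics(20.0, 10.0))
        assert compute_vpe(make_region_metrics(25.0, 10.0)) > base
        assert compute_vpe(make_region_metrics(20.0, 12.0)) > base


class TestLaterality:
    def test_normal_li_of_reference_group_means(self):
        a = make_region_metrics(24.70, 50.0)
        b = make_region_metrics(26.19, 50.0)
        li = laterality_index_normal(a, b, Parameter.MV)
        assert li.li == pytest.approx(0.943, abs=5e-4)
        assert li.definition is LIDefinition.NORMAL_LOWER_OVER_HIGHER

    def test_normal_li_symmetric_and_bounded(self):
        a = make_region_metrics(18.0, 40.0)
        b = make_region_metrics(24.0, 40.0)
        ab = laterality_index_normal(a, b, Parameter.MV).li
        ba = laterality_index_normal(b, a, Parameter.MV).li
        assert ab == ba and 0.0 <= ab <= 1.0

    def test_identical_eyes_give_unity(self):
        a = make_region_metrics(20.0, 30.0)
        assert laterality_index_normal(a, a, Parameter.MV).li == 1.0

    def test_zero_against_positive_gives_zero(self):
        a = make_region_metrics(0.0, 0.0, ma=0.0)
        b = make_region_metrics(20.0, 30.0)
        assert laterality_index_normal(a, b, Parameter.MA).li == 0.0

    def test_both_zero_defined_as_unity(self):
        a = make_region_metrics(0.0, 0.0, ma=0.0)
        assert laterality_index_normal(a, a, Parameter.MA).li == 1.0

    def test_undefined_parameter_is_error(self):
        a = make_region_metrics(20.0, 100.0)  # mt is None
        with pytest.raises(ValidationError):
            laterality_index_normal(a, a, Parameter.MT)

    def test_occlusion_li_of_reference_stage_means(self):
        occ = make_region_metrics(6.00, 10.0)
        fel = make_region_metrics(22.43, 30.0)
        li = laterality_index_occlusion(occ, fel, Parameter.MV)
        assert li.li == pytest.approx(0.268, abs=1e-3)
        assert li.definition is LIDefinition.OCCLUDED_OVER_FELLOW

    def test_occlusion_li_edge_cases(self):
        fel = make_region_metrics(20.0, 30.0)
        assert laterality_index_occlusion(fel, fel, Parameter.MV).li == 1.0
        occ0 = make_region_metrics(0.0, 0.0, ma=0.0)
        assert laterality_index_occlusion(occ0, fel, Parameter.MA).li == 0.0
        with pytest.raises(ValidationError):
            laterality_index_occlusion(fel, occ0, Parameter.MA)


class TestStandardRange:
    def test_reference_occlusion_li_column(self):
        # per-eye vascular-area occlusion LI values of the three two-eye
        # animals; the cohort mean/sd round to 0.62 +/- 0.25
        rng = standard_range([1.02, 0.26, 0.65, 0.51, 0.61, 0.66])
        assert round(rng.mean, 2) == 0.62
        assert round(rng.sd, 2) == 0.25
        assert rng.lower == pytest.approx(rng.mean - rng.sd)
        assert rng.upper == pytest.approx(rng.mean + rng.sd)

    def test_single_value(self):
        rng = standard_range([0.9])
        assert (rng.mean, rng.sd, rng.n) == (0.9, 0.0, 1)

    def test_two_point_closed_form(self):
        rng = standard_range([0.8, 1.0])
        assert rng.mean == pytest.approx(0.9)
        assert rng.sd == pytest.approx(np.sqrt(2) * 0.1, abs=1e-12)

    def test_empty_is_error(self):
        with pytest.raises(ValidationError):
            standard_range([])


class TestAbnormalityFlag:
    def test_clearly_low_li_is_abnormal(self):
        rng = standard_range([0.94 - 0.05, 0.94 + 0.05])  # mean .94 sd .05*k
        li = laterality_index_occlusion(make_region_metrics(5.2, 10.0),
                                        make_region_metrics(20.0, 30.0),
                                        Parameter.MV)
        assert li.li == pytest.approx(0.26)
        assert flag_abnormal(li, rng).abnormal is True

    def test_boundary_value_is_not_abnormal(self):
        from lsfg import LateralityResult, StandardRange
        rng = StandardRange(mean=0.94, sd=0.05, lower=0.89, upper=0.99, n=8)
        li = LateralityResult(parameter=Parameter.MV, li=0.89,
                              definition=LIDefinition.OCCLUDED_OVER_FELLOW)
        assert flag_abnormal(li, rng).abnormal is False
        high = LateralityResult(parameter=Parameter.MV, li=0.95,
                                definition=LIDefinition.OCCLUDED_OVER_FELLOW)
        assert flag_abnormal(high, rng).abnormal is False


class TestPerfusionIndex:
    def test_reference_stage_mean_ratio(self):
        pi = perfusion_index(make_region_metrics(22.43, 30.0),
                             make_region_metrics(6.00, 10.0), Parameter.MV)
        assert pi == pytest.approx(3.738, abs=5e-4)

    def test_no_change_gives_unity(self):
        m = make_region_metrics(20.0, 30.0)
        assert perfusion_index(m, m, Parameter.MV) == 1.0

    def test_zero_occluded_flow_signals_complete_occlusion(self):
        with pytest.raises(CompleteOcclusion):
            perfusion_index(make_region_metrics(20.0, 30.0),
                            make_region_metrics(0.0, 0.0, ma=0.0),
                            Parameter.MA)


class TestPerfusionStaging:
    @pytest.mark.parametrize("mv, arbs, stage", [
        (28.1, 31.0, PerfusionStage.NORMAL),
        (24.8, 6.0, PerfusionStage.LIMITED),
        (23.1, 5.0, PerfusionStage.LIMITED),
        (19.8, 3.0, PerfusionStage.WEAK),
        (15.6, 0.0, PerfusionStage.DIMINISHING),
        (0.0, 0.0, PerfusionStage.NONE),
    ])
    def test_five_reference_exemplars(self, mv, arbs, stage):
        assert classify_perfusion_stage(make_region_metrics(mv, arbs)) is stage

    def test_stage_monotone_under_flow_scaling(self):
        rng = np.random.default_rng(4)
        values = rng.uniform(0, 40, size=(12, 12))
        roi = full_image_roi(12, 12)
        stages = []
        for s in (1.0, 0.7, 0.45, 0.2, 0.05, 0.0):
            m = make_map(values * s)
            rm = compute_region_metrics(
                m, segment_by_threshold(m, roi, THRESHOLD))
            stages.append(classify_perfusion_stage(rm))
        assert all(a >= b for a, b in zip(stages, stages[1:]))


@settings(max_examples=60, deadline=None, derandomize=True)
@given(finite_maps, st.floats(1.0, 50.0))
def test_region_means_match_brute_force_oracle(values, threshold):
    m = make_map(values)
    seg = segment_by_threshold(m, full_image_roi(*values.shape), threshold)
    rm = compute_region_metrics(m, seg)
    oracle = brute_force_region_means(values, seg.roi_mask, threshold)
    assert rm.n_vascular == oracle["n_vascular"]
    assert rm.n_tissue == oracle["n_tissue"]
    assert rm.arbs == pytest.approx(oracle["arbs"], abs=1e-9)
    assert rm.ma == pytest.approx(oracle["ma"], abs=1e-9)
    for mine, ref in ((rm.mv, oracle["mv"]), (rm.mt, oracle["mt"])):
        assert (mine is None) == (ref is None)
        if mine is not None:
            assert mine == pytest.approx(ref, abs=1e-9)
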