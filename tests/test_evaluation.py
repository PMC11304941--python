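"""Benchmark metrics, ME-rate QC, marker filtering and GE calibration."""

import numpy as np
import pandas as pd
import pytest

from magicphase.evaluation import (
    EvaluationError,
    adjusted_resolution,
    calibrate_ge_from_me,
    co_count_map,
    evaluate_detection,
    filter_markers_by_me,
    match_events,
    me_rate,
    pct_filtered,
    precision_recall_f1,
)
from magicphase.events import RecombinationEvent
from magicphase.plink_io import GenotypeTable, MarkerMap, Pedigree, PedigreeRecord
from magicphase.simulator import SimConfig, SimulationTruth


def ev(start_bp, end_bp, iid="X", hom="paternal", start_idx=0, end_idx=1):
    return RecombinationEvent(
        individual=iid,
        homolog=hom,
        chrom="1",
        left_origin=1,
        right_origin=2,
        start_idx=start_idx,
        end_idx=end_idx,
        start_bp=start_bp,
        end_bp=end_bp,
        start_marker="a",
        end_marker="b",
    )


class TestMatchEvents:
    def test_breakpoint_inside_interval_matches(self):
        truth = SimulationTruth(breakpoints={("X", "paternal"): [35]})
        n, matches = match_events([ev(30, 40)], truth)
        assert n == 1 and matches == [[35]]

    def test_multiply_matched_event_counts_once(self):
        truth = SimulationTruth(breakpoints={("X", "paternal"): [32, 38]})
        n, matches = match_events([ev(30, 40)], truth)
        assert n == 1 and matches == [[32, 38]]

    def test_breakpoint_on_other_homolog_no_match(self):
        truth = SimulationTruth(
            breakpoints={("X", "paternal"): [], ("X", "maternal"): [35]}
        )
        n, _ = match_events([ev(30, 40)], truth)
        assert n == 0

    def test_closed_interval_boundaries_included(self):
        truth = SimulationTruth(breakpoints={("X", "paternal"): [30]})
        n, _ = match_events([ev(30, 40)], truth)
        assert n == 1

    def test_unknown_meiosis_raises(self):
        truth = SimulationTruth(breakpoints={("Y", "paternal"): [5]})
        with pytest.raises(EvaluationError):
            match_events([ev(30, 40)], truth)


class TestMetricArithmetic:
    def test_precision_recall_f1_from_counts(self):
        p, r, f1 = precision_recall_f1(2, 2, 3)
        assert p == 1.0 and r == pytest.approx(2 / 3) and f1 == pytest.approx(0.8)

    def test_zero_matches_give_zero_metrics(self):
        assert precision_recall_f1(0, 5, 3) == (0.0, 0.0, 0.0)

    def test_f1_equals_rate_when_precision_equals_recall(self):
        p, r, f1 = precision_recall_f1(3, 4, 4)
        assert p == r == f1 == 0.75

    def test_matched_exceeding_denominator_raises(self):
        with pytest.raises(EvaluationError):
            precision_recall_f1(4, 3, 5)

    def test_adjusted_resolution_is_precision_times_inverse_median(self):
        events = [ev(0, 1, end_idx=2), ev(0, 1, end_idx=4), ev(0, 1, end_idx=6)]
        res, adj = adjusted_resolution(0.8, events)
        assert res == pytest.approx(0.25)  # median of {2, 4, 6} intervals
        assert adj == pytest.approx(0.2)

    def test_single_interval_events_have_resolution_one(self):
        res, adj = adjusted_resolution(1.0, [ev(0, 1, end_idx=1)])
        assert res == 1.0 and adj == 1.0

    def test_no_events_is_na(self):
        assert adjusted_resolution(1.0, []) == (None, None)

    @pytest.mark.parametrize(
        "raw, kept, expect", [(100, 40, 60.0), (10, 10, 0.0), (7, 0, 100.0)]
    )
    def test_pct_filtered(self, raw, kept, expect):
        assert pct_filtered(raw, kept) == pytest.approx(expect)

    def test_pct_filtered_zero_raw_is_na(self):
        assert pct_filtered(0, 0) is None


class TestMeRate:
    def _tiny(self, off_gt):
        records = [
            PedigreeRecord("F1", None, None),
            PedigreeRecord("F2", None, None),
            PedigreeRecord("K", "F1", "F2"),
        ]
        ped = Pedigree(records)
        n = len(off_gt)
        alleles = np.array(
            [[(1, 1)] * n, [(1, 1)] * n, off_gt], dtype=np.int8
        )
        gt = GenotypeTable(["F1", "F2", "K"], [f"s{i}" for i in range(n)], alleles)
        return gt, ped

    def test_one_violation_in_ten_tested_loci(self):
        off = [(1, 2)] + [(1, 1)] * 9  # het child of two 1/1 parents
        gt, ped = self._tiny(off)
        assert me_rate(gt, ped) == pytest.approx(0.1)

    def test_missing_members_not_tested(self):
        off = [(0, 0), (1, 1)]
        gt, ped = self._tiny(off)
        assert me_rate(gt, ped) == 0.0

    def test_per_generation_scope(self):
        off = [(1, 2), (1, 1)]
        gt, ped = self._tiny(off)
        rates = me_rate(gt, ped, scope="per-generation")
        assert rates == {1: 0.5}

    def test_per_marker_scope(self):
        off = [(1, 2), (1, 1)]
        gt, ped = self._tiny(off)
        rates = me_rate(gt, ped, scope="per-marker")
        assert rates.tolist() == [1.0, 0.0]


class TestFilterMarkersByMe:
    def _population(self):
        records = [PedigreeRecord("F1", None, None), PedigreeRecord("F2", None, None)]
        records += [PedigreeRecord(f"K{i}", "F1", "F2") for i in range(10)]
        ped = Pedigree(records)
        # marker 0: 2 of 10 offspring ME (20% > 10%); marker 1: exactly 10%;
        # marker 2: clean
        rows = [[(1, 1)] * 3, [(1, 1)] * 3]
        for i in range(10):
            k = [(1, 1), (1, 1), (1, 1)]
            if i < 2:
                k[0] = (2, 2)
            if i < 1:
                k[1] = (2, 2)
            rows.append(k)
        gt = GenotypeTable(
            [r.iid for r in records], ["m1", "m2", "m3"], np.array(rows, np.int8)
        )
        mm = MarkerMap(
            pd.DataFrame(
                {"chrom": ["1"] * 3, "marker": ["m1", "m2", "m3"], "bp": [10, 20, 30]}
            )
        )
        return gt, ped, mm

    def test_above_threshold_dropped_boundary_kept(self):
        gt, ped, mm = self._population()
        out, out_map = filter_markers_by_me(gt, ped, mm, threshold=0.10)
        assert out.loci == ["m2", "m3"]
        assert out_map.markers == ["m2", "m3"]

    def test_clean_data_untouched(self):
        gt, ped, mm = self._population()
        keep = gt.subset_loci(np.array([False, False, True]))
        out, _ = filter_markers_by_me(keep, ped, None)
        assert out.loci == ["m3"]


class TestCoCountMap:
    def _map(self, n):
        return MarkerMap(
            pd.DataFrame(
                {
                    "chrom": ["1"] * n,
                    "marker": [f"s{i}" for i in range(n)],
                    "bp": [10 * (i + 1) for i in range(n)],
                }
            )
        )

    def test_single_interval_event_adds_one(self):
        df = co_count_map([ev(20, 30, start_idx=1, end_idx=2)], self._map(5))
        assert df["weight"].tolist() == [0, 1.0, 0, 0]

    def test_wide_event_distributes_evenly(self):
        df = co_count_map([ev(10, 50, start_idx=0, end_idx=4)], self._map(5))
        assert df["weight"].tolist() == [0.25] * 4

    def test_total_weight_equals_event_count(self):
        rng = np.random.default_rng(0)
        events = []
        for _ in range(37):
            a = int(rng.integers(0, 8))
            b = int(rng.integers(a + 1, 10))
            events.append(ev(0, 1, start_idx=a, end_idx=b))
        df = co_count_map(events, self._map(11))
        assert df["weight"].sum() == pytest.approx(37.0)


class TestCalibration:
    def test_round_trip_and_monotonicity(self):
        grid = [0.01, 0.02, 0.03, 0.04, 0.06]
        cal = calibrate_ge_from_me(
            SimConfig(n_loci=300, offspring_per_cross=2), grid, n_reps=2, seed=3
        )
        assert cal.slope > 0
        assert all(a < b for a, b in zip(cal.me_values, cal.me_values[1:]))
        for g, m in zip(cal.ge_grid, cal.me_values):
            assert cal.invert(m) == pytest.approx(g, rel=0.25)

    def test_curve_passes_near_zero_at_ge_zero(self):
        grid = [0.0, 0.03, 0.06]
        cal = calibrate_ge_from_me(SimConfig(n_loci=200), grid, n_reps=2, seed=1)
        assert cal.me_values[0] == 0.0
        assert abs(cal.predict(0.0)) < 0.01

    def test_too_small_grid_rejected(self):
        with pytest.raises(EvaluationError):
            calibrate_ge_from_me(SimConfig(), [0.01, 0.02], seed=0)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(EvaluationError):
            calibrate_ge_from_me(SimConfig(), [0.02, 0.02, 0.02], seed=0)


class TestEvaluateDetection:
    def test_report_composes_all_metrics(self):
        truth = SimulationTruth(
            breakpoints={("X", "paternal"): [35, 99], ("X", "maternal"): [7]}
        )
        detected = [ev(30, 40, end_idx=2), ev(5, 10, hom="maternal", end_idx=4)]
        rep = evaluate_detection(detected, truth, raw_events=4)
        assert rep.n_matched == 2 and rep.n_detected == 2 and rep.n_true == 3
        assert rep.precision == 1.0
        assert rep.recall == pytest.approx(2 / 3)
        assert rep.resolution == pytest.approx(1 / 3)
        assert rep.pct_filtered == pytest.approx(50.0)

    def test_empty_detection_reports_zeros_without_crash(self):
        truth = SimulationTruth(breakpoints={("X", "paternal"): [1]})
        rep = evaluate_detection([], truth)
        assert rep.precision == 0.0 and rep.recall == 0.0 and rep.degenerate
        assert rep.resolution is None
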