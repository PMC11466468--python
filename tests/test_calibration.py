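"""Discrepancy statistics, threshold sweeps and validation statistics."""

import math

import numpy as np
import pytest

from tomolot import (
    CalibrationEntry,
    CalibrationError,
    LOTSinogram,
    OpticalEventLog,
    calibrate_threshold,
    discrepancy_stats,
    fraction_report,
    validate_methods,
)

from conftest import make_small_plan


class TestDiscrepancyStats:
    def test_identical_lists_are_all_zero(self):
        stats = discrepancy_stats([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert stats.mean == 0.0 and stats.sd == 0.0 and not stats.outliers

    def test_constant_shift(self):
        ref = np.linspace(80, 260, 10)
        stats = discrepancy_stats(ref + 1.8, ref)
        assert stats.mean == pytest.approx(1.8)
        assert stats.sd == pytest.approx(0.0)
        assert stats.median == pytest.approx(1.8)

    def test_injected_point_flagged_by_iqr_fences(self):
        rng = np.random.default_rng(1)
        ref = np.zeros(54)
        calc = rng.normal(0.0, 0.3, 54)
        calc[17] = 5.9
        stats = discrepancy_stats(calc, ref, labels=[f"pt{i}" for i in range(54)])
        # brute-force fences from sorted data
        d = np.sort(calc)
        q1 = np.percentile(d, 25)
        q3 = np.percentile(d, 75)
        expected = {f"pt{i}" for i, v in enumerate(calc)
                    if v < q1 - 1.5 * (q3 - q1) or v > q3 + 1.5 * (q3 - q1)}
        assert {label for _, label in stats.outliers} == expected
        assert any(label == "pt17" for _, label in stats.outliers)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            discrepancy_stats([1.0], [1.0, 2.0])

    def test_sd_uses_sample_denominator(self):
        diff = [0.0, 1.0, 2.0]
        stats = discrepancy_stats(diff, [0.0] * 3)
        assert stats.sd == pytest.approx(np.std(diff, ddof=1))


def optical_entry(base_lots, slope_ms, plan, truth_at=0.5):
    """Calibration entry whose per-event LOT is affine in tau with the given
    slope, and whose truth equals the reconstruction at ``truth_at``."""
    records = []
    truth = {}
    leaf = plan.active_leaves[0]
    d_open, d_close = 20.0, 20.0 - slope_ms
    for p, lot in enumerate(base_lots):
        start = p * plan.t_proj + 40.0
        records += [
            (start, leaf, "TRANSITION"),
            (start + d_open, leaf, "OPEN"),
            (start + d_open + lot, leaf, "TRANSITION"),
            (start + d_open + lot + d_close, leaf, "CLOSED"),
        ]
    log = OpticalEventLog.from_records(records)
    lots_tau = [lot + d_open + truth_at * (d_close - d_open) for lot in base_lots]
    truth[leaf] = float(np.mean(lots_tau))
    return CalibrationEntry(plan=plan, telemetry=log, truth=truth)


class TestCalibrateThreshold:
    def test_root_at_construction_threshold(self):
        plan = make_small_plan([150.0] * 4, t_proj=300.0, leaves=(12,))
        entry = optical_entry([110.0] * 4, slope_ms=-8.0, plan=plan, truth_at=0.5)
        result = calibrate_threshold("optical_sensor", [entry], np.arange(0.3, 0.71, 0.01))
        assert result.tau_star == pytest.approx(0.5, abs=1e-6)
        assert abs(result.discrepancy_at(result.tau_star)) < 0.05

    def test_tau_star_bracketed_by_sign_change(self):
        plan = make_small_plan([150.0] * 4, t_proj=300.0, leaves=(12,))
        entry = optical_entry([110.0] * 4, slope_ms=-8.0, plan=plan, truth_at=0.62)
        result = calibrate_threshold("optical_sensor", [entry], np.arange(0.3, 0.71, 0.01))
        curve = result.mean_discrepancy_curve
        i = np.searchsorted(result.tau_grid, result.tau_star) - 1
        assert curve[i] * curve[i + 1] <= 0

    def test_flat_curve_without_root_is_error(self):
        plan = make_small_plan([150.0] * 4, t_proj=300.0, leaves=(12,))
        entry = optical_entry([110.0] * 4, slope_ms=0.0, plan=plan, truth_at=0.5)
        entry.truth[12] += 5.0  # constant bias, no crossing
        with pytest.raises(CalibrationError, match="widen"):
            calibrate_threshold("optical_sensor", [entry], np.arange(0.3, 0.71, 0.01))

    def test_unknown_method_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate_threshold("gamma_index", [], [0.3, 0.4])


class TestValidateMethods:
    def test_perfect_agreement(self):
        ref = np.linspace(80, 260, 12)
        report = validate_methods({"optical_sensor": ref.copy()}, ref)
        v = report.per_method["optical_sensor"]
        assert v.pearson_r == pytest.approx(1.0)
        assert v.slope == pytest.approx(1.0)
        assert v.intercept == pytest.approx(0.0, abs=1e-9)
        assert v.decision == "degenerate"  # zero-variance pairing

    def test_t_statistic_matches_closed_form(self):
        calc = np.array([88.1, 174.9, 260.2, 89.0, 173.5])
        ref = np.array([87.5, 175.2, 261.0, 88.1, 174.0])
        report = validate_methods({"mv_detector": calc}, ref)
        d = calc - ref
        t_manual = d.mean() / (d.std(ddof=1) / math.sqrt(d.size))
        assert report.per_method["mv_detector"].t_statistic == pytest.approx(t_manual)

    def test_systematic_shift_is_detected(self):
        rng = np.random.default_rng(2)
        ref = np.linspace(80, 260, 30)
        calc = ref + 2.0 + rng.normal(0, 0.3, 30)
        report = validate_methods({"mv_detector": calc}, ref)
        v = report.per_method["mv_detector"]
        assert v.decision == "significant_difference"
        assert v.stats.mean == pytest.approx(2.0, abs=0.3)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            validate_methods({"mv_detector": [1.0, 2.0]}, [1.0, 2.0])


class TestFractionReport:
    def test_performed_equals_planned_has_zero_discrepancy(self):
        plan = make_small_plan([150.0] * 5, t_proj=300.0)
        sino = LOTSinogram(plan.plan_id, "optical_sensor", plan.planned_lot.copy(), 0.57)
        table = fraction_report([sino, sino], plan)
        assert len(table) == 2
        assert np.allclose(table["mean_discrepancy_ms"], 0.0)

    def test_short_lot_fractions_counted(self):
        plan = make_small_plan([150.0] * 10, t_proj=300.0, leaves=(20,))
        lot = np.zeros((64, 10))
        lot[19, :4] = 80.0
        lot[19, 4:] = 150.0
        sino = LOTSinogram(plan.plan_id, "mv_detector", lot, 0.42)
        row = fraction_report([sino], plan).iloc[0]
        assert row["pct_short"] == pytest.approx(40.0)
        assert row["pct_very_short"] == 0.0
        assert row["n_open"] == 10

    def test_shape_mismatch_raises(self):
        plan = make_small_plan([150.0] * 5, t_proj=300.0)
        sino = LOTSinogram("other", "mv_detector", np.zeros((64, 4)), 0.42)
        with pytest.raises(ValueError, match="does not match"):
            fraction_report([sino], plan)
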