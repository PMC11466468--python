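"""MV-detector preprocessing chain and width-at-threshold measurement."""

import numpy as np
import pytest

from tomolot import (
    LeafSignal,
    TraceValidationError,
    compute_lots_mv,
    preprocess_trace,
    richardson_lucy_1d,
    simulate_delivery,
    true_mean_lot,
    width_at_threshold,
)
from tomolot.mv import (
    DEFAULT_KERNEL,
    correct_arcs,
    detect_arc_samples,
    read_trace,
    widths_at_thresholds,
    write_trace,
)

from conftest import make_small_plan


def signal_from(values, dt=1.0, leaf=1):
    values = np.asarray(values, dtype=float)
    return LeafSignal(leaf=leaf, times=dt * np.arange(values.size), values=values)


class TestWidthAtThreshold:
    def test_symmetric_triangle_at_half_height(self):
        sig = signal_from([0, 0.5, 1, 0.5, 0])
        assert width_at_threshold(sig, (0, 4), 0.5) == pytest.approx(2.0)

    def test_trapezoid_crossings_by_linear_interpolation(self):
        # rises 0->1 over [0, 20] ms, flat to 100 ms, falls to 0 at 120 ms
        t = np.arange(0, 121.0)
        v = np.clip(np.minimum(t / 20.0, (120.0 - t) / 20.0), 0, 1)
        sig = LeafSignal(leaf=1, times=t, values=v)
        # tau = 0.42: crossings at 8.4 and 111.6 ms
        assert width_at_threshold(sig, (0, 120), 0.42) == pytest.approx(103.2)

    def test_all_zero_signal_has_zero_width(self):
        sig = signal_from(np.zeros(50))
        assert width_at_threshold(sig, (0, 49), 0.3) == 0.0

    def test_width_nonincreasing_in_tau_for_unimodal_pulse(self):
        rng = np.random.default_rng(3)
        up = np.sort(rng.uniform(0, 1, 20))
        pulse = np.concatenate([[0.0], up, up[::-1], [0.0]])
        sig = signal_from(pulse)
        taus = np.linspace(0.05, 0.95, 19)
        widths = [width_at_threshold(sig, (0, sig.times[-1]), t) for t in taus]
        assert np.all(np.diff(widths) <= 1e-12)

    def test_pulse_clipped_by_window_counts_to_boundary(self):
        sig = signal_from(np.ones(31))
        assert width_at_threshold(sig, (5.0, 25.0), 0.5) == pytest.approx(20.0)

    def test_invalid_threshold_rejected(self):
        sig = signal_from([0, 1, 0])
        with pytest.raises(TraceValidationError):
            width_at_threshold(sig, (0, 2), 1.5)

    def test_window_outside_support_is_error(self):
        sig = signal_from([0, 1, 0])
        with pytest.raises(TraceValidationError, match="outside signal support"):
            width_at_threshold(sig, (-5, 2), 0.5)


class TestRichardsonLucy:
    def test_flux_conserved_for_interior_supported_rows(self):
        rng = np.random.default_rng(11)
        data = np.zeros((40, 64))
        data[:, 5:59] = rng.uniform(0, 2, (40, 54))
        blurred = np.apply_along_axis(np.convolve, 1, data, DEFAULT_KERNEL, "same")
        restored = richardson_lucy_1d(blurred, DEFAULT_KERNEL, iterations=10, axis=1)
        np.testing.assert_allclose(
            restored.sum(axis=1), blurred.sum(axis=1), rtol=1e-6
        )

    def test_forward_convolved_box_is_recovered(self):
        # a single open leaf blurred by the cross-talk kernel
        box = np.zeros((30, 64))
        box[5:25, 29] = 1.0
        blurred = np.apply_along_axis(np.convolve, 1, box, DEFAULT_KERNEL, "same")
        restored = richardson_lucy_1d(blurred, DEFAULT_KERNEL, iterations=50, axis=1)
        peak = restored[15, 29]
        assert peak == pytest.approx(1.0, abs=0.05)
        assert restored[15, 28] < 0.05 and restored[15, 30] < 0.05

    def test_zero_mass_kernel_rejected(self):
        with pytest.raises(TraceValidationError):
            richardson_lucy_1d(np.ones((3, 8)), np.zeros(3))

    def test_agrees_with_independent_implementation(self):
        # same fixed point as scikit-image's Richardson-Lucy (different
        # initialization, so compare after enough iterations to converge)
        from skimage.restoration import richardson_lucy as sk_rl

        rng = np.random.default_rng(0)
        row = np.zeros(64)
        row[20:40] = rng.uniform(0.5, 1.5, 20)
        blurred = np.convolve(row, DEFAULT_KERNEL, mode="same")
        mine = richardson_lucy_1d(blurred[None, :], DEFAULT_KERNEL, iterations=200, axis=1)[0]
        theirs = sk_rl(blurred, DEFAULT_KERNEL, num_iter=200, clip=False)
        np.testing.assert_allclose(mine, theirs, atol=1e-9)


class TestArcCorrection:
    def test_single_sample_spike_is_flagged_and_interpolated(self, small_plan, quiet_model):
        d = simulate_delivery(small_plan, quiet_model, seed=5)
        clean = d.trace.samples.astype(float)
        dirty = clean.copy()
        dirty[100, :] += 20.0
        flags = detect_arc_samples(dirty)
        assert flags[100] and flags.sum() == 1
        fixed = correct_arcs(dirty, flags)
        np.testing.assert_allclose(fixed[100], 0.5 * (clean[99] + clean[101]), atol=1e-5)

    def test_clean_trace_has_no_flags(self, small_plan, quiet_model):
        d = simulate_delivery(small_plan, quiet_model, seed=5)
        assert not detect_arc_samples(d.trace.samples).any()


class TestPreprocess:
    def test_constant_offset_trace_yields_zero_signals(self, quiet_model):
        plan = make_small_plan([0.0] * 6)
        d = simulate_delivery(plan, quiet_model, seed=1)
        signals = preprocess_trace(d.trace, plan=plan)
        for sig in signals:
            assert np.allclose(sig.values, 0.0, atol=1e-6)

    def test_opening_leaf_normalized_to_unit_central_max(self, small_plan, quiet_model):
        d = simulate_delivery(small_plan, quiet_model, seed=2)
        signals = preprocess_trace(d.trace, plan=small_plan)
        sig = signals[26]
        for w0, w1 in small_plan.projection_windows:
            mid, half = 0.5 * (w0 + w1), 0.25 * (w1 - w0)
            central = (sig.times >= mid - half) & (sig.times <= mid + half)
            assert sig.values[central].max() == pytest.approx(1.0)


class TestComputeLots:
    def test_exact_model_recovers_truth(self, exact_model):
        plan = make_small_plan([174.0] * 6)
        d = simulate_delivery(plan, exact_model, seed=0)
        sino = compute_lots_mv(d.trace, plan, 0.5)
        for leaf in (27, 39, 47):
            np.testing.assert_allclose(
                sino.lot[leaf - 1], d.truth.lot[leaf - 1], atol=1e-6
            )

    def test_inactive_leaves_are_zero(self, small_plan, quiet_model):
        d = simulate_delivery(small_plan, quiet_model, seed=4)
        sino = compute_lots_mv(d.trace, small_plan, 0.42)
        inactive = [i for i in range(64) if (i + 1) not in (27, 39, 47)]
        assert not sino.lot[inactive].any()

    def test_higher_threshold_gives_nested_smaller_widths(self, small_plan, quiet_model):
        d = simulate_delivery(small_plan, quiet_model, seed=4)
        signals = preprocess_trace(d.trace, plan=small_plan)
        w = widths_at_thresholds(signals[26], small_plan.projection_windows, [0.3, 0.5, 0.7])
        assert np.all(np.diff(w, axis=1) < 0)

    def test_sinogram_records_method_and_threshold(self, small_plan, quiet_model):
        d = simulate_delivery(small_plan, quiet_model, seed=4)
        sino = compute_lots_mv(d.trace, small_plan, 0.42)
        assert sino.method == "mv_detector"
        assert sino.threshold == 0.42


class TestTraceValidation:
    def test_non_monotone_leaf_channel_map_rejected(self, small_plan, quiet_model):
        from tomolot import MVDetectorTrace

        d = simulate_delivery(small_plan, quiet_model, seed=1)
        bad_map = d.trace.leaf_channel_map.copy()
        bad_map[10] = bad_map[9]
        with pytest.raises(TraceValidationError, match="increasing"):
            MVDetectorTrace(
                sample_rate=d.trace.sample_rate,
                times=d.trace.times,
                samples=d.trace.samples,
                projection_windows=d.trace.projection_windows,
                leaf_channel_map=bad_map,
            )

    def test_overlapping_projection_windows_rejected(self, small_plan, quiet_model):
        from tomolot import MVDetectorTrace

        d = simulate_delivery(small_plan, quiet_model, seed=1)
        bad = d.trace.projection_windows.copy()
        bad[1, 0] = bad[0, 0]  # second window starts before the first ends
        with pytest.raises(TraceValidationError, match="non-overlapping"):
            MVDetectorTrace(
                sample_rate=d.trace.sample_rate,
                times=d.trace.times,
                samples=d.trace.samples,
                projection_windows=bad,
                leaf_channel_map=d.trace.leaf_channel_map,
            )


def test_trace_bundle_round_trip(tmp_path, quiet_model):
    plan = make_small_plan([100.0] * 2, t_proj=200.0)
    d = simulate_delivery(plan, quiet_model, seed=9)
    write_trace(d.trace, tmp_path / "trace")
    loaded = read_trace(tmp_path / "trace")
    assert loaded.sample_rate == d.trace.sample_rate
    np.testing.assert_allclose(loaded.times, d.trace.times, atol=1e-9)
    np.testing.assert_allclose(loaded.samples, d.trace.samples, rtol=1e-4, atol=1e-6)
    np.testing.assert_allclose(loaded.projection_windows, d.trace.projection_windows)
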