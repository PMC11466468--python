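"""LOT reconstruction from the exit MV-detector trace.

The MV detector is a 640-channel ionization-chamber array mounted opposite the
linac, sampling the exit fluence at 300 Hz.  Reconstruction proceeds in five
preprocessing steps — arc-artifact correction, per-leaf channel interpolation,
offset subtraction, Richardson–Lucy deconvolution across the leaf axis, and
per-projection normalization — followed by measuring the width of each leaf's
per-projection pulse at a fractional threshold tau_mv, with sub-sample
crossing times located by linear interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import convolve1d

from .plans import N_LEAVES, DeliveryPlan, LOTSinogram

N_CHANNELS = 640
DEFAULT_SAMPLE_RATE_HZ = 300.0
#: default inter-leaf cross-talk point-spread function (leaf axis)
DEFAULT_KERNEL = np.array([0.1, 0.8, 0.1])
DEFAULT_RL_ITERATIONS = 10
#: fraction of the projection window (centred) searched for the normalization max
CENTRAL_WINDOW_FRACTION = 0.5
#: a projection whose central max falls below this fraction of the delivery-wide
#: leaf-signal max is treated as closed (avoids normalizing pure noise to 1)
NORMALIZATION_FLOOR_REL = 0.2


class TraceValidationError(ValueError):
    """Raised for malformed MV traces or invalid preprocessing configuration."""


def default_leaf_channel_map() -> np.ndarray:
    """Fractional detector-channel coordinate of each leaf centre (64,)."""
    return 5.0 + 10.0 * np.arange(N_LEAVES)


@dataclass
class MVDetectorTrace:
    """Time x channel exit-fluence samples with projection bookkeeping."""

    sample_rate: float  # Hz
    times: np.ndarray  # (T,) ms
    samples: np.ndarray  # (T, 640) fluence a.u.
    projection_windows: np.ndarray  # (P, 2) ms
    leaf_channel_map: np.ndarray = field(default_factory=default_leaf_channel_map)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.samples = np.asarray(self.samples)
        self.projection_windows = np.asarray(self.projection_windows, dtype=float)
        self.leaf_channel_map = np.asarray(self.leaf_channel_map, dtype=float)
        if self.samples.shape != (self.times.size, N_CHANNELS):
            raise TraceValidationError(
                f"samples shape {self.samples.shape} must be (n_times, {N_CHANNELS})"
            )
        dt = np.diff(self.times)
        nominal = 1000.0 / self.sample_rate
        if dt.size and not np.allclose(dt, nominal, atol=1e-6 * nominal):
            raise TraceValidationError("sample spacing is not uniform at 1/sample_rate")
        if np.any(np.diff(self.leaf_channel_map) <= 0):
            raise TraceValidationError("leaf_channel_map must be strictly increasing")
        w = self.projection_windows
        if w.ndim != 2 or w.shape[1] != 2:
            raise TraceValidationError("projection_windows must have shape (P, 2)")
        if np.any(w[:, 1] <= w[:, 0]) or np.any(w[1:, 0] < w[:-1, 1] - 1e-9):
            raise TraceValidationError("projection windows must be ordered, non-overlapping")


@dataclass
class LeafSignal:
    """Per-leaf normalized fluence amplitude over time (target range ~[0, 1])."""

    leaf: int  # 1-based
    times: np.ndarray  # (T,) ms
    values: np.ndarray  # (T,)

    def __post_init__(self) -> None:
        if self.times.shape != self.values.shape:
            raise TraceValidationError("times and values must have equal length")


# ---------------------------------------------------------------------------
# preprocessing steps
# ---------------------------------------------------------------------------

def detect_arc_samples(samples: np.ndarray, n_sigma: float = 5.0) -> np.ndarray:
    """Flag time samples hit by electrical arcing.

    A sample is flagged when its all-channel median jumps by more than
    ``n_sigma`` robust standard deviations relative to *both* temporal
    neighbours — arcing is a single-sample, all-channel transient.
    """
    med = np.median(samples, axis=1)
    if med.size < 3:
        return np.zeros(med.size, dtype=bool)
    diff = np.diff(med)
    mad = np.median(np.abs(diff - np.median(diff)))
    sigma = 1.4826 * mad
    sigma = max(sigma, 1e-12)
    jump_prev = np.abs(med[1:-1] - med[:-2]) > n_sigma * sigma
    jump_next = np.abs(med[1:-1] - med[2:]) > n_sigma * sigma
    flags = np.zeros(med.size, dtype=bool)
    flags[1:-1] = jump_prev & jump_next
    return flags


def correct_arcs(samples: np.ndarray, flags: np.ndarray) -> np.ndarray:
    """Replace flagged samples by per-channel linear temporal interpolation."""
    if not flags.any():
        return samples
    out = samples.copy()
    good = np.flatnonzero(~flags)
    bad = np.flatnonzero(flags)
    for ch in range(out.shape[1]):
        out[bad, ch] = np.interp(bad, good, out[good, ch])
    return out


def extract_leaf_signals(samples: np.ndarray, leaf_channel_map: np.ndarray) -> np.ndarray:
    """Linear interpolation of the channel axis at each leaf's coordinate.

    Returns a (T, 64) array.
    """
    i0 = np.clip(np.floor(leaf_channel_map).astype(int), 0, N_CHANNELS - 2)
    frac = leaf_channel_map - i0
    return samples[:, i0] * (1.0 - frac) + samples[:, i0 + 1] * frac


def estimate_offsets(
    leaf_vals: np.ndarray,
    times: np.ndarray,
    windows: np.ndarray,
    plan: Optional[DeliveryPlan],
) -> np.ndarray:
    """Per-leaf baseline from MLC leakage and detector dark current.

    Uses the 5th percentile over samples inside projections where the plan
    commands the leaf closed for the full projection; a low quantile rather
    than the mean, because a closed leaf's channel still sees cross-talk from
    open neighbours and that contamination must not enter the baseline.
    Leaves without any closed projection (or without a plan) fall back to the
    5th percentile of their whole trace.
    """
    offsets = np.percentile(leaf_vals, 5, axis=0)
    if plan is None:
        return offsets
    # projection index of every sample (-1 outside any window)
    proj = np.searchsorted(windows[:, 0], times, side="right") - 1
    inside = (proj >= 0) & (times < windows[np.clip(proj, 0, len(windows) - 1), 1])
    proj = np.where(inside, proj, -1)
    for leaf in range(N_LEAVES):
        closed = plan.planned_lot[leaf] == 0
        if not closed.any():
            continue
        mask = (proj >= 0) & closed[np.clip(proj, 0, len(windows) - 1)]
        if mask.any():
            offsets[leaf] = np.percentile(leaf_vals[mask, leaf], 5)
    return offsets


def richardson_lucy_1d(
    data: np.ndarray,
    kernel: np.ndarray,
    iterations: int = DEFAULT_RL_ITERATIONS,
    axis: int = -1,
) -> np.ndarray:
    """Richardson–Lucy deconvolution along one axis.

    ``data`` must be non-negative; ``kernel`` non-negative with unit mass.
    The iteration preserves the flux (sum along ``axis``) of interior-supported
    signals because the kernel is normalized.
    """
    kernel = np.asarray(kernel, dtype=float)
    if np.any(kernel < 0) or kernel.sum() <= 0:
        raise TraceValidationError("kernel must be non-negative with positive mass")
    if iterations < 1:
        raise TraceValidationError("iterations must be >= 1")
    kernel = kernel / kernel.sum()
    mirrored = kernel[::-1]
    estimate = np.clip(data, 0, None).astype(float)
    data = estimate.copy()
    eps = 1e-12
    for _ in range(iterations):
        blurred = convolve1d(estimate, kernel, axis=axis, mode="constant", cval=0.0)
        ratio = np.where(blurred > eps, data / np.where(blurred > eps, blurred, 1.0), 0.0)
        estimate = estimate * convolve1d(ratio, mirrored, axis=axis, mode="constant", cval=0.0)
    return estimate


def normalize_per_projection(
    leaf_vals: np.ndarray,
    times: np.ndarray,
    windows: np.ndarray,
    central_fraction: float = CENTRAL_WINDOW_FRACTION,
    floor_rel: float = NORMALIZATION_FLOOR_REL,
) -> np.ndarray:
    """Scale each leaf's samples so the per-projection central max is 1.

    The maximum is taken over the centred ``central_fraction`` of each
    projection window, excluding the opening/closing transitions.  Projections
    whose central max is below ``floor_rel`` times the delivery-wide maximum
    are treated as closed and zeroed: a closed leaf's residual noise must not
    be blown up to unit amplitude.
    """
    out = np.zeros_like(leaf_vals)
    global_max = leaf_vals.max() if leaf_vals.size else 0.0
    floor = floor_rel * global_max
    for w0, w1 in windows:
        mask = (times >= w0) & (times < w1)
        if not mask.any():
            raise TraceValidationError(f"projection window [{w0}, {w1}) contains no samples")
        half = 0.5 * central_fraction * (w1 - w0)
        mid = 0.5 * (w0 + w1)
        central = mask & (times >= mid - half) & (times <= mid + half)
        seg = leaf_vals[mask]
        peaks = leaf_vals[central].max(axis=0)
        scale = np.where(peaks > max(floor, 1e-12), peaks, np.inf)
        out[mask] = seg / scale
    return out


def preprocess_trace(
    trace: MVDetectorTrace,
    kernel: Sequence[float] = DEFAULT_KERNEL,
    iterations: int = DEFAULT_RL_ITERATIONS,
    plan: Optional[DeliveryPlan] = None,
) -> list[LeafSignal]:
    """Run the five-step preprocessing chain and return 64 normalized signals.

    Steps, in order: (1) arc correction, (2) per-leaf extraction from the
    channel axis, (3) offset subtraction clipped at zero, (4) Richardson–Lucy
    deconvolution across the leaf axis, (5) per-leaf, per-projection
    normalization by the central-window maximum.
    """
    flags = detect_arc_samples(trace.samples)
    samples = correct_arcs(trace.samples, flags)
    leaf_vals = extract_leaf_signals(samples, trace.leaf_channel_map).astype(float)
    offsets = estimate_offsets(leaf_vals, trace.times, trace.projection_windows, plan)
    leaf_vals = np.clip(leaf_vals - offsets, 0.0, None)
    leaf_vals = richardson_lucy_1d(leaf_vals, np.asarray(kernel, float), iterations, axis=1)
    leaf_vals = normalize_per_projection(leaf_vals, trace.times, trace.projection_windows)
    return [
        LeafSignal(leaf=leaf + 1, times=trace.times, values=leaf_vals[:, leaf])
        for leaf in range(N_LEAVES)
    ]


# ---------------------------------------------------------------------------
# width at threshold
# ---------------------------------------------------------------------------

def _window_samples(signal: LeafSignal, window: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Samples inside the window, with values interpolated onto its ends.

    Extending to the exact window boundaries makes boundary-clipped pulses
    (a leaf open across consecutive projections) contribute width up to the
    boundary rather than to the nearest interior sample.
    """
    w0, w1 = float(window[0]), float(window[1])
    t, v = signal.times, signal.values
    if w0 < t[0] - 1e-9 or w1 > t[-1] + 1e-9:
        raise TraceValidationError(f"window [{w0}, {w1}] outside signal support")
    mask = (t >= w0) & (t <= w1)
    tw, vw = t[mask], v[mask]
    if tw.size == 0 or tw[0] > w0 + 1e-9:
        tw = np.concatenate([[w0], tw])
        vw = np.concatenate([[np.interp(w0, t, v)], vw])
    if tw[-1] < w1 - 1e-9:
        tw = np.concatenate([tw, [w1]])
        vw = np.concatenate([vw, [np.interp(w1, t, v)]])
    return tw, vw


def _crossing_times(tw: np.ndarray, vw: np.ndarray, tau: float) -> Optional[tuple[float, float]]:
    above = vw >= tau
    if not above.any():
        return None
    first = int(np.argmax(above))
    last = len(above) - 1 - int(np.argmax(above[::-1]))
    if first == 0:
        t_rise = tw[0]
    else:
        v0, v1 = vw[first - 1], vw[first]
        t_rise = tw[first - 1] + (tau - v0) / (v1 - v0) * (tw[first] - tw[first - 1])
    if last == len(above) - 1:
        t_fall = tw[-1]
    else:
        v0, v1 = vw[last], vw[last + 1]
        t_fall = tw[last] + (v0 - tau) / (v0 - v1) * (tw[last + 1] - tw[last])
    return t_rise, t_fall


def width_at_threshold(signal: LeafSignal, window: Sequence[float], tau_mv: float) -> float:
    """Width in ms of the signal segment at height ``tau_mv`` inside ``window``.

    The width spans from the first upward to the last downward crossing of the
    level, located by linear interpolation between adjacent samples; 0 if the
    signal never reaches the threshold in the window.
    """
    if not 0 < tau_mv < 1:
        raise TraceValidationError(f"tau_mv must be in (0, 1), got {tau_mv}")
    tw, vw = _window_samples(signal, window)
    crossing = _crossing_times(tw, vw, tau_mv)
    if crossing is None:
        return 0.0
    t_rise, t_fall = crossing
    return float(t_fall - t_rise)


def widths_at_thresholds(
    signal: LeafSignal, windows: np.ndarray, taus: Sequence[float]
) -> np.ndarray:
    """Vectorized widths: (n_projections, n_taus) array for one leaf."""
    taus = np.asarray(taus, dtype=float)
    out = np.zeros((len(windows), taus.size))
    for p, window in enumerate(windows):
        tw, vw = _window_samples(signal, window)
        for k, tau in enumerate(taus):
            crossing = _crossing_times(tw, vw, float(tau))
            if crossing is not None:
                out[p, k] = crossing[1] - crossing[0]
    return out


def write_trace(trace: MVDetectorTrace, directory: str | Path) -> None:
    """Write a trace as a directory bundle of JSON metadata and CSV matrices.

    Intended for archiving and for small fixtures; a full clinical trace is
    large in text form.
    """
    import json

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "sample_rate_hz": trace.sample_rate,
        "t0_ms": float(trace.times[0]),
        "n_samples": int(trace.times.size),
        "leaf_channel_map": [float(c) for c in trace.leaf_channel_map],
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=1))
    np.savetxt(directory / "samples.csv", trace.samples, fmt="%.6g", delimiter=",")
    np.savetxt(directory / "projection_windows.csv", trace.projection_windows,
               fmt="%.6f", delimiter=",")


def read_trace(directory: str | Path) -> MVDetectorTrace:
    import json

    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    samples = np.atleast_2d(np.loadtxt(directory / "samples.csv", delimiter=","))
    windows = np.atleast_2d(np.loadtxt(directory / "projection_windows.csv", delimiter=","))
    times = meta["t0_ms"] + 1000.0 / meta["sample_rate_hz"] * np.arange(meta["n_samples"])
    return MVDetectorTrace(
        sample_rate=meta["sample_rate_hz"],
        times=times,
        samples=samples,
        projection_windows=windows,
        leaf_channel_map=np.asarray(meta["leaf_channel_map"], dtype=float),
    )


def compute_lots_mv(
    trace: MVDetectorTrace,
    plan: DeliveryPlan,
    tau_mv: float,
    kernel: Sequence[float] = DEFAULT_KERNEL,
    iterations: int = DEFAULT_RL_ITERATIONS,
    signals: Optional[list[LeafSignal]] = None,
) -> LOTSinogram:
    """Reconstruct the full LOT sinogram from an MV trace.

    ``signals`` may carry the output of :func:`preprocess_trace` to avoid
    repeating the preprocessing when sweeping thresholds.
    """
    if signals is None:
        signals = preprocess_trace(trace, kernel=kernel, iterations=iterations, plan=plan)
    windows = trace.projection_windows
    lot = np.zeros((N_LEAVES, len(windows)))
    for leaf_idx, signal in enumerate(signals):
        if not signal.values.any():
            continue
        lot[leaf_idx] = widths_at_thresholds(signal, windows, [tau_mv])[:, 0]
    return LOTSinogram(plan_id=plan.plan_id, method="mv_detector", threshold=tau_mv, lot=lot)
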