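"""Synthetic delivery simulator with known ground-truth LOTs.

Generates, from a planned sinogram and a parametric leaf-motion model, the
three telemetry streams the reconstruction modules consume — an MV-detector
trace, an optical sensor event log, and ionization-chamber charges — all
derived from one per-leaf transmission trajectory so they are mutually
consistent by construction.

The ground-truth LOT of a cell is the *fluence-equivalent* open time: the
time integral of the leaf's beam transmission within the projection.  This is
exactly the quantity an ionization chamber on the beamlet path measures (its
charge is proportional to the integrated fluence), so the charge-ratio
conversion is exact on noiseless simulations and both reconstruction methods
are calibrated to the same physical quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import convolve1d

from .chamber import ChamberChargeSet
from .mv import (
    DEFAULT_KERNEL,
    DEFAULT_SAMPLE_RATE_HZ,
    N_CHANNELS,
    MVDetectorTrace,
    default_leaf_channel_map,
)
from .optical import DEFAULT_RESOLUTION_MS, OpticalEventLog
from .plans import N_LEAVES, DeliveryPlan, LOTSinogram, make_reference_plans

#: transmission vs. leaf-travel fraction, as piecewise-linear node tables;
#: "penumbra" (the default) emulates the threshold asymmetry seen on real units.
# T(x) = x - 0.14 sin^2(pi x) + 0.03913 sin(2 pi x), tabulated densely: a
# smooth asymmetric S-curve with mean exactly 0.43, so the fluence-equivalent
# instant falls at travel fraction 0.57 of an opening transition and
# T(0.57) = 0.42 is the threshold at which the MV width equals the fluence LOT
_PENUMBRA_X = np.linspace(0.0, 1.0, 201)
_PENUMBRA_T = (
    _PENUMBRA_X
    - 0.14 * np.sin(np.pi * _PENUMBRA_X) ** 2
    + 0.03913 * np.sin(2 * np.pi * _PENUMBRA_X)
)
_COS_X = np.linspace(0.0, 1.0, 81)
FLUENCE_RAMPS = {
    "linear": (np.array([0.0, 1.0]), np.array([0.0, 1.0])),
    "cosine": (_COS_X, 0.5 * (1.0 - np.cos(np.pi * _COS_X))),
    "penumbra": (_PENUMBRA_X, _PENUMBRA_T),
}


class SimulationError(ValueError):
    """Raised for invalid motion-model configuration."""


@dataclass
class LeafMotionModel:
    """Parametric model of binary-leaf motion and telemetry imperfections.

    Timing parameters are in ms.  ``lot_shift`` is the systematic
    executed-minus-planned fluence LOT offset (the +1.8 ms default emulates
    the offset observed between delivered and planned LOTs on real units).
    ``sensor_open_fraction`` / ``sensor_close_fraction`` give the fraction of
    a transition's travel completed when the photodiode pair switches into
    the new state; the sensor leaves its parked state as soon as motion
    starts.  The optical method's true threshold is (1 - mu)/g_open on the
    opening edge and mu/g_close on the closing edge, where mu is the ramp's
    mean transmission; the defaults make both 0.57.  The default penumbra
    ramp puts the MV method's true threshold at T(1 - mu) = 0.42.
    """

    open_transition: float = 24.0
    close_transition: float = 16.0
    latency: float = 20.0
    lot_shift: float = 1.8
    jitter_sd: float = 1.0
    sensor_open_fraction: float = 1.0
    sensor_close_fraction: float = 0.7544
    fluence_ramp: str = "penumbra"
    crosstalk_kernel: np.ndarray = field(default_factory=lambda: DEFAULT_KERNEL.copy())
    mv_noise_sd: float = 0.01
    offset_level: float = 0.06
    arcing_rate: float = 0.05  # events per second
    charge_noise_rel: float = 0.001
    min_close_time: float = 50.0
    optical_resolution: float = DEFAULT_RESOLUTION_MS  # 0 disables quantization
    seed: int = 42

    def __post_init__(self) -> None:
        if self.open_transition < 0 or self.close_transition < 0:
            raise SimulationError("transition durations must be >= 0")
        for name in ("sensor_open_fraction", "sensor_close_fraction"):
            if not 0 < getattr(self, name) <= 1:
                raise SimulationError(f"{name} must be in (0, 1]")
        if self.fluence_ramp not in FLUENCE_RAMPS:
            raise SimulationError(
                f"fluence_ramp must be one of {sorted(FLUENCE_RAMPS)}, got {self.fluence_ramp!r}"
            )
        kernel = np.asarray(self.crosstalk_kernel, dtype=float)
        if np.any(kernel < 0) or kernel.sum() <= 0:
            raise SimulationError("crosstalk kernel must be non-negative with positive mass")
        self.crosstalk_kernel = kernel / kernel.sum()

    @property
    def ramp_nodes(self) -> tuple[np.ndarray, np.ndarray]:
        return FLUENCE_RAMPS[self.fluence_ramp]

    @property
    def ramp_mean(self) -> float:
        """Mean transmission over a transition (trapezoid-exact)."""
        x, t = self.ramp_nodes
        return float(np.trapezoid(t, x))

    @property
    def optical_equivalent_threshold(self) -> float:
        """tau at which the optical method recovers the fluence LOT exactly."""
        mu = self.ramp_mean
        tau_open = (1.0 - mu) / self.sensor_open_fraction
        tau_close = mu / self.sensor_close_fraction
        return 0.5 * (tau_open + tau_close)

    @property
    def mv_equivalent_threshold(self) -> float:
        """tau at which the MV width equals the fluence LOT: T(1 - ramp mean)."""
        x, t = self.ramp_nodes
        return float(np.interp(1.0 - self.ramp_mean, x, t))


@dataclass
class SyntheticDelivery:
    """All telemetry of one simulated delivery, plus the fluence ground truth."""

    plan: DeliveryPlan
    model: LeafMotionModel
    truth: LOTSinogram  # fluence-equivalent LOT per cell, method="planned"
    trace: MVDetectorTrace
    log: OpticalEventLog
    charges: ChamberChargeSet
    replicate: int = 1


# ---------------------------------------------------------------------------
# trajectory construction
# ---------------------------------------------------------------------------

def _commanded_intervals(plan: DeliveryPlan, leaf: int) -> list[tuple[float, float]]:
    """Commanded open intervals (ms) of a 1-based leaf, centred per projection
    and coalesced across touching projections (x = 100%)."""
    row = plan.planned_lot[leaf - 1]
    windows = plan.projection_windows
    intervals: list[tuple[float, float]] = []
    for p, lot in enumerate(row):
        if lot <= 0:
            continue
        w0, w1 = windows[p]
        start = w0 + 0.5 * (plan.t_proj - lot)
        end = start + lot
        if intervals and start - intervals[-1][1] <= 1e-9:
            intervals[-1] = (intervals[-1][0], end)
        else:
            intervals.append((start, end))
    return intervals


@dataclass
class _Breakpoints:
    """Piecewise-linear leaf travel x(t) plus sensor state-change records."""

    t: np.ndarray
    x: np.ndarray
    records: list[tuple[float, str]]


def _build_trajectory(
    intervals: Sequence[tuple[float, float]], model: LeafMotionModel, rng: np.random.Generator
) -> _Breakpoints:
    d_o, d_c = model.open_transition, model.close_transition
    mu = model.ramp_mean
    g_o, g_c = model.sensor_open_fraction, model.sensor_close_fraction
    # executed fluence-equivalent boundaries per commanded interval
    bounds = []
    for c0, c1 in intervals:
        j1 = rng.normal(0.0, model.jitter_sd) if model.jitter_sd > 0 else 0.0
        j2 = rng.normal(0.0, model.jitter_sd) if model.jitter_sd > 0 else 0.0
        b1 = c0 + model.latency - 0.5 * model.lot_shift + j1
        b2 = c1 + model.latency + 0.5 * model.lot_shift + j2
        bounds.append((b1, max(b2, b1 + 1e-6), c0, c1))

    pts_t: list[float] = []
    pts_x: list[float] = []
    records: list[tuple[float, str]] = []

    def add(t: float, x: float) -> None:
        if pts_t and t <= pts_t[-1] + 1e-9:
            t = pts_t[-1] + 1e-9
        pts_t.append(t)
        pts_x.append(x)

    n = len(bounds)
    prev_merged = False
    for k, (b1, b2, c0, c1) in enumerate(bounds):
        o_start = b1 - (1.0 - mu) * d_o
        o_end = o_start + d_o
        c_start = b2 - mu * d_c
        c_end = c_start + d_c
        # decide closing mode towards the next event
        if k + 1 < n:
            b1_next = bounds[k + 1][0]
            gap_cmd = bounds[k + 1][2] - c1
            next_o_end = b1_next + mu * d_o
            dip_span = next_o_end - c_start
            merged_next = gap_cmd < model.min_close_time or dip_span < d_o + d_c
        else:
            merged_next = False

        if c_start < o_end and not (prev_merged or merged_next):
            # isolated event too short to open fully: partial peak
            t_peak = (d_c * o_start + d_o * c_end) / (d_o + d_c)
            x_peak = (t_peak - o_start) / d_o
            if x_peak <= 0:
                prev_merged = False
                continue
            add(o_start, 0.0)
            add(t_peak, x_peak)
            add(c_end, 0.0)
            records.append((o_start, "TRANSITION"))
            if x_peak >= g_o:
                records.append((o_start + g_o * d_o, "OPEN"))
                records.append((t_peak, "TRANSITION"))
                records.append((t_peak + g_c * x_peak * d_c, "CLOSED"))
            else:
                records.append((c_end, "CLOSED"))
            prev_merged = False
            continue

        c_start = max(c_start, o_end)  # clamp degenerate plateaus inside merged chains
        if not prev_merged:
            add(o_start, 0.0)
            add(o_end, 1.0)
            records.append((o_start, "TRANSITION"))
            records.append((o_start + g_o * d_o, "OPEN"))

        if merged_next:
            # partial close: dip to x_min, then re-open; sensor stays TRANSITION
            b1_next = bounds[k + 1][0]
            next_o_end = b1_next + mu * d_o
            dip_span = next_o_end - c_start
            depth = min(dip_span / (d_o + d_c), 0.98)
            t_turn = c_start + depth * d_c
            t_back = next_o_end
            add(c_start, 1.0)
            add(t_turn, 1.0 - depth)
            if t_back - t_turn > depth * d_o + 1e-9:
                # room to spare: hover near x_min before rising
                add(t_back - depth * d_o, 1.0 - depth)
            add(t_back, 1.0)
            records.append((c_start, "TRANSITION"))
            records.append((t_back, "OPEN"))
            prev_merged = True
        else:
            add(c_start, 1.0)
            add(c_end, 0.0)
            records.append((c_start, "TRANSITION"))
            records.append((c_start + g_c * d_c, "CLOSED"))
            prev_merged = False

    return _Breakpoints(t=np.array(pts_t), x=np.array(pts_x), records=records)


# ---------------------------------------------------------------------------
# exact fluence integration
# ---------------------------------------------------------------------------

def _ramp_antiderivative(nodes_x: np.ndarray, nodes_t: np.ndarray) -> Callable[[np.ndarray], np.ndarray]:
    """Antiderivative Phi of the piecewise-linear transmission T(x)."""
    cum = np.concatenate([[0.0], np.cumsum(np.diff(nodes_x) * 0.5 * (nodes_t[1:] + nodes_t[:-1]))])
    slopes = np.diff(nodes_t) / np.diff(nodes_x)

    def phi(x: float) -> float:
        x = min(max(x, nodes_x[0]), nodes_x[-1])
        i = min(max(int(np.searchsorted(nodes_x, x, side="right")) - 1, 0), len(slopes) - 1)
        dx = x - nodes_x[i]
        return float(cum[i] + nodes_t[i] * dx + 0.5 * slopes[i] * dx * dx)

    return phi


class TrajectoryIntegrator:
    """Exact cumulative fluence of one leaf trajectory.

    Precomputes the prefix integral of T(x(t)) at every breakpoint so the
    integral over an arbitrary interval costs O(log n).
    """

    def __init__(self, bp: _Breakpoints, model: LeafMotionModel) -> None:
        nodes_x, nodes_t = model.ramp_nodes
        self._phi = _ramp_antiderivative(nodes_x, nodes_t)
        self._nodes = (nodes_x, nodes_t)
        self.t, self.x = bp.t, bp.x
        if self.t.size:
            seg = np.array(
                [self._segment_integral(i, self.t[i], self.t[i + 1]) for i in range(self.t.size - 1)]
            )
            self._prefix = np.concatenate([[0.0], np.cumsum(seg)])
        else:
            self._prefix = np.zeros(1)

    def _segment_integral(self, i: int, lo: float, hi: float) -> float:
        ta, tb = self.t[i], self.t[i + 1]
        if hi <= lo or tb <= ta:
            return 0.0
        xa = self.x[i] + (self.x[i + 1] - self.x[i]) * (lo - ta) / (tb - ta)
        xb = self.x[i] + (self.x[i + 1] - self.x[i]) * (hi - ta) / (tb - ta)
        nodes_x, nodes_t = self._nodes
        if abs(xb - xa) < 1e-15:
            return float(np.interp(xa, nodes_x, nodes_t)) * (hi - lo)
        return (hi - lo) * (self._phi(xb) - self._phi(xa)) / (xb - xa)

    def cumulative(self, t: float) -> float:
        """Integral of T(x(s)) ds from the trajectory start to time t."""
        if self.t.size == 0 or t <= self.t[0]:
            return 0.0
        if t >= self.t[-1]:
            return float(self._prefix[-1])
        i = int(np.searchsorted(self.t, t, side="right")) - 1
        return float(self._prefix[i]) + self._segment_integral(i, self.t[i], t)

    def integral(self, a: float, b: float) -> float:
        return self.cumulative(b) - self.cumulative(a) if b > a else 0.0

    @property
    def total(self) -> float:
        return float(self._prefix[-1])


def transmission_integral(
    bp: _Breakpoints, model: LeafMotionModel, a: float, b: float
) -> float:
    """Exact integral of T(x(t)) dt over [a, b] (ms of fluence-equivalent time)."""
    return TrajectoryIntegrator(bp, model).integral(a, b)


# ---------------------------------------------------------------------------
# delivery simulation
# ---------------------------------------------------------------------------

def _quantize_records(
    records: list[tuple[float, str]], resolution: float
) -> list[tuple[float, str]]:
    if resolution <= 0:
        return records
    out: list[tuple[float, str]] = []
    last = -np.inf
    for t, state in records:
        tq = round(t / resolution) * resolution
        if tq <= last:
            tq = last + resolution
        out.append((tq, state))
        last = tq
    return out


def _channel_interp(leaf_channel_map: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel (left leaf index, weight of right leaf) for mapping leaf
    values onto detector channels by linear interpolation between leaf centres."""
    channels = np.arange(N_CHANNELS, dtype=float)
    idx = np.clip(np.searchsorted(leaf_channel_map, channels) - 1, 0, N_LEAVES - 2)
    span = leaf_channel_map[idx + 1] - leaf_channel_map[idx]
    frac = np.clip((channels - leaf_channel_map[idx]) / span, 0.0, 1.0)
    return idx, frac


def simulate_delivery(
    plan: DeliveryPlan,
    model: Optional[LeafMotionModel] = None,
    seed: Optional[int] = None,
    replicate: int = 1,
    unit_id: str = "SIM1",
) -> SyntheticDelivery:
    """Simulate one delivery of ``plan`` under ``model``.

    Returns mutually consistent MV trace, optical log, chamber charges and
    the fluence-equivalent truth sinogram.  The same (plan, model, seed)
    triple reproduces the delivery bit for bit.
    """
    model = model if model is not None else LeafMotionModel()
    rng = np.random.default_rng(model.seed if seed is None else seed)
    windows = plan.projection_windows

    trajectories: dict[int, _Breakpoints] = {}
    for leaf in plan.active_leaves:
        intervals = _commanded_intervals(plan, leaf)
        trajectories[leaf] = _build_trajectory(intervals, model, rng)

    # --- truth sinogram: exact transmission integral per projection -------
    truth = np.zeros((N_LEAVES, plan.n_projections))
    integrators = {leaf: TrajectoryIntegrator(bp, model) for leaf, bp in trajectories.items()}
    for leaf, integ in integrators.items():
        edges = np.concatenate([windows[:, 0], windows[-1:, 1]])
        cum = np.array([integ.cumulative(e) for e in edges])
        truth[leaf - 1, :] = np.diff(cum)
    truth_sino = LOTSinogram(plan_id=plan.plan_id, method="planned", lot=truth)

    # --- MV trace ---------------------------------------------------------
    dt = 1000.0 / DEFAULT_SAMPLE_RATE_HZ
    all_t = [bp.t for bp in trajectories.values() if bp.t.size]
    t_lo = min([0.0] + [t[0] for t in all_t]) - 10 * dt
    t_hi = max([plan.total_time] + [t[-1] for t in all_t]) + 10 * dt
    n_samples = int(np.ceil((t_hi - t_lo) / dt)) + 1
    times = t_lo + dt * np.arange(n_samples)

    # detector samples are float32 under noise (the noise floor dominates);
    # noiseless simulations keep float64 so consistency checks hit 1e-6 ms
    dtype = np.float32 if model.mv_noise_sd > 0 else np.float64
    nodes_x, nodes_t = model.ramp_nodes
    leaf_trans = np.zeros((n_samples, N_LEAVES), dtype=dtype)
    for leaf, bp in trajectories.items():
        if bp.t.size:
            xs = np.interp(times, bp.t, bp.x, left=0.0, right=0.0)
            leaf_trans[:, leaf - 1] = np.interp(xs, nodes_x, nodes_t)
    conv = convolve1d(leaf_trans, model.crosstalk_kernel, axis=1, mode="constant", cval=0.0)

    amp = plan.jaw_opening
    leaf_map = default_leaf_channel_map()
    # noise + offset background, then signal added only on channels that can
    # carry it (columns between leaves with any transmission) — the detector
    # is 640 channels wide but a delivery usually opens a handful of leaves
    if model.mv_noise_sd > 0:
        samples = rng.standard_normal((n_samples, N_CHANNELS), dtype=np.float32)
        samples *= np.float32(model.mv_noise_sd * amp)
        samples += np.float32(model.offset_level * amp)
    else:
        samples = np.full((n_samples, N_CHANNELS), model.offset_level * amp, dtype=dtype)
    idx, frac = _channel_interp(leaf_map)
    live = conv.any(axis=0)
    for ch in np.flatnonzero(live[idx] | live[idx + 1]):
        j, f = idx[ch], frac[ch]
        samples[:, ch] += (amp * (1.0 - f)) * conv[:, j] + (amp * f) * conv[:, j + 1]
    if model.arcing_rate > 0:
        n_arcs = rng.poisson(model.arcing_rate * (t_hi - t_lo) / 1000.0)
        if n_arcs:
            arc_idx = rng.integers(1, n_samples - 1, size=n_arcs)
            samples[arc_idx, :] += 20.0 * amp
    trace = MVDetectorTrace(
        sample_rate=DEFAULT_SAMPLE_RATE_HZ,
        times=times,
        samples=samples,
        projection_windows=windows,
        leaf_channel_map=leaf_map,
    )

    # --- optical log ------------------------------------------------------
    rows = []
    for leaf, bp in trajectories.items():
        for t, state in _quantize_records(bp.records, model.optical_resolution):
            rows.append((t, leaf, state))
    rows.sort(key=lambda r: r[0])
    log = OpticalEventLog.from_records(
        rows, resolution=model.optical_resolution or DEFAULT_RESOLUTION_MS
    )

    # --- chamber charges --------------------------------------------------
    charge_rows = []
    for chamber_idx, leaf in enumerate(sorted(trajectories), start=1):
        q = integrators[leaf].total * amp
        if model.charge_noise_rel > 0:
            q *= 1.0 + rng.normal(0.0, model.charge_noise_rel)
        charge_rows.append(
            {
                "chamber": chamber_idx,
                "leaf": leaf,
                "jaw_cm": plan.jaw_opening,
                "x_fraction": plan.lot_fraction_x if plan.lot_fraction_x is not None else np.nan,
                "replicate": replicate,
                "charge": max(q, 0.0),
            }
        )
    charge_columns = ["chamber", "leaf", "jaw_cm", "x_fraction", "replicate", "charge"]
    charges = ChamberChargeSet(
        unit_id=unit_id, records=pd.DataFrame(charge_rows, columns=charge_columns)
    )

    return SyntheticDelivery(
        plan=plan,
        model=model,
        truth=truth_sino,
        trace=trace,
        log=log,
        charges=charges,
        replicate=replicate,
    )


def true_mean_lot(delivery: SyntheticDelivery, leaf: int) -> float:
    """Mean fluence-equivalent LOT of an active leaf over all projections."""
    if leaf not in delivery.plan.active_leaves:
        raise SimulationError(f"leaf {leaf} is not active in plan {delivery.plan.plan_id!r}")
    return delivery.truth.mean_lot(leaf)


def simulate_reference_session(
    model: Optional[LeafMotionModel] = None,
    seed: int = 42,
    replicates: int = 1,
    fractions: Optional[Sequence[float]] = None,
    unit_id: str = "SIM1",
    reduce: Optional[Callable[[SyntheticDelivery], object]] = None,
):
    """Simulate the 12 reference calibration plans (optionally a subset of
    LOT fractions), ``replicates`` deliveries each.

    Returns ``(items, charge_set)`` where ``items`` is a list of
    ``SyntheticDelivery`` (or of ``reduce(delivery)`` results — handy for
    discarding the ~100 MB trace of each delivery right after
    preprocessing) and ``charge_set`` pools all chamber records.
    """
    model = model if model is not None else LeafMotionModel()
    plans = make_reference_plans()
    if fractions is not None:
        plans = [p for p in plans if p.lot_fraction_x in set(fractions)]
    seeds = np.random.SeedSequence(seed).generate_state(len(plans) * replicates) % (2**31)
    items = []
    charge_frames = []
    i = 0
    for plan in plans:
        for rep in range(1, replicates + 1):
            delivery = simulate_delivery(
                plan, model, seed=int(seeds[i]), replicate=rep, unit_id=unit_id
            )
            i += 1
            charge_frames.append(delivery.charges.records)
            items.append(reduce(delivery) if reduce is not None else delivery)
    charge_set = ChamberChargeSet(
        unit_id=unit_id, records=pd.concat(charge_frames, ignore_index=True)
    )
    return items, charge_set
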