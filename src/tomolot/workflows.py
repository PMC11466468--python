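"""End-to-end reference-plan workflows: simulate, calibrate, validate.

These helpers chain the simulator, the two reconstruction methods and the
chamber ground truth over the 12 static-gantry reference plans, mirroring how
the thresholds of a real unit would be commissioned: deliver the plans, read
back the telemetry, convert the chamber charges, sweep the threshold grid,
then validate the calibrated methods on an independent delivery session.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import (
    DEFAULT_TAU_GRID,
    CalibrationEntry,
    CalibrationResult,
    ValidationReport,
    calibrate_threshold,
    mean_lots_at,
    validate_methods,
)
from .chamber import ground_truth_table
from .mv import LeafSignal, preprocess_trace
from .optical import OpticalEventLog
from .plans import REFERENCE_T_PROJ_MS, DeliveryPlan
from .simulate import LeafMotionModel, SyntheticDelivery, simulate_reference_session


@dataclass
class ReducedDelivery:
    """A delivery reduced to what calibration needs (the raw trace dropped)."""

    plan: DeliveryPlan
    replicate: int
    signals: Mapping[int, LeafSignal]  # active leaves only
    log: OpticalEventLog


def reduce_delivery(delivery: SyntheticDelivery) -> ReducedDelivery:
    """Preprocess the MV trace and keep only the active-leaf signals."""
    signals = preprocess_trace(delivery.trace, plan=delivery.plan)
    keep = {leaf: signals[leaf - 1] for leaf in delivery.plan.active_leaves}
    return ReducedDelivery(
        plan=delivery.plan,
        replicate=delivery.replicate,
        signals=keep,
        log=delivery.log,
    )


def reference_dataset(
    model: Optional[LeafMotionModel] = None,
    seed: int = 42,
    replicates: int = 1,
    fractions: Optional[Sequence[float]] = None,
) -> tuple[list[ReducedDelivery], pd.DataFrame]:
    """Simulate reference plans and convert their charges to ground truth.

    The 100% plans always take part (their charges are the denominators of
    the charge-ratio conversion) even when ``fractions`` restricts the
    partial-LOT plans.  Returns the reduced deliveries of the requested
    fractions plus the tidy ground-truth table.
    """
    model = model if model is not None else LeafMotionModel()
    sim_fractions = None if fractions is None else sorted(set(fractions) | {1.0})
    items, charges = simulate_reference_session(
        model=model,
        seed=seed,
        replicates=replicates,
        fractions=sim_fractions,
        reduce=reduce_delivery,
    )
    truth = ground_truth_table(charges, REFERENCE_T_PROJ_MS)
    if fractions is not None:
        items = [r for r in items if r.plan.lot_fraction_x in set(fractions)]
    return items, truth


def calibration_entries(
    dataset: Sequence[ReducedDelivery], truth: pd.DataFrame, method: str
) -> list[CalibrationEntry]:
    """Pair each partial-LOT delivery with its chamber ground truth.

    Plans at 100% LOT are reference-only (their charge defines the ratio
    denominator) and are skipped.
    """
    entries = []
    for item in dataset:
        x = item.plan.lot_fraction_x
        if x is None or x >= 1.0:
            continue
        rows = truth[
            (truth["jaw_cm"] == item.plan.jaw_opening)
            & (truth["x_fraction"] == x)
            & (truth["replicate"] == item.replicate)
        ]
        leaf_truth = {int(r.leaf): float(r.mean_lot_ms) for r in rows.itertuples(index=False)}
        telemetry = item.signals if method == "mv_detector" else item.log
        entries.append(CalibrationEntry(plan=item.plan, telemetry=telemetry, truth=leaf_truth))
    return entries


def run_reference_calibrations(
    methods: Sequence[str] = ("mv_detector", "optical_sensor"),
    model: Optional[LeafMotionModel] = None,
    seed: int = 42,
    replicates: int = 1,
    tau_grid: Sequence[float] = DEFAULT_TAU_GRID,
) -> dict[str, tuple[CalibrationResult, list[CalibrationEntry]]]:
    """Commission thresholds on one shared simulated calibration session."""
    dataset, truth = reference_dataset(model=model, seed=seed, replicates=replicates)
    out = {}
    for method in methods:
        entries = calibration_entries(dataset, truth, method)
        out[method] = (calibrate_threshold(method, entries, tau_grid), entries)
    return out


def run_reference_calibration(
    method: str,
    model: Optional[LeafMotionModel] = None,
    seed: int = 42,
    replicates: int = 1,
    tau_grid: Sequence[float] = DEFAULT_TAU_GRID,
) -> tuple[CalibrationResult, list[CalibrationEntry]]:
    """Commission one method's threshold on a simulated calibration session."""
    return run_reference_calibrations([method], model, seed, replicates, tau_grid)[method]


def run_reference_validation(
    thresholds: Mapping[str, float],
    model: Optional[LeafMotionModel] = None,
    seed: int = 43,
    replicates: int = 2,
    fractions: Sequence[float] = (0.25, 0.50, 0.75),
) -> tuple[pd.DataFrame, ValidationReport]:
    """Validate calibrated methods on an independent simulated session.

    Simulates the partial-LOT reference plans ``replicates`` times, computes
    each method's mean LOT per (plan, leaf) at its calibrated threshold,
    averages replicates, and runs the validation statistics against the
    replicate-averaged chamber ground truth.

    Returns the merged tidy table (one row per plan x leaf with one column
    per method plus ``truth_ms``) and the statistical report.
    """
    dataset, truth = reference_dataset(
        model=model, seed=seed, replicates=replicates, fractions=fractions
    )
    frames = []
    for method, tau in thresholds.items():
        entries = calibration_entries(dataset, truth, method)
        table = mean_lots_at(method, entries, tau)
        # replicate entries share plan_id; average at the mean-LOT level
        agg = (
            table.groupby(["plan_id", "leaf"], as_index=False)
            .agg(calculated_ms=("calculated_ms", "mean"), truth_ms=("truth_ms", "mean"))
            .rename(columns={"calculated_ms": method})
        )
        frames.append(agg)
    merged = frames[0]
    for frame in frames[1:]:
        merged = merged.merge(frame, on=["plan_id", "leaf", "truth_ms"], how="inner")
    labels = list(zip(merged["plan_id"], merged["leaf"]))
    report = validate_methods(
        {m: merged[m].to_numpy() for m in thresholds},
        merged["truth_ms"].to_numpy(),
        labels=labels,
    )
    return merged, report
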