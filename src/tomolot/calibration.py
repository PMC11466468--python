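"""Threshold calibration against chamber ground truth, and QA statistics.

The fractional thresholds tau_mv / tau_opt of the two reconstruction methods
are free parameters: they are fixed by sweeping a grid of candidate values,
computing the mean discrepancy between method-calculated and chamber-measured
mean LOTs over a calibration set, and locating the zero crossing.  Validation
then compares both calibrated methods to ground truth with paired t-tests,
Pearson correlation and ordinary least-squares fits; per-fraction delivery
reports summarise MLC performance for clinical monitoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .mv import LeafSignal, MVDetectorTrace, preprocess_trace, widths_at_thresholds
from .optical import OpticalEventLog, mean_lot_curve_coefficients
from .plans import DeliveryPlan, LOTSinogram

DEFAULT_TAU_GRID = np.round(np.arange(0.30, 0.70 + 1e-9, 0.01), 2)
SHORT_LOT_MS = 100.0
VERY_SHORT_LOT_MS = 50.0


class CalibrationError(ValueError):
    """Raised when a threshold sweep cannot bracket a zero crossing."""


# ---------------------------------------------------------------------------
# discrepancy statistics
# ---------------------------------------------------------------------------

@dataclass
class DiscrepancyStats:
    """Summary of paired LOT discrepancies (calculated - reference), ms."""

    n: int
    mean: float
    median: float
    sd: float
    iqr: float
    min: float
    max: float
    outliers: list[tuple[float, object]] = field(default_factory=list)


def discrepancy_stats(
    calculated: Sequence[float],
    reference: Sequence[float],
    labels: Optional[Sequence[object]] = None,
) -> DiscrepancyStats:
    """Elementwise (calculated - reference) summary with 1.5*IQR outliers.

    ``sd`` is the sample standard deviation (n-1 denominator).  Outliers lie
    beyond 1.5 interquartile ranges outside the quartiles and are returned
    with their labels (indices when no labels are given).
    """
    calculated = np.asarray(calculated, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if calculated.shape != reference.shape:
        raise ValueError(
            f"length mismatch: {calculated.shape} calculated vs {reference.shape} reference"
        )
    diff = calculated - reference
    n = diff.size
    q1, q3 = np.percentile(diff, [25, 75]) if n else (0.0, 0.0)
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    labels = list(labels) if labels is not None else list(range(n))
    outliers = [
        (float(d), labels[i]) for i, d in enumerate(diff) if d < lo or d > hi
    ]
    return DiscrepancyStats(
        n=n,
        mean=float(diff.mean()) if n else 0.0,
        median=float(np.median(diff)) if n else 0.0,
        sd=float(diff.std(ddof=1)) if n > 1 else 0.0,
        iqr=float(iqr),
        min=float(diff.min()) if n else 0.0,
        max=float(diff.max()) if n else 0.0,
        outliers=outliers,
    )


# ---------------------------------------------------------------------------
# threshold calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationEntry:
    """One delivery of the calibration set.

    ``telemetry`` is an :class:`MVDetectorTrace` or a preprocessed
    ``list[LeafSignal]`` for the MV method, or an :class:`OpticalEventLog`
    for the optical method.  ``truth`` maps each active leaf (1-based) to its
    chamber-derived mean LOT in ms.
    """

    plan: DeliveryPlan
    telemetry: Union[MVDetectorTrace, "list[LeafSignal]", OpticalEventLog]
    truth: Mapping[int, float]


@dataclass
class CalibrationResult:
    method: str
    tau_grid: np.ndarray
    mean_discrepancy_curve: np.ndarray  # ms, one value per grid point
    tau_star: float

    def discrepancy_at(self, tau: float) -> float:
        """Mean discrepancy linearly interpolated at an arbitrary tau."""
        return float(np.interp(tau, self.tau_grid, self.mean_discrepancy_curve))


def _entry_mean_lots_mv(
    entry: CalibrationEntry, taus: np.ndarray
) -> dict[int, np.ndarray]:
    telemetry = entry.telemetry
    if isinstance(telemetry, MVDetectorTrace):
        signals = preprocess_trace(telemetry, plan=entry.plan)
    else:
        signals = telemetry
    windows = entry.plan.projection_windows
    out = {}
    for leaf in entry.truth:
        signal = signals[leaf] if isinstance(signals, Mapping) else signals[leaf - 1]
        widths = widths_at_thresholds(signal, windows, taus)
        out[leaf] = widths.mean(axis=0)
    return out


def _entry_mean_lots_optical(
    entry: CalibrationEntry, taus: np.ndarray
) -> dict[int, np.ndarray]:
    out = {}
    for leaf in entry.truth:
        base, slope = mean_lot_curve_coefficients(entry.telemetry, entry.plan, leaf)
        out[leaf] = base + slope * taus
    return out


def calibrate_threshold(
    method: str,
    entries: Sequence[CalibrationEntry],
    tau_grid: Sequence[float] = DEFAULT_TAU_GRID,
) -> CalibrationResult:
    """Locate the threshold at which the mean discrepancy crosses zero.

    At every grid tau the method's mean LOT is recomputed for every
    (delivery, active leaf) pair and compared with the chamber ground truth;
    the zero of the aggregate mean-discrepancy curve is found by linear
    interpolation between the bracketing grid points.
    """
    if method not in ("mv_detector", "optical_sensor"):
        raise CalibrationError(f"unknown method {method!r}")
    taus = np.asarray(tau_grid, dtype=float)
    if taus.size < 2 or np.any(np.diff(taus) <= 0):
        raise CalibrationError("tau_grid must be increasing with >= 2 points")
    per_pair = []
    compute = _entry_mean_lots_mv if method == "mv_detector" else _entry_mean_lots_optical
    for entry in entries:
        lots = compute(entry, taus)
        for leaf, curve in lots.items():
            per_pair.append(curve - entry.truth[leaf])
    if not per_pair:
        raise CalibrationError("calibration set is empty")
    curve = np.mean(per_pair, axis=0)
    sign_change = np.flatnonzero(np.sign(curve[:-1]) * np.sign(curve[1:]) <= 0)
    crossings = [i for i in sign_change if curve[i] != 0 or curve[i + 1] != 0]
    if not crossings:
        raise CalibrationError(
            "mean-discrepancy curve has no sign change on the grid "
            f"[{taus[0]:g}, {taus[-1]:g}]; widen the tau grid"
        )
    i = crossings[0]
    c0, c1 = curve[i], curve[i + 1]
    tau_star = taus[i] if c0 == 0 else taus[i] + (taus[i + 1] - taus[i]) * c0 / (c0 - c1)
    return CalibrationResult(
        method=method, tau_grid=taus, mean_discrepancy_curve=curve, tau_star=float(tau_star)
    )


def mean_lots_at(
    method: str, entries: Sequence[CalibrationEntry], tau: float
) -> pd.DataFrame:
    """Method-calculated and ground-truth mean LOTs at one threshold.

    Returns a tidy frame with columns plan_id, leaf, calculated_ms, truth_ms.
    """
    taus = np.asarray([tau])
    compute = _entry_mean_lots_mv if method == "mv_detector" else _entry_mean_lots_optical
    rows = []
    for entry in entries:
        lots = compute(entry, taus)
        for leaf, curve in lots.items():
            rows.append(
                {
                    "plan_id": entry.plan.plan_id,
                    "leaf": leaf,
                    "calculated_ms": float(curve[0]),
                    "truth_ms": float(entry.truth[leaf]),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# validation statistics
# ---------------------------------------------------------------------------

@dataclass
class MethodValidation:
    stats: DiscrepancyStats
    t_statistic: float
    p_value: float
    alpha: float
    decision: str  # "no_significant_difference" | "significant_difference" | "degenerate"
    pearson_r: float
    pearson_p: float
    slope: float
    intercept: float  # ms


@dataclass
class ValidationReport:
    per_method: dict[str, MethodValidation]


def validate_methods(
    calculated_by_method: Mapping[str, Sequence[float]],
    reference: Sequence[float],
    alpha: float = 0.05,
    labels: Optional[Sequence[object]] = None,
) -> ValidationReport:
    """Paired t-test, Pearson correlation and OLS fit per method.

    The paired two-tailed t-test compares each method's mean LOTs with the
    chamber-measured ones (equivalently, their discrepancies relative to the
    plan, since the planned values cancel in the pairing).  A zero-variance
    pairing is reported as degenerate rather than raising.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.size < 3:
        raise ValueError("validation requires at least 3 paired values")
    report: dict[str, MethodValidation] = {}
    for method, calculated in calculated_by_method.items():
        calculated = np.asarray(calculated, dtype=float)
        if calculated.shape != reference.shape:
            raise ValueError(f"method {method!r}: length mismatch with reference")
        stats_ = discrepancy_stats(calculated, reference, labels=labels)
        diff = calculated - reference
        if np.allclose(diff, diff[0]):
            t_stat, p_val, decision = float("nan"), float("nan"), "degenerate"
        else:
            t_res = stats.ttest_rel(calculated, reference)
            t_stat, p_val = float(t_res.statistic), float(t_res.pvalue)
            decision = (
                "significant_difference" if p_val < alpha else "no_significant_difference"
            )
        pear = stats.pearsonr(calculated, reference)
        fit = stats.linregress(reference, calculated)
        report[method] = MethodValidation(
            stats=stats_,
            t_statistic=t_stat,
            p_value=p_val,
            alpha=alpha,
            decision=decision,
            pearson_r=float(pear.statistic),
            pearson_p=float(pear.pvalue),
            slope=float(fit.slope),
            intercept=float(fit.intercept),
        )
    return ValidationReport(per_method=report)


# ---------------------------------------------------------------------------
# per-fraction MLC performance report
# ---------------------------------------------------------------------------

def fraction_report(
    performed: Sequence[LOTSinogram], planned: DeliveryPlan
) -> pd.DataFrame:
    """Per-fraction summary of executed LOTs against the plan.

    For every fraction: summary statistics of the nonzero LOTs, the share of
    short LOTs (< 100 ms) and very short LOTs (< 50 ms), and the mean
    discrepancy versus the planned sinogram over the plan's open cells.
    """
    open_cells = planned.planned_lot > 0
    rows = []
    for idx, sino in enumerate(performed, start=1):
        if sino.lot.shape != planned.planned_lot.shape:
            raise ValueError(
                f"fraction {idx}: sinogram shape {sino.lot.shape} does not match plan "
                f"{planned.planned_lot.shape}"
            )
        nonzero = sino.lot[sino.lot > 0]
        disc = sino.lot[open_cells] - planned.planned_lot[open_cells]
        rows.append(
            {
                "fraction": idx,
                "method": sino.method,
                "n_open": int(nonzero.size),
                "mean_ms": float(nonzero.mean()) if nonzero.size else 0.0,
                "median_ms": float(np.median(nonzero)) if nonzero.size else 0.0,
                "sd_ms": float(nonzero.std(ddof=1)) if nonzero.size > 1 else 0.0,
                "min_ms": float(nonzero.min()) if nonzero.size else 0.0,
                "max_ms": float(nonzero.max()) if nonzero.size else 0.0,
                "pct_short": 100.0 * float((nonzero < SHORT_LOT_MS).mean()) if nonzero.size else 0.0,
                "pct_very_short": 100.0 * float((nonzero < VERY_SHORT_LOT_MS).mean())
                if nonzero.size
                else 0.0,
                "mean_discrepancy_ms": float(disc.mean()) if disc.size else 0.0,
            }
        )
    return pd.DataFrame(rows)
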