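"""Planned and reconstructed leaf-open-time (LOT) sinograms.

A tomotherapy delivery is described by a *sinogram*: a 64-row matrix with one
row per binary-MLC leaf and one column per projection, each cell holding the
commanded (or reconstructed) leaf open time in milliseconds.  This module
defines the in-memory containers, their open JSON + CSV serialization, and the
generator for the twelve static-gantry reference plans used for threshold
calibration (three jaw openings crossed with four LOT fractions, three active
leaves, 400 projections of 348 ms).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

N_LEAVES = 64
#: reference-plan constants: projection time and active leaves
REFERENCE_T_PROJ_MS = 348.0
REFERENCE_N_PROJECTIONS = 400
REFERENCE_ACTIVE_LEAVES = (27, 39, 47)
JAW_OPENINGS_CM = (1.0, 2.5, 5.0)
LOT_FRACTIONS = (0.25, 0.50, 0.75, 1.00)

#: recognised reconstruction methods for LOTSinogram provenance
METHODS = ("planned", "mv_detector", "optical_sensor", "ion_chamber")


class PlanValidationError(ValueError):
    """Raised when a delivery plan or sinogram violates its invariants."""


@dataclass
class DeliveryPlan:
    """A planned delivery: LOT sinogram plus timing and jaw metadata.

    Leaves are indexed 1..64 (matching machine numbering); projections are
    0-based internally.  ``planned_lot`` has shape (64, n_projections) in ms.
    """

    plan_id: str
    n_projections: int
    t_proj: float  # ms
    jaw_opening: float  # cm, one of {1, 2.5, 5}
    planned_lot: np.ndarray  # (64, n_projections) ms
    gantry_mode: str = "static"
    lot_fraction_x: Optional[float] = None
    n_leaves: int = N_LEAVES

    def __post_init__(self) -> None:
        self.planned_lot = np.asarray(self.planned_lot, dtype=float)
        if self.n_leaves != N_LEAVES:
            raise PlanValidationError(f"n_leaves must be {N_LEAVES}, got {self.n_leaves}")
        if self.planned_lot.shape != (self.n_leaves, self.n_projections):
            raise PlanValidationError(
                f"plan {self.plan_id!r}: sinogram shape {self.planned_lot.shape} "
                f"does not match ({self.n_leaves}, {self.n_projections})"
            )
        if self.gantry_mode not in ("static", "helical"):
            raise PlanValidationError(f"unknown gantry_mode {self.gantry_mode!r}")
        if not np.all(np.isfinite(self.planned_lot)):
            raise PlanValidationError(f"plan {self.plan_id!r}: non-finite LOT value")
        bad = np.argwhere((self.planned_lot < 0) | (self.planned_lot > self.t_proj + 1e-9))
        if bad.size:
            leaf, proj = bad[0]
            raise PlanValidationError(
                f"plan {self.plan_id!r}: LOT {self.planned_lot[leaf, proj]:g} ms at "
                f"leaf {leaf + 1}, projection {proj} outside [0, t_proj={self.t_proj:g}]"
            )

    @property
    def active_leaves(self) -> tuple[int, ...]:
        """1-based indices of leaves with any nonzero planned LOT."""
        rows = np.flatnonzero(self.planned_lot.any(axis=1))
        return tuple(int(i) + 1 for i in rows)

    @property
    def projection_windows(self) -> np.ndarray:
        """(n_projections, 2) array of [start, end) times in ms, starting at 0."""
        starts = np.arange(self.n_projections) * self.t_proj
        return np.column_stack([starts, starts + self.t_proj])

    @property
    def total_time(self) -> float:
        return self.n_projections * self.t_proj


@dataclass
class LOTSinogram:
    """A reconstructed (or planned) LOT sinogram with method provenance."""

    plan_id: str
    method: str
    lot: np.ndarray  # (64, n_projections) ms
    threshold: Optional[float] = None

    def __post_init__(self) -> None:
        self.lot = np.asarray(self.lot, dtype=float)
        if self.method not in METHODS:
            raise PlanValidationError(f"unknown method {self.method!r}")
        if self.lot.ndim != 2 or self.lot.shape[0] != N_LEAVES:
            raise PlanValidationError(
                f"sinogram shape {self.lot.shape} must be ({N_LEAVES}, n_projections)"
            )
        if not np.all(np.isfinite(self.lot)) or np.any(self.lot < 0):
            raise PlanValidationError("sinogram values must be finite and >= 0")
        if self.threshold is not None and not 0 <= self.threshold <= 1:
            raise PlanValidationError(f"threshold {self.threshold} outside [0, 1]")

    def mean_lot(self, leaf: int) -> float:
        """Mean LOT of a (1-based) leaf over all projections, in ms.

        This is the time-integrated quantity an ionization chamber on the
        leaf's beamlet path measures, divided by the number of projections.
        """
        return float(self.lot[leaf - 1].sum() / self.lot.shape[1])


def make_reference_plans() -> list[DeliveryPlan]:
    """The 12 static-gantry calibration plans.

    Cross product of jaw opening {1, 2.5, 5} cm and LOT fraction
    x in {25, 50, 75, 100}% of the projection time; 400 projections of
    348 ms; leaves 27, 39 and 47 open for x*t_proj in every projection,
    all other leaves closed throughout.
    """
    plans = []
    for jo in JAW_OPENINGS_CM:
        for x in LOT_FRACTIONS:
            lot = np.zeros((N_LEAVES, REFERENCE_N_PROJECTIONS))
            for leaf in REFERENCE_ACTIVE_LEAVES:
                lot[leaf - 1, :] = x * REFERENCE_T_PROJ_MS
            plans.append(
                DeliveryPlan(
                    plan_id=f"ref_jo{jo:g}_x{int(round(x * 100))}",
                    n_projections=REFERENCE_N_PROJECTIONS,
                    t_proj=REFERENCE_T_PROJ_MS,
                    jaw_opening=jo,
                    planned_lot=lot,
                    gantry_mode="static",
                    lot_fraction_x=x,
                )
            )
    return plans


# ---------------------------------------------------------------------------
# serialization: JSON metadata + CSV matrix (row = leaf), ms with >=3 decimals
# ---------------------------------------------------------------------------

def _write_matrix_csv(path: Path, matrix: np.ndarray) -> None:
    np.savetxt(path, matrix, fmt="%.6f", delimiter=",")


def _read_matrix_csv(path: Path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=","))


def write_plan(plan: DeliveryPlan, path: str | Path) -> None:
    """Write a plan as ``<path>`` (JSON) plus ``<stem>.sinogram.csv`` beside it."""
    path = Path(path)
    csv_name = path.stem + ".sinogram.csv"
    meta = {
        "plan_id": plan.plan_id,
        "n_leaves": plan.n_leaves,
        "n_projections": plan.n_projections,
        "t_proj_ms": plan.t_proj,
        "jaw_opening_cm": plan.jaw_opening,
        "gantry_mode": plan.gantry_mode,
        "lot_fraction_x": plan.lot_fraction_x,
        "sinogram_csv": csv_name,
    }
    path.write_text(json.dumps(meta, indent=1))
    _write_matrix_csv(path.parent / csv_name, plan.planned_lot)


def read_plan(path: str | Path) -> DeliveryPlan:
    path = Path(path)
    try:
        meta = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise PlanValidationError(f"malformed plan file {path}: {exc}") from exc
    matrix = _read_matrix_csv(path.parent / meta["sinogram_csv"])
    x = meta.get("lot_fraction_x")
    if x is not None:
        # exact-fraction plans: rederive cells from x to avoid decimal drift
        expected = np.where(matrix > 0, x * meta["t_proj_ms"], 0.0)
        if np.allclose(matrix, expected, atol=5e-6):
            matrix = expected
    return DeliveryPlan(
        plan_id=meta["plan_id"],
        n_projections=int(meta["n_projections"]),
        t_proj=float(meta["t_proj_ms"]),
        jaw_opening=float(meta["jaw_opening_cm"]),
        planned_lot=matrix,
        gantry_mode=meta.get("gantry_mode", "static"),
        lot_fraction_x=x,
    )


def write_sinogram(sino: LOTSinogram, path: str | Path) -> None:
    path = Path(path)
    csv_name = path.stem + ".sinogram.csv"
    meta = {
        "plan_id": sino.plan_id,
        "method": sino.method,
        "threshold": sino.threshold,
        "sinogram_csv": csv_name,
    }
    path.write_text(json.dumps(meta, indent=1))
    _write_matrix_csv(path.parent / csv_name, sino.lot)


def read_sinogram(path: str | Path) -> LOTSinogram:
    path = Path(path)
    meta = json.loads(path.read_text())
    matrix = _read_matrix_csv(path.parent / meta["sinogram_csv"])
    return LOTSinogram(
        plan_id=meta["plan_id"],
        method=meta["method"],
        threshold=meta.get("threshold"),
        lot=matrix,
    )
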