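"""LOT reconstruction from the per-leaf optical position-sensor stream.

Each leaf carries a notch read by two photoemitter/photoreceptor pairs,
yielding a three-state reading — CLOSED, TRANSITION, OPEN — polled at a cycle
time of about 0.18 ms.  A leaf's state sequence is segmented into open events;
each event's LOT is the threshold-weighted interval

    LOT(tau) = [t3 + tau*(t4 - t3)] - [t1 + tau*(t2 - t1)]

where t1..t4 are the four state-change times (closed->transition,
transition->open, open->transition, transition->closed) and tau places the
effective opening/closing instant within the transition interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .plans import N_LEAVES, DeliveryPlan, LOTSinogram

STATES = ("CLOSED", "TRANSITION", "OPEN")
_STATE_LEVEL = {"CLOSED": 0, "TRANSITION": 1, "OPEN": 2}
DEFAULT_RESOLUTION_MS = 0.18  # ~5556 Hz polling cycle


class EventLogError(ValueError):
    """Raised for malformed optical event logs."""


@dataclass
class OpticalEventLog:
    """Timestamped per-leaf state-change records.

    Only changes are stored (sparse form); a record means the leaf entered
    ``state`` at ``time_ms``.  Leaves are assumed CLOSED before their first
    record.
    """

    records: pd.DataFrame  # columns: time_ms, leaf, state
    resolution: float = DEFAULT_RESOLUTION_MS

    def __post_init__(self) -> None:
        needed = {"time_ms", "leaf", "state"}
        if not needed.issubset(self.records.columns):
            raise EventLogError(f"records must have columns {sorted(needed)}")
        if not self.records["state"].isin(STATES).all():
            bad = self.records.loc[~self.records["state"].isin(STATES)].iloc[0]
            raise EventLogError(f"unknown state {bad['state']!r} at t={bad['time_ms']}")
        if not self.records["time_ms"].is_monotonic_increasing:
            raise EventLogError("timestamps must be non-decreasing")

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[float, int, str]], resolution: float = DEFAULT_RESOLUTION_MS
    ) -> "OpticalEventLog":
        df = pd.DataFrame(records, columns=["time_ms", "leaf", "state"])
        df = df.sort_values("time_ms", kind="stable").reset_index(drop=True)
        return cls(records=df, resolution=resolution)

    def leaf_records(self, leaf: int) -> pd.DataFrame:
        return self.records.loc[self.records["leaf"] == leaf]

    def write_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def read_csv(cls, path: str | Path, resolution: float = DEFAULT_RESOLUTION_MS) -> "OpticalEventLog":
        df = pd.read_csv(path)
        return cls(records=df[["time_ms", "leaf", "state"]], resolution=resolution)


@dataclass
class OpenEvent:
    """One opening of a leaf, delimited by the four state-change times.

    ``kind`` is ``normal`` for the full closed->transition->open->transition->
    closed sequence, ``merged_open`` when the event shares a transition with a
    neighbouring open event (leaf did not fully close), and ``no_open`` when
    the leaf turned back before reaching the open state (LOT defined as 0).
    """

    leaf: int
    t1: float
    t4: float
    t2: Optional[float] = None
    t3: Optional[float] = None
    kind: str = "normal"

    def __post_init__(self) -> None:
        if self.kind not in ("normal", "merged_open", "no_open"):
            raise EventLogError(f"unknown event kind {self.kind!r}")
        if self.kind == "no_open":
            if not self.t1 <= self.t4:
                raise EventLogError("no_open event requires t1 <= t4")
        else:
            ts = (self.t1, self.t2, self.t3, self.t4)
            if any(t is None for t in ts):
                raise EventLogError(f"{self.kind} event requires all of t1..t4")
            if not (self.t1 <= self.t2 <= self.t3 <= self.t4):
                raise EventLogError(f"event times must be ordered, got {ts}")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.t1 + self.t4)


def segment_leaf_events(log: OpticalEventLog, leaf: int) -> list[OpenEvent]:
    """Partition one leaf's state sequence into open events.

    Handles the three sequences a moving leaf can produce: the normal
    open/close cycle; a merged pair of opens separated only by a transition
    (short commanded closed time — the shared transition is split at its
    midpoint, which serves as t3=t4 of the first event and t1=t2 of the
    second); and a transition that returns to closed without reaching open
    (short commanded LOT — the LOT is set to 0).
    """
    recs = log.leaf_records(leaf)
    events: list[OpenEvent] = []
    state = "CLOSED"
    t1 = t2 = t3 = None
    opened = False  # current transition chain has reached OPEN at least once
    from_split = False  # current event started at a merged-split boundary
    for row in recs.itertuples(index=False):
        t, new = float(row.time_ms), row.state
        if new == state:
            raise EventLogError(
                f"leaf {leaf}: repeated state {new!r} at t={t} ms"
            )
        if abs(_STATE_LEVEL[new] - _STATE_LEVEL[state]) != 1:
            raise EventLogError(
                f"leaf {leaf}: illegal {state}->{new} change at t={t} ms"
            )
        if state == "CLOSED" and new == "TRANSITION":
            t1, t2, t3, opened, from_split = t, None, None, False, False
        elif state == "TRANSITION" and new == "OPEN":
            if opened and t3 is not None:
                # merged pair: no CLOSED between two OPENs; split at midpoint
                mid = 0.5 * (t3 + t)
                events.append(
                    OpenEvent(leaf=leaf, t1=t1, t2=t2, t3=mid, t4=mid, kind="merged_open")
                )
                t1 = t2 = mid
                from_split = True
            elif t2 is None:
                t2 = t
            opened = True
            t3 = None
        elif state == "OPEN" and new == "TRANSITION":
            t3 = t
        elif state == "TRANSITION" and new == "CLOSED":
            if opened:
                kind = "merged_open" if from_split else "normal"
                events.append(OpenEvent(leaf=leaf, t1=t1, t2=t2, t3=t3, t4=t, kind=kind))
            else:
                events.append(OpenEvent(leaf=leaf, t1=t1, t4=t, kind="no_open"))
            t1 = t2 = t3 = None
            opened = False
            from_split = False
        state = new
    return events


def lot_from_event(event: OpenEvent, tau_opt: float) -> float:
    """Evaluate the threshold-weighted LOT of one event, in ms.

    ``no_open`` events return 0.  For merged events the split boundary stands
    in for the missing edge times, so the formula applies unchanged.
    """
    if not 0 <= tau_opt <= 1:
        raise EventLogError(f"tau_opt must be in [0, 1], got {tau_opt}")
    if event.kind == "no_open":
        return 0.0
    closing = event.t3 + tau_opt * (event.t4 - event.t3)
    opening = event.t1 + tau_opt * (event.t2 - event.t1)
    return float(closing - opening)


def event_affine_coefficients(event: OpenEvent) -> tuple[float, float]:
    """(intercept, slope) of the event's LOT as an affine function of tau.

    LOT(tau) = (t3 - t1) + tau * [(t4 - t3) - (t2 - t1)]; no_open events are
    identically 0.  Useful for threshold sweeps without re-segmentation.
    """
    if event.kind == "no_open":
        return 0.0, 0.0
    return (event.t3 - event.t1), (event.t4 - event.t3) - (event.t2 - event.t1)


def compute_lots_optical(
    log: OpticalEventLog, plan: DeliveryPlan, tau_opt: float
) -> LOTSinogram:
    """Reconstruct the LOT sinogram from an optical event log.

    Each event is assigned to the projection containing its temporal midpoint
    (t1+t4)/2; events are never split across projections, so an event's LOT
    identity is preserved.  Events spanning more than two projection windows
    are still assigned by midpoint, with a warning.
    """
    windows = plan.projection_windows
    starts = windows[:, 0]
    lot = np.zeros((N_LEAVES, plan.n_projections))
    for leaf in sorted(log.records["leaf"].unique()):
        for event in segment_leaf_events(log, int(leaf)):
            value = lot_from_event(event, tau_opt)
            if value == 0.0 and event.kind == "no_open":
                continue
            if event.t4 - event.t1 > 2 * plan.t_proj:
                warnings.warn(
                    f"leaf {leaf}: event [{event.t1:.1f}, {event.t4:.1f}] ms spans "
                    "more than two projections; assigned by midpoint",
                    stacklevel=2,
                )
            p = int(np.searchsorted(starts, event.midpoint, side="right")) - 1
            p = min(max(p, 0), plan.n_projections - 1)
            lot[int(leaf) - 1, p] += value
    return LOTSinogram(plan_id=plan.plan_id, method="optical_sensor", threshold=tau_opt, lot=lot)


def mean_lot_curve_coefficients(
    log: OpticalEventLog, plan: DeliveryPlan, leaf: int
) -> tuple[float, float]:
    """(intercept, slope) in tau of the leaf's mean LOT over all projections."""
    base = slope = 0.0
    for event in segment_leaf_events(log, leaf):
        b, s = event_affine_coefficients(event)
        base += b
        slope += s
    n = plan.n_projections
    return base / n, slope / n
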