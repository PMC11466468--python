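"""Ground-truth mean LOTs from in-phantom ionization-chamber charges.

Three chambers sit in a cylindrical solid-water ("cheese") phantom on the
beamlet paths of leaves 27, 39 and 47.  Because chamber charge is proportional
to the time-integrated beamlet fluence, the ratio of the charge measured for a
partial-LOT plan to the charge of the matching 100%-LOT plan converts directly
to a mean leaf open time:

    mean_LOT_x(i, jo) = q_x(i, jo) / q_100(i, jo) * t_proj

Only relative charge matters, so no electrometer calibration or
volume-averaging correction enters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

CHAMBER_LEAVES = {1: 27, 2: 39, 3: 47}  # chamber index -> leaf on its beamlet path


class ChargeConversionError(ValueError):
    """Raised for invalid charge inputs (e.g., missing 100% reference)."""


@dataclass
class ChamberChargeSet:
    """Charges per (chamber, jaw opening, LOT fraction, delivery replicate)."""

    unit_id: str
    records: pd.DataFrame  # columns: chamber, leaf, jaw_cm, x_fraction, replicate, charge

    def __post_init__(self) -> None:
        needed = {"chamber", "leaf", "jaw_cm", "x_fraction", "replicate", "charge"}
        missing = needed - set(self.records.columns)
        if missing:
            raise ChargeConversionError(f"charge records missing columns {sorted(missing)}")
        if (self.records["charge"] < 0).any():
            raise ChargeConversionError("charges must be >= 0")

    def write_csv(self, path: str | Path) -> None:
        df = self.records.copy()
        df.insert(0, "unit_id", self.unit_id)
        df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "ChamberChargeSet":
        df = pd.read_csv(path)
        unit = str(df["unit_id"].iloc[0]) if "unit_id" in df.columns and len(df) else ""
        cols = ["chamber", "leaf", "jaw_cm", "x_fraction", "replicate", "charge"]
        return cls(unit_id=unit, records=df[cols])


def mean_lot_from_charges(q_x: float, q_100: float, t_proj: float) -> float:
    """Charge-ratio conversion to a mean LOT in ms.

    ``q_x`` is the charge for the plan under test, ``q_100`` the charge for
    the matching plan whose leaves stay open for the full projection time.
    A ratio above 1 is physically possible (executed LOTs exceeding planned)
    and is flagged rather than rejected.
    """
    if q_100 <= 0:
        raise ChargeConversionError(f"reference charge must be > 0, got {q_100}")
    if q_x < 0:
        raise ChargeConversionError(f"charge must be >= 0, got {q_x}")
    if q_x > q_100:
        warnings.warn(
            f"charge ratio {q_x / q_100:.4f} > 1: mean LOT exceeds the projection time",
            stacklevel=2,
        )
    return q_x / q_100 * t_proj


def ground_truth_table(
    charges: ChamberChargeSet,
    t_proj: float,
    leakage_reference: Optional[Mapping[tuple[int, float], float]] = None,
) -> pd.DataFrame:
    """Convert a charge set into ground-truth mean LOTs.

    Returns a tidy table with one row per (chamber/leaf, jaw opening,
    LOT fraction x < 1, replicate) and a ``mean_lot_ms`` column.  Replicate
    deliveries are kept separate; averaging is a validation-stage decision.
    Each x-plan charge is divided by the 100%-plan charge of the same chamber,
    jaw opening and replicate (falling back to the replicate-mean reference
    when the matching replicate is absent).

    ``leakage_reference`` optionally maps (chamber, jaw_cm) to a closed-leaf
    leakage charge to subtract from both numerator and denominator; the
    formula as printed performs no such subtraction, which biases small-x
    plans high in the presence of leakage.
    """
    df = charges.records
    rows = []
    refs = df[df["x_fraction"] == 1.0]
    partials = df[df["x_fraction"] < 1.0]
    for (chamber, jaw), group in partials.groupby(["chamber", "jaw_cm"]):
        ref_group = refs[(refs["chamber"] == chamber) & (refs["jaw_cm"] == jaw)]
        if ref_group.empty:
            raise ChargeConversionError(
                f"missing 100% reference charge for chamber {chamber}, jaw {jaw} cm"
            )
        leak = leakage_reference.get((chamber, jaw), 0.0) if leakage_reference else 0.0
        for row in group.itertuples(index=False):
            match = ref_group[ref_group["replicate"] == row.replicate]
            q100 = float(match["charge"].iloc[0] if len(match) else ref_group["charge"].mean())
            rows.append(
                {
                    "unit_id": charges.unit_id,
                    "chamber": int(chamber),
                    "leaf": int(row.leaf),
                    "jaw_cm": float(jaw),
                    "x_fraction": float(row.x_fraction),
                    "replicate": int(row.replicate),
                    "mean_lot_ms": mean_lot_from_charges(
                        max(row.charge - leak, 0.0), q100 - leak, t_proj
                    ),
                }
            )
    columns = ["unit_id", "chamber", "leaf", "jaw_cm", "x_fraction", "replicate", "mean_lot_ms"]
    return pd.DataFrame(rows, columns=columns)
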