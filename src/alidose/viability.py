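"""WST-1 plate-reader viability normalization.

Each insert contributes three technical-replicate absorbance readings at
450 nm (formazan signal) plus a 562 nm reading outside the dye spectrum used
as an interference control.  Percentage viability relative to the incubator
negative control is

    viability = 100 * (test - blank) / (negative_control - blank)

where blank is the cell-free medium + reagent absorbance of the same plate.
Technical replicates are averaged per insert before normalization; because
the formula is affine in the test absorbance the order does not matter for
noise-free data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CONTROL_CONDITION",
    "BLANK_CONDITION",
    "ViabilityRecord",
    "aggregate_technical_replicates",
    "percent_viability",
    "flag_interference",
    "compute_viability_table",
]

CONTROL_CONDITION = "incubator_control"
BLANK_CONDITION = "medium_blank"

#: 562 nm reading above this multiple of the plate-blank 562 nm mean flags
#: an interference (bubble, debris).
DEFAULT_INTERFERENCE_FACTOR = 2.0

PLATE_COLUMNS = ["plate_id", "date", "condition", "insert_id", "replicate", "abs450", "abs562"]


@dataclass(frozen=True)
class ViabilityRecord:
    plate_id: str
    date: str
    condition: str
    insert_id: str
    viability_pct: float
    interference_flag: bool
    negative_flag: bool


def aggregate_technical_replicates(readings: pd.DataFrame) -> pd.DataFrame:
    """Mean absorbance per insert and wavelength over technical replicates.

    ``readings`` is the long-format plate table with columns
    ``plate_id, date, condition, insert_id, replicate, abs450, abs562``.
    Returns one row per insert with ``abs450``, ``abs562`` means and the
    replicate count ``n_replicates``.  A missing (NaN) absorbance raises,
    naming the insert.
    """
    missing = [c for c in PLATE_COLUMNS if c not in readings.columns]
    if missing:
        raise ValueError(f"plate table is missing columns {missing}")
    if len(readings) == 0:
        raise ValueError("empty plate table")
    bad = readings[readings[["abs450", "abs562"]].isna().any(axis=1)]
    if len(bad):
        inserts = sorted(bad["insert_id"].astype(str).unique())
        raise ValueError(f"missing absorbance values for insert(s) {inserts}")
    if (readings[["abs450", "abs562"]] < 0).to_numpy().any():
        raise ValueError("absorbances must be non-negative")
    grouped = (
        readings.groupby(["plate_id", "date", "condition", "insert_id"], as_index=False)
        .agg(abs450=("abs450", "mean"), abs562=("abs562", "mean"), n_replicates=("abs450", "size"))
    )
    return grouped


def percent_viability(test_mean: float, blank_mean: float, negative_control_mean: float) -> float:
    """Percentage viability relative to the incubator negative control.

    Raises if the assay is invalid (control signal not above blank).
    Values below 0 are returned as computed; callers flag rather than clip
    so the Gaussian consensus model downstream stays unbiased.
    """
    denom = negative_control_mean - blank_mean
    if denom <= 0:
        raise ValueError(
            "assay invalid: negative control mean must exceed the medium blank mean "
            f"(control={negative_control_mean}, blank={blank_mean})"
        )
    return 100.0 * (test_mean - blank_mean) / denom


def flag_interference(
    insert_abs562: float,
    plate_blank_abs562: float,
    factor: float = DEFAULT_INTERFERENCE_FACTOR,
) -> bool:
    """True when the off-spectrum 562 nm signal exceeds ``factor`` x blank level."""
    if factor <= 0:
        raise ValueError("interference factor must be > 0")
    return bool(insert_abs562 > factor * plate_blank_abs562)


def compute_viability_table(
    readings: pd.DataFrame,
    control_condition: str = CONTROL_CONDITION,
    blank_condition: str = BLANK_CONDITION,
    interference_factor: float = DEFAULT_INTERFERENCE_FACTOR,
    include_blank_wells: bool = False,
) -> pd.DataFrame:
    """Full plate pipeline: replicate aggregation, per-plate blank correction,
    normalization to the plate's incubator control, interference flagging.

    Blanks are never mixed across plates.  Returns one row per non-blank
    insert with columns ``plate_id, date, condition, insert_id,
    viability_pct, interference_flag, negative_flag``.  With
    ``include_blank_wells`` the blank wells themselves are also emitted on
    the viability scale (scattering around 0%), which the QC dynamic-range
    check compares against the positive control.
    """
    per_insert = aggregate_technical_replicates(readings)
    records: list[dict] = []
    for plate_id, plate in per_insert.groupby("plate_id"):
        blanks = plate[plate["condition"] == blank_condition]
        controls = plate[plate["condition"] == control_condition]
        if len(blanks) == 0:
            raise ValueError(f"plate {plate_id!r} has no {blank_condition!r} wells")
        if len(controls) == 0:
            raise ValueError(f"plate {plate_id!r} has no {control_condition!r} wells")
        blank450 = float(blanks["abs450"].mean())
        blank562 = float(blanks["abs562"].mean())
        control450 = float(controls["abs450"].mean())
        samples = plate if include_blank_wells else plate[plate["condition"] != blank_condition]
        for row in samples.itertuples(index=False):
            v = percent_viability(row.abs450, blank450, control450)
            records.append(
                {
                    "plate_id": row.plate_id,
                    "date": row.date,
                    "condition": row.condition,
                    "insert_id": row.insert_id,
                    "viability_pct": v,
                    "interference_flag": flag_interference(
                        row.abs562, blank562, interference_factor
                    ),
                    "negative_flag": bool(v < 0),
                }
            )
    out = pd.DataFrame.from_records(records)
    return out.sort_values(["plate_id", "condition", "insert_id"]).reset_index(drop=True)
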