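"""ICP-MS cerium quantification bookkeeping.

Elemental Ce is measured in three compartments per insert — digested cells,
PBS wash, and basolateral medium — plus method blanks.  Detection limits
follow the blank-sd convention (LOD = 3 sd, LOQ = 10 sd over the blank
replicates), samples are corrected by subtracting the blank mean, and the
areal deposition rate is the blank-corrected compartment sum per insert area
per exposure hour.  The intracellular fraction is the cells share of that
sum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CompartmentMeasurement",
    "DetectionLimits",
    "DepositionRates",
    "lod_loq",
    "blank_correct_samples",
    "recovery_check",
    "total_deposition",
    "deposition_table",
]

COMPARTMENTS = ("cells", "wash", "basal", "blank")

#: Acceptable recovery window for the QC reference material, % of reference.
RECOVERY_RANGE = (86.0, 120.0)


@dataclass(frozen=True)
class CompartmentMeasurement:
    sample_id: str
    insert_id: str
    timepoint_h: float
    compartment: str
    ce_mass_ng: float
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if not math.isfinite(self.ce_mass_ng):
            raise ValueError("ce_mass must be finite")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")


@dataclass(frozen=True)
class DetectionLimits:
    lod: float
    loq: float
    n_blanks: int
    blank_mean: float
    blank_sd: float


@dataclass(frozen=True)
class DepositionRates:
    deposition_rate: float  # ng cm-2 h-1, all compartments
    uptake_rate: float  # ng cm-2 h-1, cells only
    intracellular_fraction: float | None  # None when total mass is 0


def lod_loq(blank_values) -> DetectionLimits:
    """Detection limits from blank replicates: LOD = 3 sd, LOQ = 10 sd.

    Sample sd (ddof=1); at least two blanks are required.
    """
    blanks = np.asarray(list(blank_values), dtype=float)
    if blanks.size < 2:
        raise ValueError("need at least 2 blank measurements")
    sd = float(blanks.std(ddof=1))
    return DetectionLimits(
        lod=3.0 * sd,
        loq=10.0 * sd,
        n_blanks=int(blanks.size),
        blank_mean=float(blanks.mean()),
        blank_sd=sd,
    )


def blank_correct_samples(sample_values, blank_values) -> pd.DataFrame:
    """Subtract the blank mean from every sample value.

    Returns a frame with ``raw``, ``corrected``, ``below_lod`` and
    ``negative`` columns.  Below-LOD and negative corrected values are
    flagged but retained, so downstream sums stay unbiased.
    """
    samples = np.asarray(list(sample_values), dtype=float)
    blanks = np.asarray(list(blank_values), dtype=float)
    if blanks.size < 1:
        raise ValueError("need at least 1 blank measurement")
    blank_mean = float(blanks.mean())
    corrected = samples - blank_mean
    lod = lod_loq(blanks).lod if blanks.size >= 2 else 0.0
    return pd.DataFrame(
        {
            "raw": samples,
            "corrected": corrected,
            "below_lod": corrected < lod,
            "negative": corrected < 0,
        }
    )


def recovery_check(
    measured: float, reference: float, bounds: tuple[float, float] = RECOVERY_RANGE
) -> tuple[float, bool]:
    """Recovery percentage of a QC reference and a pass/fail at the method window."""
    if reference <= 0:
        raise ValueError("reference value must be > 0")
    recovery = 100.0 * measured / reference
    lo, hi = bounds
    return recovery, bool(lo <= recovery <= hi)


def total_deposition(
    cells_ng: float,
    wash_ng: float,
    basal_ng: float,
    insert_area_cm2: float,
    exposure_time_h: float,
) -> DepositionRates:
    """Areal deposition and uptake rates from blank-corrected compartment masses.

    Deposition counts everything that left the aerosol (cells + wash +
    basal); uptake counts the intracellular compartment only.  With an
    all-zero deposition the fraction is undefined and reported as None.
    """
    if insert_area_cm2 <= 0 or exposure_time_h <= 0:
        raise ValueError("insert area and exposure time must be > 0")
    total = cells_ng + wash_ng + basal_ng
    denom = insert_area_cm2 * exposure_time_h
    fraction = (cells_ng / total) if total != 0 else None
    return DepositionRates(
        deposition_rate=total / denom,
        uptake_rate=cells_ng / denom,
        intracellular_fraction=fraction,
    )


def deposition_table(
    measurements: pd.DataFrame,
    insert_area_cm2: float,
) -> pd.DataFrame:
    """Per-insert deposition rates from a long measurement table.

    ``measurements`` has columns ``insert_id, timepoint_h, compartment,
    ce_mass_ng`` where ``compartment == 'blank'`` rows are the method blanks
    shared across inserts.  Compartment masses are blank-corrected before
    summation.
    """
    required = {"insert_id", "timepoint_h", "compartment", "ce_mass_ng"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurement table is missing columns {sorted(missing)}")
    blanks = measurements.loc[measurements["compartment"] == "blank", "ce_mass_ng"]
    blank_mean = float(blanks.mean()) if len(blanks) else 0.0
    rows = []
    samples = measurements[measurements["compartment"] != "blank"]
    for (insert_id, t), grp in samples.groupby(["insert_id", "timepoint_h"]):
        masses = {c: 0.0 for c in ("cells", "wash", "basal")}
        for row in grp.itertuples(index=False):
            masses[row.compartment] += row.ce_mass_ng - blank_mean
        rates = total_deposition(
            masses["cells"], masses["wash"], masses["basal"], insert_area_cm2, float(t)
        )
        rows.append(
            {
                "insert_id": insert_id,
                "timepoint_h": float(t),
                "cells_ng": masses["cells"],
                "wash_ng": masses["wash"],
                "basal_ng": masses["basal"],
                "deposition_rate": rates.deposition_rate,
                "uptake_rate": rates.uptake_rate,
                "intracellular_fraction": rates.intracellular_fraction,
            }
        )
    return pd.DataFrame(rows).sort_values(["timepoint_h", "insert_id"]).reset_index(drop=True)
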