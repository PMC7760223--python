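"""Deposition dosimetry for flow-through air-liquid-interface (ALI) exposures.

The exposure chamber draws aerosol at a fixed flow over each cell-culture
insert.  If every particle passing over an insert deposited, the areal dose
rate would be

    max_rate = C * Q / A

with aerosol mass concentration C, per-insert flow Q and insert area A.  The
deposition efficiency is the measured areal deposition rate (from elemental
analysis of cells + wash + basal medium) as a percentage of that theoretical
maximum.  An in-vivo reference uptake rate (lung burden / alveolar surface
area / exposure duration) puts the in-vitro rate on the same
ng per cm2 per h scale for a direct equivalence check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from . import units

__all__ = [
    "ExposureConfig",
    "InVivoReference",
    "DoseReport",
    "maximum_deposition",
    "deposition_efficiency",
    "in_vivo_reference_rate",
    "compare_in_vitro_in_vivo",
    "coverage_fraction",
    "build_dose_report",
]

#: Growth area of the 12-well transwell inserts used at the ALI (cm2).
DEFAULT_INSERT_AREA_CM2 = 1.12


@dataclass(frozen=True)
class ExposureConfig:
    """Exposure-side inputs of the maximum-deposition calculation.

    aerosol_concentration : mg/m3
    flow_rate             : mL/min per insert
    exposure_time         : h
    insert_area           : cm2
    """

    aerosol_concentration: float
    flow_rate: float
    exposure_time: float
    insert_area: float = DEFAULT_INSERT_AREA_CM2

    def __post_init__(self) -> None:
        for name in ("aerosol_concentration", "flow_rate", "exposure_time", "insert_area"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if self.aerosol_concentration < 0:
            raise ValueError("aerosol_concentration must be >= 0")
        for name in ("flow_rate", "exposure_time", "insert_area"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class InVivoReference:
    """Whole-animal inhalation reference: lung burden over alveolar area and time.

    lung_burden       : ug deposited per lung
    alveolar_area     : cm2
    exposure_duration : h
    """

    lung_burden: float
    alveolar_area: float
    exposure_duration: float

    def __post_init__(self) -> None:
        if self.lung_burden < 0:
            raise ValueError("lung_burden must be >= 0")
        if self.alveolar_area <= 0 or self.exposure_duration <= 0:
            raise ValueError("alveolar_area and exposure_duration must be > 0")


@dataclass
class DoseReport:
    max_deposition_rate: float  # ug cm-2 h-1
    max_deposition_total: float  # ug cm-2 over exposure_time
    measured_deposition_rate: float  # ng cm-2 h-1
    efficiency: float  # %
    uptake_rate: float | None = None  # ng cm-2 h-1 (intracellular)
    in_vivo_rate: float | None = None  # ng cm-2 h-1
    in_vitro_to_in_vivo_ratio: float | None = None
    comparable: bool | None = None
    coverage_fraction: float | None = None
    notes: list[str] = field(default_factory=list)


def maximum_deposition(cfg: ExposureConfig) -> tuple[float, float]:
    """Theoretical 100%-deposition rate and total areal dose.

    Returns ``(rate, total)`` with rate in ug cm-2 h-1 and total in ug cm-2
    over ``cfg.exposure_time``.
    """
    c_ng_ml = units.mg_m3_to_ng_ml(cfg.aerosol_concentration)
    rate_ng = c_ng_ml * cfg.flow_rate * units.MIN_PER_H / cfg.insert_area
    rate_ug = units.ng_to_ug(rate_ng)
    return rate_ug, rate_ug * cfg.exposure_time


def deposition_efficiency(measured_rate_ng_cm2_h: float, maximum_rate_ug_cm2_h: float) -> float:
    """Measured areal deposition rate as % of the theoretical maximum.

    ``measured`` is in ng cm-2 h-1, ``maximum`` in ug cm-2 h-1; the unit gap
    is harmonized internally.
    """
    if maximum_rate_ug_cm2_h <= 0:
        raise ValueError("maximum deposition rate must be > 0")
    max_ng = units.ug_to_ng(maximum_rate_ug_cm2_h)
    return 100.0 * measured_rate_ng_cm2_h / max_ng


def in_vivo_reference_rate(ref: InVivoReference) -> float:
    """Mean areal dose rate of the reference inhalation study, ng cm-2 h-1."""
    return units.ug_to_ng(ref.lung_burden) / ref.alveolar_area / ref.exposure_duration


def compare_in_vitro_in_vivo(
    in_vitro_rate: float,
    in_vivo_rate: float,
    comparability_band: tuple[float, float] = (0.5, 2.0),
) -> tuple[float, bool]:
    """Ratio of in-vitro to in-vivo areal dose rate and a comparability call.

    The two rates are "comparable" when the ratio falls inside
    ``comparability_band`` (inclusive).
    """
    if in_vivo_rate <= 0:
        raise ValueError("in_vivo rate must be > 0")
    lo, hi = comparability_band
    if not lo <= hi:
        raise ValueError("comparability_band must satisfy lo <= hi")
    ratio = in_vitro_rate / in_vivo_rate
    return ratio, bool(lo <= ratio <= hi)


def coverage_fraction(
    areal_dose_ng_cm2: float,
    particle_diameter_nm: float = 90.0,
    density_g_cm3: float = 7.3,
) -> float:
    """Fraction of the cell surface covered by deposited particles.

    Projected-area monolayer model: spheres of diameter d deposited at areal
    mass m cover a fraction  (m / sphere_mass) * pi d^2 / 4  =  1.5 m / (rho d)
    of the surface.  The default diameter is the principal ~90 nm aerosol
    mode; a fraction << 1 means far below a monolayer.
    """
    if particle_diameter_nm <= 0 or density_g_cm3 <= 0:
        raise ValueError("diameter and density must be > 0")
    if areal_dose_ng_cm2 < 0:
        raise ValueError("areal dose must be >= 0")
    m_g_cm2 = areal_dose_ng_cm2 * units.G_PER_NG
    d_cm = units.nm_to_cm(particle_diameter_nm)
    return 1.5 * m_g_cm2 / (density_g_cm3 * d_cm)


def build_dose_report(
    cfg: ExposureConfig,
    measured_deposition_rate: float,
    uptake_rate: float | None = None,
    in_vivo: InVivoReference | None = None,
    particle_diameter_nm: float = 90.0,
    density_g_cm3: float = 7.3,
    comparability_band: tuple[float, float] = (0.5, 2.0),
) -> DoseReport:
    """Assemble the full dose report for one exposure condition."""
    max_rate, max_total = maximum_deposition(cfg)
    eff = deposition_efficiency(measured_deposition_rate, max_rate)
    report = DoseReport(
        max_deposition_rate=max_rate,
        max_deposition_total=max_total,
        measured_deposition_rate=measured_deposition_rate,
        efficiency=eff,
        uptake_rate=uptake_rate,
    )
    if eff > 100.0:
        report.notes.append("measured deposition exceeds the theoretical maximum")
    if in_vivo is not None and uptake_rate is not None:
        report.in_vivo_rate = in_vivo_reference_rate(in_vivo)
        ratio, comparable = compare_in_vitro_in_vivo(
            uptake_rate, report.in_vivo_rate, comparability_band
        )
        report.in_vitro_to_in_vivo_ratio = ratio
        report.comparable = comparable
    report.coverage_fraction = coverage_fraction(
        measured_deposition_rate * cfg.exposure_time, particle_diameter_nm, density_g_cm3
    )
    return report
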