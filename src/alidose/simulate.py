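"""Seeded generators for every input the pipeline consumes.

The generators target the statistical structure of the real measurements,
not the underlying physics or biology: Gaussian per-well absorbances with a
plate-level random effect and ~12% well-to-well COV, a medium blank at ~3%
of the control absorbance, a bimodal lognormal aerosol (residual ~20 nm mode
from the nebulized water plus the ~90 nm particle mode), ICP-MS compartment
partitioning with a six-blank background and ~56% of deposited mass
intracellular, and group-separated mass spectra with downregulated lipid
ions in the exposed groups.

One global ``seed`` drives everything; each generator derives an
independent stream by a stable offset, so a fixed seed gives byte-identical
outputs regardless of which generators are called.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .aerosol import SizeDistribution
from .tofsims import Spectrum

__all__ = [
    "SimulationConfig",
    "simulate_plate_readings",
    "simulate_smps_scans",
    "simulate_icpms_study",
    "simulate_tofsims_spectra",
]

_STREAM = {"plates": 1, "smps": 2, "icpms": 3, "tofsims": 4}


def _default_condition_truths() -> dict[str, float]:
    # flow-rate study conditions: 1, 5 and 10 mL/min
    return {"flow_1ml_min": 97.0, "flow_5ml_min": 86.0, "flow_10ml_min": 39.0}


def _default_aerosol_modes() -> list[tuple[float, float, float]]:
    # (geometric mean diameter nm, GSD, total number #/cm3):
    # residual mode from the nebulized water plus the particle mode; totals
    # chosen so the analytic mass is ~1.06 mg/m3 with a ~4% sub-50 nm share
    return [(20.0, 1.45, 7.0e5), (90.0, 1.6, 1.35e5)]


def _default_spectra_groups() -> dict[str, list[tuple[float, float, float]]]:
    # lipid ions (phosphatidylcholines 791/813, phosphatidylethanolamine 777,
    # ceramide 625) downregulated after exposure
    control = [(625.4, 2.0, 0.20), (777.4, 2.5, 0.25), (791.4, 3.0, 0.30), (813.4, 2.2, 0.22)]
    exposed = [(m, 0.55 * mu, 0.10 * 0.55 * mu) for m, mu, _ in control]
    return {"control": control, "exposed_4h": exposed}


def _default_common_peaks() -> list[tuple[float, float, float]]:
    # membrane fragment ions present in every group
    return [(284.3, 8.0, 0.8), (369.4, 6.0, 0.6), (551.5, 4.0, 0.4)]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, defaulting to the study conditions."""

    seed: int = 0
    # plate assay
    n_plates: int = 3
    wells_per_condition: int = 3
    technical_reps_per_well: int = 3
    condition_truths: dict[str, float] = field(default_factory=_default_condition_truths)
    well_cov: float = 0.12
    plate_effect_sd: float = 5.0  # % viability units
    blank_fraction: float = 0.03
    blank_cov: float = 0.075
    replicate_cov: float = 0.0
    control_absorbance_mean: float = 1.0  # AU
    n_blank_wells: int = 3
    abs562_level: float = 0.05  # AU, off-spectrum channel
    abs562_sd: float = 0.002
    # aerosol
    aerosol_modes: list[tuple[float, float, float]] = field(default_factory=_default_aerosol_modes)
    n_smps_scans: int = 9
    scan_gsd: float = 1.1  # scan-to-scan multiplicative factor
    bin_gsd: float = 1.05  # per-bin multiplicative noise
    n_bins: int = 64
    bin_range_nm: tuple[float, float] = (10.0, 1000.0)
    particle_density: float = 7.3
    # ICP-MS
    icpms_blank_mean: float = 0.5  # ng
    icpms_blank_sd: float = 0.05  # ng
    icpms_n_blanks: int = 6
    icpms_noise_cov: float = 0.25
    uptake_rate_true: float = 4.85  # ng cm-2 h-1
    intracellular_fraction_true: float = 0.56
    insert_area_cm2: float = 1.12
    timepoints_h: tuple[float, ...] = (1.0, 2.0, 4.0)
    inserts_per_timepoint: int = 3
    wash_share_of_extracellular: float = 0.6
    # ToF-SIMS
    spectra_groups: dict[str, list[tuple[float, float, float]]] = field(
        default_factory=_default_spectra_groups
    )
    common_peaks: list[tuple[float, float, float]] = field(default_factory=_default_common_peaks)
    spectra_per_group: int = 6

    def __post_init__(self) -> None:
        for name in ("n_plates", "wells_per_condition", "technical_reps_per_well", "n_blank_wells"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        for name in ("well_cov", "plate_effect_sd", "blank_cov", "replicate_cov",
                     "icpms_blank_sd", "icpms_noise_cov", "abs562_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(v < 0 for v in self.condition_truths.values()):
            raise ValueError("condition truths must be >= 0")
        if not 0 <= self.blank_fraction < 1:
            raise ValueError("blank_fraction must be in [0, 1)")
        if self.control_absorbance_mean <= 0:
            raise ValueError("control_absorbance_mean must be > 0")
        for gmd, gsd, total in self.aerosol_modes:
            if gmd <= 0 or total < 0:
                raise ValueError("mode diameters must be > 0 and totals >= 0")
            if gsd <= 1:
                raise ValueError("GSD must be > 1")
        if self.scan_gsd < 1 or self.bin_gsd < 1:
            raise ValueError("noise GSDs must be >= 1")
        if self.uptake_rate_true < 0:
            raise ValueError("uptake_rate_true must be >= 0")
        if not 0 < self.intracellular_fraction_true <= 1:
            raise ValueError("intracellular_fraction_true must be in (0, 1]")
        if not 0 <= self.wash_share_of_extracellular <= 1:
            raise ValueError("wash_share_of_extracellular must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "aerosol_modes" in raw:
            raw["aerosol_modes"] = [tuple(m) for m in raw["aerosol_modes"]]
        if "spectra_groups" in raw:
            raw["spectra_groups"] = {
                g: [tuple(p) for p in peaks] for g, peaks in raw["spectra_groups"].items()
            }
        if "common_peaks" in raw:
            raw["common_peaks"] = [tuple(p) for p in raw["common_peaks"]]
        if "timepoints_h" in raw:
            raw["timepoints_h"] = tuple(raw["timepoints_h"])
        if "bin_range_nm" in raw:
            raw["bin_range_nm"] = tuple(raw["bin_range_nm"])
        return cls(**raw)


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), _STREAM[stream]])


def simulate_plate_readings(config: SimulationConfig) -> pd.DataFrame:
    """Long-format plate table: one row per technical replicate reading.

    Each plate draws a plate effect (viability units) applied to the test
    conditions; the incubator control and blank wells are unaffected so the
    control normalizes to exactly 100% in expectation.  Absorbance noise is
    Gaussian at the measurement level with relative sd ``well_cov`` across
    wells (the viability noise then arises through the normalization).
    """
    rng = _rng(config, "plates")
    blank_mean = config.blank_fraction * config.control_absorbance_mean
    span = config.control_absorbance_mean - blank_mean
    rows = []

    def emit(plate_id: str, date: str, condition: str, insert: int, mean_abs: float,
             rel_sd: float) -> None:
        well_abs = max(0.0, rng.normal(mean_abs, rel_sd * mean_abs)) if mean_abs > 0 else 0.0
        for rep in range(1, config.technical_reps_per_well + 1):
            a = well_abs
            if config.replicate_cov > 0:
                a = max(0.0, a * (1.0 + rng.normal(0.0, config.replicate_cov)))
            a562 = max(0.0, rng.normal(config.abs562_level, config.abs562_sd))
            rows.append(
                {"plate_id": plate_id, "date": date, "condition": condition,
                 "insert_id": f"{condition}_{insert}", "replicate": rep,
                 "abs450": a, "abs562": a562}
            )

    base = pd.Timestamp("2020-01-01")
    for p in range(config.n_plates):
        plate_id = f"P{p + 1}"
        date = (base + pd.Timedelta(days=p)).date().isoformat()
        effect = rng.normal(0.0, config.plate_effect_sd) if config.plate_effect_sd > 0 else 0.0
        for w in range(1, config.wells_per_condition + 1):
            emit(plate_id, date, "incubator_control", w, config.control_absorbance_mean,
                 config.well_cov)
        for w in range(1, config.n_blank_wells + 1):
            emit(plate_id, date, "medium_blank", w, blank_mean, config.blank_cov)
        for condition, truth in config.condition_truths.items():
            mean_abs = blank_mean + (truth + effect) / 100.0 * span
            for w in range(1, config.wells_per_condition + 1):
                emit(plate_id, date, condition, w, max(mean_abs, 0.0), config.well_cov)
    return pd.DataFrame(rows)


def _bin_grid(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = config.bin_range_nm
    if config.n_bins < 1 or lo <= 0 or hi <= lo:
        raise ValueError("invalid bin grid")
    edges = np.geomspace(lo, hi, config.n_bins + 1)
    mids = np.sqrt(edges[:-1] * edges[1:])
    return edges, mids


def simulate_smps_scans(config: SimulationConfig) -> list[SizeDistribution]:
    """SMPS scans on a fixed log-spaced grid.

    Per-bin expected counts integrate the lognormal number density of each
    mode over the bin (CDF differences), so bin totals sum to the configured
    mode totals up to grid truncation.  Noise is multiplicative: one
    lognormal factor per scan (``scan_gsd``) and one per bin (``bin_gsd``).
    """
    if not config.aerosol_modes:
        raise ValueError("need at least one aerosol mode")
    rng = _rng(config, "smps")
    edges, mids = _bin_grid(config)
    log_edges = np.log(edges)
    expected = np.zeros_like(mids)
    for gmd, gsd, total in config.aerosol_modes:
        cdf = norm.cdf(log_edges, loc=np.log(gmd), scale=np.log(gsd))
        expected += total * np.diff(cdf)
    scans = []
    for s in range(config.n_smps_scans):
        scan_factor = rng.lognormal(0.0, np.log(config.scan_gsd)) if config.scan_gsd > 1 else 1.0
        bin_factors = (
            rng.lognormal(0.0, np.log(config.bin_gsd), size=mids.size)
            if config.bin_gsd > 1
            else np.ones_like(mids)
        )
        scans.append(
            SizeDistribution(
                diameters_nm=mids,
                number_concentrations=expected * scan_factor * bin_factors,
                scan_id=f"scan_{s + 1}",
                particle_density=config.particle_density,
            )
        )
    return scans


def simulate_icpms_study(config: SimulationConfig) -> pd.DataFrame:
    """ICP-MS measurement table: six blanks plus cells/wash/basal per insert.

    The blank-corrected compartment sum per area per hour has expectation
    ``uptake_rate_true / intracellular_fraction_true`` (the deposition
    rate), with the cells share equal to ``intracellular_fraction_true``.
    Measured values carry the blank background on top of the true mass.
    """
    rng = _rng(config, "icpms")
    rows = []
    for b in range(1, config.icpms_n_blanks + 1):
        rows.append(
            {"sample_id": f"blank_{b}", "insert_id": f"blank_{b}", "timepoint_h": 0.0,
             "compartment": "blank",
             "ce_mass_ng": rng.normal(config.icpms_blank_mean, config.icpms_blank_sd)}
        )
    deposition_rate = config.uptake_rate_true / config.intracellular_fraction_true
    for t in config.timepoints_h:
        for i in range(1, config.inserts_per_timepoint + 1):
            insert_id = f"t{t:g}h_insert{i}"
            total = deposition_rate * config.insert_area_cm2 * t
            cells = total * config.intracellular_fraction_true
            extra = total - cells
            wash = extra * config.wash_share_of_extracellular
            basal = extra - wash
            for compartment, true_mass in (("cells", cells), ("wash", wash), ("basal", basal)):
                noisy = true_mass
                if config.icpms_noise_cov > 0:
                    noisy = max(0.0, true_mass * (1.0 + rng.normal(0.0, config.icpms_noise_cov)))
                measured = noisy + rng.normal(config.icpms_blank_mean, config.icpms_blank_sd)
                rows.append(
                    {"sample_id": f"{insert_id}_{compartment}", "insert_id": insert_id,
                     "timepoint_h": float(t), "compartment": compartment,
                     "ce_mass_ng": measured}
                )
    return pd.DataFrame(rows)


def simulate_tofsims_spectra(config: SimulationConfig) -> list[Spectrum]:
    """Group-labelled spectra with shared background peaks and group-specific
    lipid peak means; peak intensities are truncated Gaussians."""
    if len(config.spectra_groups) < 1:
        raise ValueError("need at least one spectra group")
    rng = _rng(config, "tofsims")
    spectra = []
    for group in sorted(config.spectra_groups):
        peaks = list(config.common_peaks) + list(config.spectra_groups[group])
        peaks.sort(key=lambda p: p[0])
        mz = np.array([p[0] for p in peaks])
        if np.any(np.diff(mz) <= 0):
            raise ValueError(f"duplicate m/z in group {group!r}")
        for r in range(1, config.spectra_per_group + 1):
            inten = np.array(
                [max(0.0, rng.normal(mu, sd)) for _, mu, sd in peaks]
            )
            spectra.append(
                Spectrum(mz=mz, intensity=inten, group=group, replicate_id=f"{group}_{r}")
            )
    return spectra
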