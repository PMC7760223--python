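"""SMPS number-size-distribution handling and mass conversion.

A scanning mobility particle sizer classifies aerosol particles into
mobility-diameter bins and counts them.  Assuming spherical particles of
known bulk density rho, the mass concentration follows from the number
concentrations N_i (particles per cm3) at bin midpoint diameters d_i:

    M = sum_i N_i * rho * (pi/6) * d_i^3

with d_i converted to cm and the result expressed in mg/m3.  A
diameter cutoff excludes the sub-50 nm residual mode (nebulized-water
background) that cannot be separated from the particle signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks

from . import units

__all__ = [
    "SizeDistribution",
    "mass_concentration",
    "apply_size_cutoff",
    "detect_modes",
    "mean_mass_over_scans",
]

#: CeO2 bulk density, g/cm3.
DEFAULT_PARTICLE_DENSITY = 7.3


@dataclass(frozen=True)
class SizeDistribution:
    """One SMPS scan: bin midpoint diameters (nm) and number concentrations (#/cm3)."""

    diameters_nm: np.ndarray
    number_concentrations: np.ndarray
    scan_id: str = "scan"
    particle_density: float = DEFAULT_PARTICLE_DENSITY

    def __post_init__(self) -> None:
        d = np.asarray(self.diameters_nm, dtype=float)
        n = np.asarray(self.number_concentrations, dtype=float)
        object.__setattr__(self, "diameters_nm", d)
        object.__setattr__(self, "number_concentrations", n)
        if d.ndim != 1 or n.shape != d.shape:
            raise ValueError("diameters and concentrations must be 1-D and equal length")
        if d.size < 1:
            raise ValueError("distribution needs at least one bin")
        if np.any(d <= 0):
            raise ValueError("diameters must be > 0")
        if np.any(np.diff(d) <= 0):
            raise ValueError("diameters must be strictly increasing")
        if self.particle_density <= 0:
            raise ValueError("particle density must be > 0")


def mass_concentration(dist: SizeDistribution) -> float:
    """Total aerosol mass concentration in mg/m3 under the spherical model."""
    n = dist.number_concentrations
    if np.any(n < 0):
        raise ValueError("negative number concentration")
    d_cm = dist.diameters_nm * units.CM_PER_NM
    mass_g_cm3 = float(np.sum(n * dist.particle_density * (math.pi / 6.0) * d_cm**3))
    return mass_g_cm3 * units.MG_M3_PER_G_CM3


def apply_size_cutoff(dist: SizeDistribution, cutoff_nm: float) -> SizeDistribution:
    """Drop bins with midpoint diameter below ``cutoff_nm``.

    Removing bins can only reduce mass; a cutoff of 0 is the identity.
    """
    if cutoff_nm < 0:
        raise ValueError("cutoff must be >= 0")
    keep = dist.diameters_nm >= cutoff_nm
    if not np.any(keep):
        # keep the grid shape degenerate-safe: single zero bin at the cutoff
        return replace(
            dist,
            diameters_nm=np.array([max(cutoff_nm, dist.diameters_nm[-1])]),
            number_concentrations=np.array([0.0]),
        )
    return replace(
        dist,
        diameters_nm=dist.diameters_nm[keep],
        number_concentrations=dist.number_concentrations[keep],
    )


def detect_modes(dist: SizeDistribution, smoothing_window: int = 3) -> list[float]:
    """Diameters (nm) of local maxima of the number distribution, ascending.

    A centered moving average of ``smoothing_window`` bins is applied first;
    window 1 disables smoothing.  Only interior maxima are reported, so a
    flat distribution yields none.
    """
    if dist.diameters_nm.size < 3:
        raise ValueError("need at least 3 bins for mode detection")
    if smoothing_window < 1:
        raise ValueError("smoothing_window must be >= 1")
    y = dist.number_concentrations.astype(float)
    if smoothing_window > 1:
        # edge-replicate padding so the moving average has no boundary dip
        pad = smoothing_window // 2
        padded = np.pad(y, (pad, smoothing_window - 1 - pad), mode="edge")
        kernel = np.ones(smoothing_window) / smoothing_window
        y = np.convolve(padded, kernel, mode="valid")
    peaks, _ = find_peaks(y)
    return [float(dist.diameters_nm[i]) for i in peaks]


def mean_mass_over_scans(
    scans: list[SizeDistribution], cutoff_nm: float | None = None
) -> tuple[float, float]:
    """Mean and sample sd (ddof=1) of per-scan mass concentration, mg/m3.

    An optional diameter cutoff is applied per scan before the mass
    conversion.  With a single scan the sd is reported as 0.
    """
    if not scans:
        raise ValueError("need at least one scan")
    masses = []
    for s in scans:
        if cutoff_nm is not None:
            s = apply_size_cutoff(s, cutoff_nm)
        masses.append(mass_concentration(s))
    arr = np.asarray(masses)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd
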