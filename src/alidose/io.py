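"""Readers and writers for the pipeline's CSV/text dialects.

All formats are plain text: long-format plate CSVs, two-column SMPS scan
exports (optionally in dN/dlogDp convention), long ICP-MS tables and
two-column m/z-intensity spectra with a manifest CSV carrying group labels.
"""

from __future__ import annotations

import glob
import os

import numpy as np
import pandas as pd

from .aerosol import DEFAULT_PARTICLE_DENSITY, SizeDistribution
from .tofsims import Spectrum
from .viability import PLATE_COLUMNS

__all__ = [
    "read_plate_csv",
    "write_plate_csv",
    "read_smps_csv",
    "read_smps_dir",
    "write_smps_csv",
    "read_icpms_csv",
    "write_icpms_csv",
    "read_spectrum_txt",
    "read_spectra_manifest",
]


def read_plate_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"plate_id": str, "insert_id": str, "condition": str})
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def write_plate_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_smps_csv(
    path,
    scan_id: str | None = None,
    density: float = DEFAULT_PARTICLE_DENSITY,
    dndlogdp: bool = False,
) -> SizeDistribution:
    """One scan per file, columns ``diameter_nm, concentration``.

    With ``dndlogdp`` the concentration column is interpreted as dN/dlogDp
    and converted to per-bin counts by multiplying with the local log10 bin
    width (midpoint differences, edge bins extrapolated).
    """
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    try:
        d = df[cols["diameter_nm"]].to_numpy(dtype=float)
        n = df[cols["concentration"]].to_numpy(dtype=float)
    except KeyError as exc:
        raise ValueError(f"{path}: expected columns diameter_nm, concentration") from exc
    if dndlogdp:
        logd = np.log10(d)
        width = np.gradient(logd)
        n = n * width
    sid = scan_id or os.path.splitext(os.path.basename(str(path)))[0]
    return SizeDistribution(diameters_nm=d, number_concentrations=n, scan_id=sid,
                            particle_density=density)


def read_smps_dir(directory, density: float = DEFAULT_PARTICLE_DENSITY,
                  dndlogdp: bool = False) -> list[SizeDistribution]:
    paths = sorted(glob.glob(os.path.join(str(directory), "*.csv")))
    if not paths:
        raise ValueError(f"no scan CSVs in {directory}")
    return [read_smps_csv(p, density=density, dndlogdp=dndlogdp) for p in paths]


def write_smps_csv(dist: SizeDistribution, path) -> None:
    pd.DataFrame(
        {"diameter_nm": dist.diameters_nm, "concentration": dist.number_concentrations}
    ).to_csv(path, index=False)


def read_icpms_csv(path) -> pd.DataFrame:
    """Long ICP-MS table.  Mass is either given directly (``unit == ng``) or
    as a concentration with a volume (``unit == ng/mL`` + ``volume_ml``);
    the conversion to ng happens here at ingest."""
    df = pd.read_csv(path)
    required = {"sample_id", "insert_id", "timepoint_h", "compartment", "value", "unit"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    masses = []
    for row in df.itertuples(index=False):
        unit = str(row.unit).strip()
        if unit == "ng":
            masses.append(float(row.value))
        elif unit in ("ng/mL", "ng/ml"):
            if "volume_ml" not in df.columns or pd.isna(getattr(row, "volume_ml")):
                raise ValueError(f"{path}: ng/mL rows need a volume_ml column")
            masses.append(float(row.value) * float(row.volume_ml))
        else:
            raise ValueError(f"{path}: unsupported unit {unit!r}")
    out = df.copy()
    out["ce_mass_ng"] = masses
    return out


def write_icpms_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_spectrum_txt(path, group: str = "", replicate_id: str = "") -> Spectrum:
    """Two-column whitespace- or comma-separated m/z intensity text."""
    arr = np.loadtxt(path, delimiter=None if _is_whitespace(path) else ",")
    arr = np.atleast_2d(arr)
    if arr.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (m/z, intensity)")
    order = np.argsort(arr[:, 0])
    rid = replicate_id or os.path.splitext(os.path.basename(str(path)))[0]
    return Spectrum(mz=arr[order, 0], intensity=arr[order, 1], group=group, replicate_id=rid)


def _is_whitespace(path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "," not in line
    return True


def read_spectra_manifest(manifest_path) -> list[Spectrum]:
    """Manifest CSV with columns ``path, group``; paths relative to the manifest."""
    df = pd.read_csv(manifest_path)
    if not {"path", "group"} <= set(df.columns):
        raise ValueError(f"{manifest_path}: manifest needs 'path' and 'group' columns")
    base = os.path.dirname(os.path.abspath(str(manifest_path)))
    spectra = []
    for row in df.itertuples(index=False):
        p = row.path if os.path.isabs(str(row.path)) else os.path.join(base, str(row.path))
        spectra.append(read_spectrum_txt(p, group=str(row.group)))
    return spectra
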