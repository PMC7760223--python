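"""Centralized unit conversions.

Canonical internal units across the package: mass in ng, area in cm2,
time in h, flow in mL/min, aerosol concentration in mg/m3, diameters in nm,
particle density in g/cm3.  Every cross-unit step goes through the constants
and helpers here so the arithmetic is property-testable in one place.
"""

# 1 mg/m3 == 1 ug/L == 1 ng/mL
NG_PER_ML_PER_MG_M3 = 1.0

MIN_PER_H = 60.0

NG_PER_UG = 1.0e3
UG_PER_NG = 1.0e-3
NG_PER_G = 1.0e9
G_PER_NG = 1.0e-9

CM_PER_NM = 1.0e-7

# 1 g/cm3 == 1e9 mg/m3
MG_M3_PER_G_CM3 = 1.0e9


def mg_m3_to_ng_ml(c_mg_m3: float) -> float:
    """Aerosol mass concentration mg/m3 -> ng per mL of sampled air."""
    return c_mg_m3 * NG_PER_ML_PER_MG_M3


def nm_to_cm(d_nm: float) -> float:
    return d_nm * CM_PER_NM


def ng_to_ug(m_ng: float) -> float:
    return m_ng * UG_PER_NG


def ug_to_ng(m_ug: float) -> float:
    return m_ug * NG_PER_UG
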