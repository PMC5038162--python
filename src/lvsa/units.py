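"""Unit conversion constants.

All internal computation is in CGS (cm, g, s; pressure in dyn cm^-2).
Conversions to clinical units (mmHg, kPa, mL, cJ) happen only at I/O and
index-reporting boundaries.
"""

MMHG = 1333.22  # dyn cm^-2 per mmHg
KPA = 1.0e4  # dyn cm^-2 per kPa
MMHG_ML_TO_CJ = 1.33322e-2  # 1 mmHg*mL = 133.322 Pa * 1e-6 m^3 = 1.33322e-4 J


def mmhg_to_cgs(p: float) -> float:
    return p * MMHG


def cgs_to_mmhg(p: float) -> float:
    return p / MMHG


def kpa_to_cgs(p: float) -> float:
    return p * KPA


def cgs_to_kpa(p: float) -> float:
    return p / KPA
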