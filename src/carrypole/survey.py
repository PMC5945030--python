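"""Reference survey of 14 traditional bamboo carrying poles.

Bench measurements for the four lab-characterised poles (C-F: CT-scanned,
load-deflection tested and resonance tested) and the ten field-surveyed
poles (A, B, G-N: hand-measured geometry plus resonance tests at a
Vietnamese farm site).  These published summary values serve as inputs for
the model-based property derivations and as ground truth in validation.

Units follow the field conventions: geometry in mm (second moment in
10^4 mm^4), length in m, mass in kg, stiffness in kN m^-1, modulus in GPa,
damping coefficient in N s m^-1, hysteresis in percent.  The deflection
surface coefficient ``a`` is in 10^-4 s^2 kg^-1 m^-3.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import BASKET_MASS

__all__ = [
    "lab_poles",
    "field_poles",
    "all_poles",
    "load_schedule",
    "LOAD_STEP_KG",
    "N_LOAD_LEVELS",
]

#: Nominal per-end load increment (one lead weight), kg.
LOAD_STEP_KG = 2.225

#: Number of load increments in the resonance/deflection protocol.
N_LOAD_LEVELS = 9

# Lab-characterised poles: geometry from CT (mean over the internode centre
# region, SD across slices), a from the deflection-surface regression
# (95% CI), damping from ring-down analysis, hysteresis from loop areas.
_LAB = [
    # id, mass, I_zzc(e4 mm4), I_sd, width, height, R, length,
    #   a(e-4), a_lo, a_hi, k(kN/m), E(GPa), c(N s/m), zeta, zeta_sd, hys(%)
    ("C", 0.70, 1.028, 0.059, 61.4, 17.9, 35.3, 1.550,
     7.29, 7.25, 7.34, 1.47, 22.2, 2.77, 0.011, 0.019, 9.4),
    ("D", 0.83, 1.538, 0.058, 60.6, 22.5, 31.7, 1.573,
     5.14, 5.12, 5.16, 2.00, 21.1, 2.77, 0.010, 0.016, 3.2),
    ("E", 0.73, 1.322, 0.052, 58.2, 19.4, 31.5, 1.527,
     8.56, 8.53, 8.60, 1.31, 14.7, 3.41, 0.013, 0.032, 9.6),
    ("F", 0.98, 2.740, 0.117, 55.7, 25.0, 28.0, 1.409,
     3.98, 3.94, 4.02, 3.59, 15.3, 3.56, 0.010, 0.022, 2.9),
]

# Field-surveyed poles: hand-measured geometry; k from the inverse resonance
# fit (95% CI); E back-computed from k and the partial-tube second moment.
_FIELD = [
    # id, mass, I_zzc(e4 mm4), width, height, R, length,
    #   k(kN/m), k_lo, k_hi, E(GPa), c(N s/m), zeta, zeta_sd
    ("A", 0.85, 1.862, 60.0, 22.0, 31.5, 1.297, 2.46, 1.20, 4.16, 11.2, 3.92, 0.012, 0.012),
    ("B", 0.85, 1.422, 59.0, 20.0, 31.8, 1.256, 2.99, 1.80, 4.48, 10.1, 4.24, 0.012, 0.010),
    ("G", 0.90, 1.191, 62.0, 18.0, 35.7, 1.237, 2.50, 0.95, 4.78, 16.5, 3.45, 0.011, 0.034),
    ("H", 0.94, 1.689, 61.0, 21.0, 32.7, 1.272, 3.28, 1.25, 6.29, 16.7, 5.51, 0.014, 0.020),
    ("I", 0.94, 1.650, 60.0, 21.0, 31.9, 1.424, 1.83, 1.25, 2.52, 13.3, 4.02, 0.015, 0.015),
    ("J", 0.76, 1.078, 48.0, 20.0, 24.4, 1.255, 2.75, 1.91, 3.75, 21.0, 5.23, 0.015, 0.011),
    ("K", 0.81, 1.905, 61.0, 22.0, 32.1, 1.305, 3.42, 2.29, 4.76, 16.6, 4.63, 0.012, 0.010),
    ("L", 1.00, 2.254, 58.0, 24.0, 29.5, 1.348, 4.18, 3.09, 5.44, 18.9, 7.28, 0.018, 0.042),
    ("M", 0.90, 1.698, 56.0, 22.0, 28.8, 1.395, 2.65, 1.84, 3.59, 17.6, 3.68, 0.011, 0.010),
    ("N", 0.93, 1.318, 61.0, 19.0, 34.0, 1.296, 2.66, 1.80, 3.69, 18.3, 4.34, 0.013, 0.040),
]


def lab_poles() -> pd.DataFrame:
    """Bench measurements of the four lab-characterised poles (C-F)."""
    cols = [
        "pole_id", "mass_kg", "I_zzc_e4mm4", "I_zzc_sd_e4mm4", "width_mm",
        "height_mm", "outer_radius_mm", "length_m", "a_e-4", "a_ci_lo_e-4",
        "a_ci_hi_e-4", "k_kN_per_m", "E_GPa", "c_Ns_per_m", "zeta_median",
        "zeta_sd", "hysteresis_pct",
    ]
    df = pd.DataFrame(_LAB, columns=cols)
    df["cohort"] = "lab"
    return df


def field_poles() -> pd.DataFrame:
    """Farm-site measurements of the ten field-surveyed poles."""
    cols = [
        "pole_id", "mass_kg", "I_zzc_e4mm4", "width_mm", "height_mm",
        "outer_radius_mm", "length_m", "k_kN_per_m", "k_ci_lo_kN_per_m",
        "k_ci_hi_kN_per_m", "E_GPa", "c_Ns_per_m", "zeta_median", "zeta_sd",
    ]
    df = pd.DataFrame(_FIELD, columns=cols)
    df["cohort"] = "field"
    return df


def all_poles() -> pd.DataFrame:
    """Both cohorts in one table (columns unioned; missing values NaN)."""
    return pd.concat([lab_poles(), field_poles()], ignore_index=True)


def load_schedule(basket_mass: float = BASKET_MASS) -> np.ndarray:
    """Per-end load masses of the test protocol, kg (basket tare included).

    Nine lead weights of 2.225 kg each were added per end on top of the
    0.480 kg basket: m_n = basket + n * 2.225 for n = 1..9.
    """
    return basket_mass + LOAD_STEP_KG * np.arange(1, N_LOAD_LEVELS + 1)
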