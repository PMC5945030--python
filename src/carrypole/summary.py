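"""Per-pole property records and cohort statistics.

Collates the outputs of the geometry, deflection, vibration and dynamics
stages into one record per pole (the row of a property-summary table) and
compares the lab and field cohorts: arithmetic means, sample standard
deviations, and percent differences relative to the lab mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PoleRecord",
    "GroupSummary",
    "MissingStageError",
    "summarize_pole",
    "group_stats",
    "records_to_frame",
    "export_report",
]

#: Stage outputs each cohort's pathway must supply.
_REQUIRED = {
    "lab": ("geometry", "deflection", "vibration"),
    "field": ("geometry", "vibration", "resonance_fit"),
}


class MissingStageError(ValueError):
    """A mandatory analysis stage output is absent for the pole's cohort."""


@dataclass(frozen=True)
class PoleRecord:
    """One pole's assembled properties, in reporting units.

    Geometry in mm (second moment in 10^4 mm^4), length in m, stiffness in
    kN m^-1, modulus in GPa, damping coefficient in N s m^-1.  Field poles
    carry a stiffness CI (from the inverse resonance fit) and no hysteresis
    (loop testing needs the bench rig).
    """

    pole_id: str
    cohort: str
    mass_kg: float
    length_m: float
    width_mm: float
    height_mm: float
    outer_radius_mm: float | None
    I_zzc_e4mm4: float
    I_zzc_sd_e4mm4: float | None
    E_GPa: float
    k_kN_per_m: float
    k_ci_kN_per_m: tuple[float, float] | None
    c_Ns_per_m: float
    zeta_median: float
    zeta_sd: float | None
    hysteresis_pct: float | None

    def __post_init__(self) -> None:
        if self.cohort not in ("lab", "field"):
            raise ValueError(f"unknown cohort {self.cohort!r}")
        if self.cohort == "field" and self.hysteresis_pct is not None:
            raise ValueError("field poles carry no hysteresis value")


@dataclass(frozen=True)
class GroupSummary:
    """Cohort comparison for one property."""

    property_name: str
    lab_mean: float
    lab_sd: float
    field_mean: float
    field_sd: float
    percent_difference: float


def summarize_pole(
    pole_id: str,
    cohort: str,
    *,
    mass_kg: float,
    length_m: float,
    geometry=None,
    deflection=None,
    vibration=None,
    resonance_fit=None,
    hysteresis=None,
    width_mm: float | None = None,
    height_mm: float | None = None,
    outer_radius_mm: float | None = None,
) -> PoleRecord:
    """Assemble one pole's record from its stage outputs.

    Parameters mirror the analysis pathway: ``geometry`` supplies the
    centroidal second moment (dict with ``I_zzc_mm4`` and optionally
    ``I_zzc_sd_mm4``, mm^4); ``deflection`` a :class:`~carrypole.deflection.
    DeflectionFit` with Young's modulus attached (lab pathway);
    ``vibration`` the pole's damping summary (dict with ``zeta_median`` and
    optionally ``zeta_sd``); ``resonance_fit`` a :class:`~carrypole.dynamics.
    DynamicsModel` from the inverse fit (field pathway); ``hysteresis`` a
    :class:`~carrypole.deflection.HysteresisResult` (lab only).  ``c`` is
    the load-schedule mean damping coefficient and must be precomputed into
    the vibration summary as ``c_mean``.
    """
    if cohort not in _REQUIRED:
        raise ValueError(f"unknown cohort {cohort!r}")
    stages = {
        "geometry": geometry,
        "deflection": deflection,
        "vibration": vibration,
        "resonance_fit": resonance_fit,
    }
    for name in _REQUIRED[cohort]:
        if stages[name] is None:
            raise MissingStageError(f"{cohort} pole {pole_id}: missing stage {name!r}")

    izzc_mm4 = float(geometry["I_zzc_mm4"])
    izzc_sd = geometry.get("I_zzc_sd_mm4")
    I_m4 = izzc_mm4 * 1e-12

    if cohort == "lab":
        from .deflection import young_modulus
        from .dynamics import spring_constant

        E = deflection.E if deflection.E is not None else young_modulus(deflection.a, I_m4)
        k = spring_constant(E, I_m4, deflection.x_L)
        k_ci = None
    else:
        k = resonance_fit.k
        E = k * resonance_fit.x_L**3 / (3.0 * I_m4) if resonance_fit.x_L else np.nan
        if resonance_fit.k_se is not None:
            k_ci = (
                (k - 1.96 * resonance_fit.k_se) / 1e3,
                (k + 1.96 * resonance_fit.k_se) / 1e3,
            )
        else:
            k_ci = None

    return PoleRecord(
        pole_id=pole_id,
        cohort=cohort,
        mass_kg=mass_kg,
        length_m=length_m,
        width_mm=width_mm if width_mm is not None else np.nan,
        height_mm=height_mm if height_mm is not None else np.nan,
        outer_radius_mm=outer_radius_mm,
        I_zzc_e4mm4=izzc_mm4 / 1e4,
        I_zzc_sd_e4mm4=(izzc_sd / 1e4) if izzc_sd is not None else None,
        E_GPa=E / 1e9,
        k_kN_per_m=k / 1e3,
        k_ci_kN_per_m=k_ci,
        c_Ns_per_m=float(vibration["c_mean"]),
        zeta_median=float(vibration["zeta_median"]),
        zeta_sd=vibration.get("zeta_sd"),
        hysteresis_pct=(hysteresis.hysteresis * 100.0) if hysteresis is not None else None,
    )


def records_to_frame(records) -> pd.DataFrame:
    """Records as a tidy table with units in the column names."""
    rows = []
    for r in records:
        d = asdict(r)
        ci = d.pop("k_ci_kN_per_m")
        d["k_ci_lo_kN_per_m"] = ci[0] if ci else np.nan
        d["k_ci_hi_kN_per_m"] = ci[1] if ci else np.nan
        rows.append(d)
    cols = [
        "pole_id", "cohort", "mass_kg", "length_m", "width_mm", "height_mm",
        "outer_radius_mm", "I_zzc_e4mm4", "I_zzc_sd_e4mm4", "E_GPa",
        "k_kN_per_m", "k_ci_lo_kN_per_m", "k_ci_hi_kN_per_m", "c_Ns_per_m",
        "zeta_median", "zeta_sd", "hysteresis_pct",
    ]
    return pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)


def group_stats(records_or_frame, property_name: str) -> GroupSummary:
    """Cohort means/SDs and percent difference for one property column.

    Sample standard deviations use the n-1 denominator; the percent
    difference is ``|field - lab| / lab * 100`` (lab mean as reference,
    the directly-measured cohort).
    """
    df = (
        records_or_frame
        if isinstance(records_or_frame, pd.DataFrame)
        else records_to_frame(records_or_frame)
    )
    if property_name not in df.columns:
        raise KeyError(f"unknown property {property_name!r}")
    out = {}
    for cohort in ("lab", "field"):
        vals = df.loc[df["cohort"] == cohort, property_name].dropna().to_numpy(float)
        if vals.size == 0:
            raise ValueError(f"no {cohort} values for {property_name!r}")
        out[cohort] = (
            float(np.mean(vals)),
            float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
        )
    lab_mean, lab_sd = out["lab"]
    field_mean, field_sd = out["field"]
    pct = abs(field_mean - lab_mean) / abs(lab_mean) * 100.0
    return GroupSummary(
        property_name=property_name,
        lab_mean=lab_mean,
        lab_sd=lab_sd,
        field_mean=field_mean,
        field_sd=field_sd,
        percent_difference=pct,
    )


def export_report(records, summaries, out_dir, run_info: dict | None = None) -> dict:
    """Write per-pole and cohort tables plus a structured run log.

    Produces ``poles.csv`` (one row per pole, deterministic column order),
    ``group_summary.csv`` and ``run_log.json``; returns the paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    poles_path = out / "poles.csv"
    records_to_frame(records).to_csv(poles_path, index=False)
    groups_path = out / "group_summary.csv"
    pd.DataFrame([asdict(s) for s in summaries]).to_csv(groups_path, index=False)
    log_path = out / "run_log.json"
    log = {
        "n_poles": len(list(records)),
        "n_summaries": len(list(summaries)),
        **(run_info or {}),
    }
    log_path.write_text(json.dumps(log, indent=2, default=str))
    return {"poles": poles_path, "groups": groups_path, "log": log_path}
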