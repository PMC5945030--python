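"""Synthetic pole data with known ground truth.

Raw bench data (inertial-sensor traces, digitised video, CT meshes) are bulky
supplementary downloads, so every analysis stage is validated instead on
generated inputs whose true parameters are known:

* **Vibration traces** — the exact underdamped step response of
  ``m y'' + c y' + k y = m g`` released from rest at the neutral position,

      y(t) = d_st * [1 - e^(-zeta w_n t) (cos w_d t + zeta/sqrt(1-zeta^2) sin w_d t)]

  with ``d_st = m g / k``; the analytic acceleration plus seeded Gaussian
  sensor noise is returned.

* **Deflection surfaces** — beam-theory deflections
  ``delta = a (3 m g x_L x^2 - m g x^3)`` with additive marker noise; the
  unloading branch is scaled by ``(1 + offset)`` in deflection, producing a
  loop whose analytic area ratio is ``offset / (1 + offset)``.

* **Cross-section meshes** — a lofted partial-tube whose chord cut opens the
  lumen, giving a single C-shaped contour per slice (watertight, fixed
  topology); growth nodes are local lumen constrictions (wall thickenings)
  and the ends taper linearly.  The analytic section properties at every
  station are attached as ground truth.

``gen_pole`` ties the three together into one internally consistent bundle:
the window-mean second moment of the generated geometry fixes the flexural
rigidity that drives both the deflection surface and the vibration traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import trimesh

from .config import DEFAULT_R_RATIO, GRAVITY
from .geometry import PartialTubeSpec, partial_tube_second_moment
from .survey import load_schedule
from .vibration import VibrationTrial

__all__ = [
    "SyntheticPoleSpec",
    "SyntheticVibration",
    "SyntheticDeflection",
    "SyntheticPoleBundle",
    "gen_vibration_trace",
    "gen_deflection_dataset",
    "gen_cross_section_mesh",
    "gen_pole",
    "hysteresis_offset_for",
]


@dataclass(frozen=True)
class SyntheticPoleSpec:
    """Ground-truth parameters of a generated pole.

    Geometry in mm, length/lever arms in m, modulus in Pa.  Defaults emulate
    a typical surveyed pole: 18 GPa bamboo, a 31.5 mm outer radius partial
    tube of height 22 mm with ``r = 0.73 R``, 1.40 m long with the
    functional centre biased toward the front end, damping ratio 0.011,
    growth nodes every 300 mm and a 3% end taper.
    """

    E: float = 18.0e9
    r_ratio: float = DEFAULT_R_RATIO
    R: float = 31.5
    h: float = 22.0
    length: float = 1.40
    x_L_front: float = 0.65
    x_L_back: float = 0.75
    zeta: float = 0.011
    node_spacing: float = 300.0
    node_thickening: float = 0.5
    node_width: float = 30.0
    taper: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("E", "R", "h", "length", "x_L_front", "x_L_back",
                     "node_spacing", "node_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.zeta < 1.0):
            raise ValueError("zeta must lie in [0, 1) (underdamped)")
        if not (0.0 <= self.r_ratio < 1.0):
            raise ValueError("r_ratio must lie in [0, 1)")
        if not (0.0 <= self.node_thickening < 1.0):
            raise ValueError("node_thickening must lie in [0, 1)")
        if not (0.0 <= self.taper < 0.5):
            raise ValueError("taper must lie in [0, 0.5)")
        if self.h >= self.R + self.r_ratio * self.R:
            raise ValueError("chord must cut above the inner circle bottom (h < R + r)")
        if self.h <= self.R - self.r_ratio * self.R:
            raise ValueError(
                "chord must open the lumen (h > R - r) for a single-contour section"
            )

    @property
    def section(self) -> PartialTubeSpec:
        """Nominal (untapered, internode) cross-section."""
        return PartialTubeSpec(
            outer_radius=self.R, inner_radius=self.r_ratio * self.R, height=self.h
        )

    @property
    def I_zzc_nominal_m4(self) -> float:
        """Centroidal second moment of the nominal section, m^4."""
        return partial_tube_second_moment(self.section).I_zzc * 1e-12


@dataclass(frozen=True)
class SyntheticVibration:
    """A generated ring-down trial with its generating parameters."""

    trial: VibrationTrial
    omega_d: float  # rad s^-1
    zeta: float
    k: float  # N m^-1
    displacement: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class SyntheticDeflection:
    """Generated load-deflection records with the true surface coefficient."""

    records: tuple
    a: float
    x_L: float
    hysteresis_offset: float

    @property
    def hysteresis_true(self) -> float:
        """Analytic loop-area ratio implied by the unloading offset."""
        return self.hysteresis_offset / (1.0 + self.hysteresis_offset)


def hysteresis_offset_for(hys: float) -> float:
    """Unloading deflection offset producing a given analytic loop-area ratio."""
    if not (0.0 <= hys < 1.0):
        raise ValueError("hysteresis must lie in [0, 1)")
    return hys / (1.0 - hys)


def gen_vibration_trace(
    spec: SyntheticPoleSpec,
    load_mass: float,
    fs: float = 100.0,
    duration: float = 30.0,
    noise_sd: float | None = None,
    k: float | None = None,
    rng: np.random.Generator | None = None,
    end_label: str = "front",
    pole_id: str = "synthetic",
) -> SyntheticVibration:
    """Analytic underdamped ring-down acceleration plus sensor noise.

    ``k`` defaults to the cantilever stiffness of the nominal section at the
    front lever arm; ``noise_sd`` (m s^-2) defaults to 1% of the peak
    acceleration amplitude.  The returned bundle carries the true damped
    frequency, damping ratio and stiffness.
    """
    if load_mass <= 0:
        raise ValueError("load_mass must be positive")
    if not (0.0 <= spec.zeta < 1.0):
        raise ValueError("underdamped response requires zeta < 1")
    if k is None:
        k = 3.0 * spec.E * spec.I_zzc_nominal_m4 / spec.x_L_front**3
    zeta = spec.zeta
    omega_n = np.sqrt(k / load_mass)
    omega_d = omega_n * np.sqrt(1.0 - zeta**2)
    sigma = zeta * omega_n
    d_st = load_mass * GRAVITY / k

    t = np.arange(0.0, duration, 1.0 / fs)
    env = np.exp(-sigma * t)
    # y'' of the step response; y(0)=0, y'(0)=0, y''(0)=g
    acc = d_st * (omega_n**2 / omega_d) * env * (
        omega_d * np.cos(omega_d * t) - sigma * np.sin(omega_d * t)
    )
    disp = d_st * (1.0 - env * (np.cos(omega_d * t) + (sigma / omega_d) * np.sin(omega_d * t)))
    if noise_sd is None:
        noise_sd = 0.01 * d_st * omega_n**2
    if noise_sd > 0:
        rng = rng if rng is not None else np.random.default_rng(spec.seed)
        acc = acc + rng.normal(0.0, noise_sd, size=t.size)
    trial = VibrationTrial(
        time=t, acceleration=acc, load_mass=load_mass,
        pole_id=pole_id, end_label=end_label,
    )
    return SyntheticVibration(
        trial=trial, omega_d=omega_d, zeta=zeta, k=k, displacement=disp
    )


def gen_deflection_dataset(
    spec: SyntheticPoleSpec,
    loads=None,
    marker_positions=None,
    noise_sd: float = 0.0,
    hysteresis_offset: float = 0.0,
    a: float | None = None,
    x_L: float | None = None,
    rng: np.random.Generator | None = None,
    end_label: str = "front",
) -> SyntheticDeflection:
    """Beam-theory deflection records for a loading/unloading cycle.

    Loading deflections follow ``delta = a (3 m g x_L x^2 - m g x^3)``;
    unloading deflections are scaled by ``(1 + hysteresis_offset)``.
    ``noise_sd`` (m) is added to every marker reading.  The true ``a``
    defaults to ``1 / (6 E I)`` of the nominal section.
    """
    from .deflection import DeflectionRecord

    x_L = x_L if x_L is not None else spec.x_L_front
    if a is None:
        a = 1.0 / (6.0 * spec.E * spec.I_zzc_nominal_m4)
    if hysteresis_offset < 0:
        raise ValueError("hysteresis_offset must be nonnegative")
    loads = np.asarray(load_schedule() if loads is None else loads, dtype=float)
    if marker_positions is None:
        marker_positions = np.linspace(x_L / 12.0, x_L, 12)
    marker_positions = np.asarray(marker_positions, dtype=float)
    if np.any(marker_positions > x_L * (1 + 1e-9)):
        raise ValueError("marker beyond the load attachment x_L")
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    records = []
    for phase, scale in (("loading", 1.0), ("unloading", 1.0 + hysteresis_offset)):
        for m in loads:
            for x in marker_positions:
                delta = scale * a * (3.0 * m * GRAVITY * x_L * x**2 - m * GRAVITY * x**3)
                if noise_sd > 0:
                    delta += rng.normal(0.0, noise_sd)
                records.append(
                    DeflectionRecord(
                        load_mass=float(m), marker_distance=float(x),
                        deflection=float(delta), phase=phase, end_label=end_label,
                    )
                )
    return SyntheticDeflection(
        records=tuple(records), a=a, x_L=x_L, hysteresis_offset=hysteresis_offset
    )


# ---------------------------------------------------------------------------
# Mesh generation
# ---------------------------------------------------------------------------


def _axial_profiles(spec: SyntheticPoleSpec, stations: np.ndarray):
    """Per-station (scale, inner-radius) profiles along the pole, mm.

    The whole section scales linearly from 1 at midlength to ``1 - taper``
    at the ends; at growth nodes the lumen constricts by
    ``node_thickening`` over a cosine bump of ``node_width``, clamped so the
    chord still cuts the lumen open (fixed slice topology).
    """
    L = spec.length * 1e3
    s = 1.0 - spec.taper * (2.0 * np.abs(stations - L / 2.0) / L)
    r0 = spec.r_ratio * spec.R
    bump = np.zeros_like(stations)
    node_positions = np.arange(spec.node_spacing / 2.0, L, spec.node_spacing)
    for x0 in node_positions:
        d = np.abs(stations - x0)
        inside = d < spec.node_width / 2.0
        bump[inside] = np.maximum(
            bump[inside], 0.5 * (1.0 + np.cos(2.0 * np.pi * d[inside] / spec.node_width))
        )
    r = s * r0 * (1.0 - spec.node_thickening * bump)
    # keep the lumen open at the chord: r must exceed the chord depth R - h
    r_min = 1.05 * s * (spec.R - spec.h)
    return s, np.maximum(r, r_min), node_positions


def _section_ring(R: float, r: float, h_frac_chord: float, n_arc: int):
    """Closed boundary polygon of the partial-tube section, (z, y) mm.

    ``h_frac_chord`` is the chord height y = -(R - h) in the same scale as
    R, r.  Outer arc left-to-right, then inner arc right-to-left.
    """
    c = h_frac_chord
    t_o = np.arccos(np.clip(-c / R, -1.0, 1.0))
    t_i = np.arccos(np.clip(-c / r, -1.0, 1.0))
    to = np.linspace(-t_o, t_o, n_arc)
    ti = np.linspace(t_i, -t_i, n_arc)
    outer = np.column_stack([R * np.sin(to), -R * np.cos(to)])
    inner = np.column_stack([r * np.sin(ti), -r * np.cos(ti)])
    return np.vstack([outer, inner])


def gen_cross_section_mesh(
    spec: SyntheticPoleSpec,
    station_interval: float = 5.0,
    n_arc: int = 64,
) -> tuple[trimesh.Trimesh, pd.DataFrame]:
    """Lofted partial-tube pole mesh plus analytic per-station ground truth.

    The mesh axis is x (mm), vertical y, horizontal z.  Returns the
    watertight surface and a table of the analytic section properties
    (area, I_zzc) at every loft station.
    """
    if station_interval <= 0:
        raise ValueError("station_interval must be positive")
    if n_arc < 8:
        raise ValueError("need at least 8 arc points per side")
    L = spec.length * 1e3
    stations = np.arange(0.0, L + 1e-9, station_interval)
    s, r, _ = _axial_profiles(spec, stations)

    rings = []
    truth_rows = []
    for x, si, ri in zip(stations, s, r):
        Ri, hi = si * spec.R, si * spec.h
        chord = -(Ri - hi)
        ring = _section_ring(Ri, ri, chord, n_arc)
        pts = np.column_stack([np.full(len(ring), x), ring[:, 1], ring[:, 0]])
        rings.append(pts)
        p = partial_tube_second_moment(
            PartialTubeSpec(outer_radius=Ri, inner_radius=ri, height=hi)
        )
        truth_rows.append(
            {"axial_position_mm": x, "area_mm2": p.area, "Izzc_mm4": p.I_zzc}
        )

    P = 2 * n_arc
    vertices = np.vstack(rings)
    faces = []
    n_rings = len(rings)
    for j in range(n_rings - 1):
        base, nxt = j * P, (j + 1) * P
        for kk in range(P):
            a0, a1 = base + kk, base + (kk + 1) % P
            b0, b1 = nxt + kk, nxt + (kk + 1) % P
            faces.append([a0, a1, b1])
            faces.append([a0, b1, b0])
    # end caps: strip between outer arc point k and inner arc point k
    for ring_idx, flip in ((0, False), (n_rings - 1, True)):
        base = ring_idx * P
        for kk in range(n_arc - 1):
            o0, o1 = base + kk, base + kk + 1
            i0, i1 = base + P - 1 - kk, base + P - 2 - kk
            tris = [[o0, o1, i1], [o0, i1, i0]]
            if flip:
                tris = [t[::-1] for t in tris]
            faces.extend(tris)

    mesh = trimesh.Trimesh(vertices=vertices, faces=np.asarray(faces), process=False)
    trimesh.repair.fix_normals(mesh)
    truth = pd.DataFrame(truth_rows)
    return mesh, truth


# ---------------------------------------------------------------------------
# End-to-end bundle
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticPoleBundle:
    """Internally consistent synthetic pole: mesh, deflection set, ring-downs.

    ``truth`` collects the generating parameters: window-mean second moment
    (m^4), surface coefficient ``a``, stiffness ``k`` (front end), damping
    ratio and the per-load damped frequencies.
    """

    spec: SyntheticPoleSpec
    mesh: trimesh.Trimesh
    slice_truth: pd.DataFrame
    deflection: SyntheticDeflection
    vibration: tuple
    truth: dict


def gen_pole(
    spec: SyntheticPoleSpec | None = None,
    loads=None,
    fs: float = 100.0,
    duration: float = 30.0,
    accel_noise_sd: float | None = None,
    deflection_noise_sd: float = 2e-4,
    hysteresis_offset: float | None = None,
    station_interval: float = 5.0,
    n_arc: int = 64,
    axial_window: tuple[float, float] = (0.40, 0.60),
) -> SyntheticPoleBundle:
    """Generate a full, internally consistent test pole.

    The flexural rigidity driving the deflection surface and the vibration
    traces is computed from the *generated geometry*: the mean analytic
    ``I_zzc`` over the configured axial window (the internode centre region
    convention), so every downstream stage can be checked against a single
    parameter set.  Per-end masses default to the nine-level test schedule.
    All randomness derives from ``spec.seed``.
    """
    spec = spec if spec is not None else SyntheticPoleSpec()
    loads = np.asarray(load_schedule() if loads is None else loads, dtype=float)
    if hysteresis_offset is None:
        hysteresis_offset = hysteresis_offset_for(0.05)

    mesh, slice_truth = gen_cross_section_mesh(
        spec, station_interval=station_interval, n_arc=n_arc
    )
    x = slice_truth["axial_position_mm"]
    lo = x.min() + axial_window[0] * (x.max() - x.min())
    hi = x.min() + axial_window[1] * (x.max() - x.min())
    I_mm4 = float(slice_truth.loc[(x >= lo) & (x <= hi), "Izzc_mm4"].mean())
    I_m4 = I_mm4 * 1e-12
    a = 1.0 / (6.0 * spec.E * I_m4)
    k = 3.0 * spec.E * I_m4 / spec.x_L_front**3

    seq = np.random.SeedSequence(spec.seed)
    rng_defl, rng_vib = (np.random.default_rng(s) for s in seq.spawn(2))
    deflection = gen_deflection_dataset(
        spec,
        loads=loads,
        noise_sd=deflection_noise_sd,
        hysteresis_offset=hysteresis_offset,
        a=a,
        x_L=spec.x_L_front,
        rng=rng_defl,
    )
    vibration = tuple(
        gen_vibration_trace(
            spec, load_mass=float(m), fs=fs, duration=duration,
            noise_sd=accel_noise_sd, k=k, rng=rng_vib,
        )
        for m in loads
    )
    truth = {
        "E": spec.E,
        "I_m4": I_m4,
        "a": a,
        "k": k,
        "zeta": spec.zeta,
        "loads_kg": loads,
        "frequency_hz": np.array([v.omega_d / (2 * np.pi) for v in vibration]),
        "axial_window": axial_window,
    }
    return SyntheticPoleBundle(
        spec=spec, mesh=mesh, slice_truth=slice_truth,
        deflection=deflection, vibration=vibration, truth=truth,
    )
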