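"""Cross-sectional properties of carrying poles.

Two routes to the second moment of area are provided, matching the two ways
pole geometry is captured in practice:

* **Mesh slices** — a CT-derived (or synthetic) surface mesh is cut at regular
  axial stations; each planar contour is treated as a polygon and its area,
  centroid and second moment about the horizontal axis follow from the
  shoelace-moment sums.  Hollow sections are handled as an outer contour minus
  lumen contour(s).

* **Partial-tube model** — a hand-measured section (width and height at the
  functional centre) is idealised as the bottom portion of a hollow tube: the
  region between two concentric circles of radii ``R`` and ``r`` cut by a
  horizontal chord at height ``h`` above the lowest point.  The inner radius,
  unobservable by hand, is taken proportional to the outer one
  (``r = 0.73 R`` by default).

Coordinates in the section plane are ``(z, y)`` with ``z`` horizontal and
``y`` vertical (positive up); bending of interest is about the horizontal
``z`` axis, so the relevant moment is :math:`I_{zz}`.  All section quantities
are in millimetres.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import trimesh
from scipy.integrate import quad

from .config import DEFAULT_R_RATIO

logger = logging.getLogger(__name__)

__all__ = [
    "PolygonSection",
    "SectionProperties",
    "PartialTubeSpec",
    "MeshSlice",
    "InvalidSectionError",
    "DegenerateSectionError",
    "polygon_area",
    "polygon_centroid",
    "polygon_second_moment",
    "section_properties",
    "outer_radius_from_chord",
    "partial_tube_second_moment",
    "slice_mesh",
    "mesh_section_table",
    "mean_section_properties",
    "write_slice_table",
]


class InvalidSectionError(ValueError):
    """A section violates its structural invariants (too few vertices...)."""


class DegenerateSectionError(ValueError):
    """A polygon with (numerically) zero signed area."""


@dataclass(frozen=True)
class PolygonSection:
    """A simple planar polygon in section coordinates (z horizontal, y vertical).

    Vertices are ordered (either winding); the closing edge from the last
    vertex back to the first is implicit.  Units: mm.
    """

    vertices: np.ndarray
    axial_position: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise InvalidSectionError("vertices must be an (n, 2) array")
        if v.shape[0] < 3:
            raise InvalidSectionError("a polygon needs at least 3 vertices")
        object.__setattr__(self, "vertices", v)

    def translated(self, dz: float, dy: float) -> "PolygonSection":
        return PolygonSection(self.vertices + [dz, dy], self.axial_position)


@dataclass(frozen=True)
class SectionProperties:
    """Area/centroid/second-moment summary of one cross-section (mm-based).

    ``I_zz_origin`` is taken about the horizontal axis through the reference
    origin of the section plane; ``I_zzc`` about the parallel axis through the
    centroid, related by the parallel-axis theorem
    ``I_zzc = I_zz_origin - area * D**2`` with ``D`` the vertical
    origin-to-centroid distance.
    """

    area: float
    centroid: tuple[float, float]
    I_zz_origin: float
    I_zzc: float

    @property
    def D(self) -> float:
        """Vertical distance from the reference origin to the centroid, mm."""
        return abs(self.centroid[1])


def _shoelace_sums(vertices: np.ndarray) -> tuple[float, float, float, float]:
    """Signed shoelace sums: (area, z-moment, y-moment, Izz about origin)."""
    z = vertices[:, 0]
    y = vertices[:, 1]
    z1 = np.roll(z, -1)
    y1 = np.roll(y, -1)
    cross = z * y1 - z1 * y
    area = 0.5 * np.sum(cross)
    sz = np.sum((z + z1) * cross) / 6.0
    sy = np.sum((y + y1) * cross) / 6.0
    izz = np.sum((y * y + y * y1 + y1 * y1) * cross) / 12.0
    return area, sz, sy, izz


def _signed_sums(section: PolygonSection) -> tuple[float, float, float, float]:
    area, sz, sy, izz = _shoelace_sums(section.vertices)
    scale = np.abs(section.vertices).max() or 1.0
    if abs(area) <= 1e-12 * scale**2:
        raise DegenerateSectionError("polygon has zero signed area")
    return area, sz, sy, izz


def polygon_area(section: PolygonSection) -> float:
    """Area of a simple polygon (mm^2), independent of vertex winding."""
    return abs(_signed_sums(section)[0])


def polygon_centroid(section: PolygonSection) -> tuple[float, float]:
    """Centroid ``(C_z, C_y)`` of a simple polygon, mm."""
    area, sz, sy, _ = _signed_sums(section)
    return (sz / area, sy / area)


def polygon_second_moment(section: PolygonSection) -> SectionProperties:
    """Section properties of one polygon about the horizontal axis.

    The origin moment is sign-corrected so either vertex winding yields the
    same nonnegative value; the centroidal moment follows from the
    parallel-axis theorem.
    """
    area, sz, sy, izz = _signed_sums(section)
    sign = np.sign(area)
    a = sign * area
    izz0 = sign * izz
    cz, cy = sz / area, sy / area
    izzc = izz0 - a * cy * cy
    return SectionProperties(area=a, centroid=(cz, cy), I_zz_origin=izz0, I_zzc=izzc)


def section_properties(
    outer: PolygonSection, inner: Sequence[PolygonSection] = ()
) -> SectionProperties:
    """Properties of a (possibly hollow) section: outer contour minus lumens.

    Areas, first moments and origin moments combine by subtraction; the
    centroid and centroidal moment are recomputed from the combined sums.
    """
    ao, szo, syo, izzo = _signed_sums(outer)
    sgn = np.sign(ao)
    area, sz, sy, izz = sgn * ao, sgn * szo, sgn * syo, sgn * izzo
    for lumen in inner:
        ai, szi, syi, izzi = _signed_sums(lumen)
        s = np.sign(ai)
        area -= s * ai
        sz -= s * szi
        sy -= s * syi
        izz -= s * izzi
    if area <= 0:
        raise DegenerateSectionError("lumen area exceeds outer contour area")
    cz, cy = sz / area, sy / area
    return SectionProperties(
        area=area, centroid=(cz, cy), I_zz_origin=izz, I_zzc=izz - area * cy * cy
    )


# ---------------------------------------------------------------------------
# Partial-tube (hand-measured) model
# ---------------------------------------------------------------------------


def outer_radius_from_chord(width: float, height: float) -> float:
    """Outer radius of a circular segment from its chord width and height (mm).

    A horizontal chord of length ``width`` sits ``height`` above the lowest
    point of a circle; the circle's radius is
    ``R = ((width/2)**2 + height**2) / (2 * height)``.
    """
    if height <= 0:
        raise ValueError("height must be positive")
    if width <= 0:
        raise ValueError("width must be positive")
    return ((0.5 * width) ** 2 + height**2) / (2.0 * height)


@dataclass(frozen=True)
class PartialTubeSpec:
    """Idealised pole cross-section: bottom portion of a hollow tube.

    ``height`` is the section height h measured from the lowest outer point
    to the flat cut; ``outer_radius``/``inner_radius`` are the tube radii.
    The reference origin sits at the centre of the concentric circles, y
    positive up, so the material occupies ``y in [-R, -R + h]``.
    """

    outer_radius: float
    inner_radius: float
    height: float
    width: float | None = None

    def __post_init__(self) -> None:
        R, r, h = self.outer_radius, self.inner_radius, self.height
        if R <= 0:
            raise ValueError("outer radius must be positive")
        if not (0 <= r < R):
            raise ValueError("inner radius must satisfy 0 <= r < R")
        if not (0 < h <= 2 * R):
            raise ValueError("height must satisfy 0 < h <= 2R")
        if self.width is None:
            w = 2.0 * np.sqrt(R**2 - (R - h) ** 2) if h <= R else 2.0 * R
            object.__setattr__(self, "width", float(w))

    @classmethod
    def from_hand_measurements(
        cls, width: float, height: float, r_ratio: float = DEFAULT_R_RATIO
    ) -> "PartialTubeSpec":
        """Build a spec from the two farm-site measurements (width, height)."""
        if not (0 <= r_ratio < 1):
            raise ValueError("r_ratio must lie in [0, 1)")
        R = outer_radius_from_chord(width, height)
        return cls(outer_radius=R, inner_radius=r_ratio * R, height=height, width=width)


def _segment_sums(radius: float, y_lo: float, y_hi: float) -> tuple[float, float, float]:
    """(area, first y-moment, Izz about y=0) of the disc of given radius
    restricted to the horizontal band ``y in [y_lo, y_hi]``, by adaptive
    quadrature of the horizontal chord width ``2*sqrt(radius^2 - y^2)``."""
    lo = max(y_lo, -radius)
    hi = min(y_hi, radius)
    if radius <= 0 or hi <= lo:
        return 0.0, 0.0, 0.0
    w = lambda y: 2.0 * np.sqrt(max(radius * radius - y * y, 0.0))
    # absolute floors scale with the integral's natural magnitude (R^2..R^4)
    area = quad(w, lo, hi, epsabs=1e-13 * radius**2, epsrel=1e-10, limit=200)[0]
    s_y = quad(lambda y: y * w(y), lo, hi, epsabs=1e-13 * radius**3, epsrel=1e-10, limit=200)[0]
    izz = quad(lambda y: y * y * w(y), lo, hi, epsabs=1e-13 * radius**4, epsrel=1e-10, limit=200)[0]
    return area, s_y, izz


def partial_tube_second_moment(spec: PartialTubeSpec) -> SectionProperties:
    """Section properties of the partial tube about the circle centre / centroid.

    Outer-segment integrals minus inner-segment integrals over the band
    ``y in [-R, -R + h]`` give area, first moment and I_zz about the circle
    centre; the centroidal moment follows from the parallel-axis theorem.
    """
    R, r, h = spec.outer_radius, spec.inner_radius, spec.height
    y_lo, y_hi = -R, -R + h
    ao, so, io = _segment_sums(R, y_lo, y_hi)
    ai, si, ii = _segment_sums(r, y_lo, y_hi)
    area = ao - ai
    s_y = so - si
    izz = io - ii
    if area <= 0:
        raise DegenerateSectionError("partial tube has zero material area")
    cy = s_y / area
    return SectionProperties(
        area=area, centroid=(0.0, cy), I_zz_origin=izz, I_zzc=izz - area * cy * cy
    )


# ---------------------------------------------------------------------------
# Mesh slicing
# ---------------------------------------------------------------------------


@dataclass
class MeshSlice:
    """Contours of one axial station: outer boundary plus any lumen contours."""

    axial_position: float
    outer: PolygonSection
    inner: list[PolygonSection] = field(default_factory=list)

    @property
    def properties(self) -> SectionProperties:
        return section_properties(self.outer, self.inner)


_SECTION_AXES = {0: (2, 1), 1: (0, 2), 2: (0, 1)}  # axial -> (z-like, y-like)


def slice_mesh(
    mesh: "trimesh.Trimesh | str | Path",
    interval: float = 5.0,
    axis: int | None = None,
) -> list[MeshSlice]:
    """Cut a surface mesh at regular axial stations into planar contours.

    The pole axis defaults to the longest bounding-box dimension.  At each
    station the contour of largest area is the outer boundary; any further
    closed contours are lumens, reported separately so hollow-section
    properties can be computed as outer minus inner.  Empty or degenerate
    stations are skipped with a logged warning rather than aborting.
    """
    if isinstance(mesh, (str, Path)):
        mesh = trimesh.load_mesh(str(mesh))
    if interval <= 0:
        raise ValueError("interval must be positive")
    extents = mesh.bounds[1] - mesh.bounds[0]
    if axis is None:
        axis = int(np.argmax(extents))
    zi, yi = _SECTION_AXES[axis]
    normal = np.zeros(3)
    normal[axis] = 1.0
    lo, hi = mesh.bounds[0][axis], mesh.bounds[1][axis]
    stations = np.arange(lo, hi + 1e-9, interval)
    # nudge end stations off the exact boundary so the cut plane intersects
    eps = 1e-6 * max(extents[axis], 1.0)
    slices: list[MeshSlice] = []
    for station in stations:
        x = float(np.clip(station, lo + eps, hi - eps))
        origin = np.zeros(3)
        origin[axis] = x
        path = mesh.section(plane_origin=origin, plane_normal=normal)
        if path is None:
            logger.warning("empty slice at axial position %.3f mm; skipped", station)
            continue
        contours = []
        for loop in path.discrete:
            pts = np.asarray(loop)[:, [zi, yi]]
            if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
                pts = pts[:-1]
            if len(pts) < 3:
                continue
            try:
                sec = PolygonSection(pts, axial_position=float(station))
                polygon_area(sec)
            except (InvalidSectionError, DegenerateSectionError):
                continue
            contours.append(sec)
        if not contours:
            logger.warning("degenerate slice at axial position %.3f mm; skipped", station)
            continue
        contours.sort(key=polygon_area, reverse=True)
        slices.append(
            MeshSlice(
                axial_position=float(station), outer=contours[0], inner=contours[1:]
            )
        )
    return slices


def mesh_section_table(
    mesh: "trimesh.Trimesh | str | Path",
    interval: float = 5.0,
    axis: int | None = None,
) -> pd.DataFrame:
    """Per-slice section properties of a mesh as a tidy table (mm units)."""
    rows = []
    for sl in slice_mesh(mesh, interval=interval, axis=axis):
        try:
            p = sl.properties
        except DegenerateSectionError:
            logger.warning("degenerate section at %.3f mm; skipped", sl.axial_position)
            continue
        rows.append(
            {
                "axial_position_mm": sl.axial_position,
                "area_mm2": p.area,
                "Cz_mm": p.centroid[0],
                "Cy_mm": p.centroid[1],
                "Izzc_mm4": p.I_zzc,
            }
        )
    return pd.DataFrame(rows, columns=["axial_position_mm", "area_mm2", "Cz_mm", "Cy_mm", "Izzc_mm4"])


def mean_section_properties(
    table: pd.DataFrame, window: tuple[float, float] = (0.40, 0.60)
) -> pd.Series:
    """Mean and SD of per-slice properties over a fractional axial window.

    The window (fractions of the pole length) selects the internode centre
    region used to characterise the pole, avoiding end taper and growth-node
    thickenings.
    """
    if table.empty:
        raise ValueError("empty slice table")
    x = table["axial_position_mm"]
    lo = x.min() + window[0] * (x.max() - x.min())
    hi = x.min() + window[1] * (x.max() - x.min())
    sel = table[(x >= lo) & (x <= hi)]
    if sel.empty:
        raise ValueError("axial window selects no slices")
    out = {}
    for col in ("area_mm2", "Izzc_mm4"):
        out[f"{col}_mean"] = sel[col].mean()
        out[f"{col}_sd"] = sel[col].std(ddof=1) if len(sel) > 1 else 0.0
    out["n_slices"] = float(len(sel))
    return pd.Series(out)


def write_slice_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write per-slice properties as delimited text."""
    table.to_csv(path, index=False)
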