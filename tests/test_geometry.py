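"""Section-property operators against closed-form geometry."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from carrypole.geometry import (
    DegenerateSectionError,
    InvalidSectionError,
    PartialTubeSpec,
    PolygonSection,
    mean_section_properties,
    mesh_section_table,
    outer_radius_from_chord,
    partial_tube_second_moment,
    polygon_area,
    polygon_centroid,
    polygon_second_moment,
    section_properties,
    slice_mesh,
)
from carrypole.synthetic import SyntheticPoleSpec, gen_cross_section_mesh

from conftest import make_hollow_cylinder


def circle(radius: float, n: int = 3600, center=(0.0, 0.0), ccw: bool = True):
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    if not ccw:
        th = th[::-1]
    return PolygonSection(
        np.column_stack([center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)])
    )


def partial_tube_polygon(R, r, h, n=3600):
    """Discretised C-shaped partial-tube section (chord cutting the lumen)."""
    c = -(R - h)
    t_o = np.arccos(-c / R)
    t_i = np.arccos(-c / r)
    to = np.linspace(-t_o, t_o, n)
    ti = np.linspace(t_i, -t_i, n)
    outer = np.column_stack([R * np.sin(to), -R * np.cos(to)])
    inner = np.column_stack([r * np.sin(ti), -r * np.cos(ti)])
    return PolygonSection(np.vstack([outer, inner]))


class TestPolygonOperators:
    def test_unit_square_area_any_orientation(self):
        sq = PolygonSection([(0, 0), (1, 0), (1, 1), (0, 1)])
        rev = PolygonSection([(0, 1), (1, 1), (1, 0), (0, 0)])
        assert polygon_area(sq) == pytest.approx(1.0)
        assert polygon_area(rev) == pytest.approx(1.0)

    def test_circle_area_matches_closed_form(self):
        c = circle(10.0)
        assert polygon_area(c) == pytest.approx(np.pi * 100.0, rel=1e-4)

    def test_centroids(self):
        sq = PolygonSection([(-1, -1), (1, -1), (1, 1), (-1, 1)])
        assert polygon_centroid(sq) == pytest.approx((0.0, 0.0), abs=1e-12)
        tri = PolygonSection([(0, 0), (3, 0), (0, 3)])
        assert polygon_centroid(tri) == pytest.approx((1.0, 1.0))

    @given(
        dz=st.floats(-50, 50, allow_nan=False),
        dy=st.floats(-50, 50, allow_nan=False),
    )
    def test_translation_equivariance(self, dz, dy):
        tri = PolygonSection([(0, 0), (3, 0), (1, 2)])
        cz, cy = polygon_centroid(tri)
        cz2, cy2 = polygon_centroid(tri.translated(dz, dy))
        assert cz2 == pytest.approx(cz + dz, abs=1e-9)
        assert cy2 == pytest.approx(cy + dy, abs=1e-9)

    def test_rectangle_second_moment_and_parallel_axis(self):
        b, h = 10.0, 2.0
        centered = PolygonSection(
            [(-b / 2, -h / 2), (b / 2, -h / 2), (b / 2, h / 2), (-b / 2, h / 2)]
        )
        p = polygon_second_moment(centered)
        assert p.I_zzc == pytest.approx(b * h**3 / 12.0)
        on_axis = PolygonSection([(0, 0), (b, 0), (b, h), (0, h)])
        p2 = polygon_second_moment(on_axis)
        assert p2.I_zz_origin == pytest.approx(b * h**3 / 3.0)
        assert p2.I_zzc == pytest.approx(b * h**3 / 12.0)
        # parallel-axis identity to machine precision
        assert p2.I_zzc == pytest.approx(
            p2.I_zz_origin - p2.area * p2.D**2, rel=1e-14
        )

    def test_vertical_translation_leaves_centroidal_moment(self):
        tri = PolygonSection([(0, 0), (4, 0), (1, 3)])
        p = polygon_second_moment(tri)
        p_up = polygon_second_moment(tri.translated(0.0, 7.5))
        assert p_up.I_zzc == pytest.approx(p.I_zzc, rel=1e-12)
        assert p_up.I_zz_origin != pytest.approx(p.I_zz_origin, rel=1e-3)

    def test_annulus_outer_minus_inner(self):
        R, r = 30.0, 21.9
        p = section_properties(circle(R), [circle(r, ccw=False)])
        assert p.I_zzc == pytest.approx(np.pi / 4.0 * (R**4 - r**4), rel=1e-4)
        assert p.area == pytest.approx(np.pi * (R**2 - r**2), rel=1e-4)

    def test_degenerate_polygons_raise(self):
        with pytest.raises(InvalidSectionError):
            PolygonSection([(0, 0), (1, 1)])
        line = PolygonSection([(0, 0), (1, 1), (2, 2)])
        with pytest.raises(DegenerateSectionError):
            polygon_area(line)


class TestPartialTube:
    def test_outer_radius_from_chord_hand_measurements(self):
        assert outer_radius_from_chord(60.0, 22.0) == pytest.approx(31.5, abs=0.1)
        assert outer_radius_from_chord(48.0, 20.0) == pytest.approx(24.4, abs=0.1)

    def test_half_circle_chord_gives_radius_equal_height(self):
        h = 17.3
        assert outer_radius_from_chord(2 * h, h) == pytest.approx(h)

    def test_invalid_chord_inputs(self):
        with pytest.raises(ValueError):
            outer_radius_from_chord(60.0, 0.0)
        with pytest.raises(ValueError):
            outer_radius_from_chord(-1.0, 5.0)

    def test_full_annulus_limit(self):
        R = 20.0
        spec = PartialTubeSpec(outer_radius=R, inner_radius=0.73 * R, height=2 * R)
        p = partial_tube_second_moment(spec)
        assert p.I_zzc == pytest.approx(np.pi / 4 * (R**4 - (0.73 * R) ** 4), rel=1e-8)
        assert p.D == pytest.approx(0.0, abs=1e-8)

    def test_hand_measured_pole_section(self):
        # width 60 mm, height 22 mm reproduces the reported 1.862e4 mm^4
        spec = PartialTubeSpec.from_hand_measurements(60.0, 22.0, r_ratio=0.73)
        p = partial_tube_second_moment(spec)
        assert p.I_zzc == pytest.approx(1.862e4, rel=0.01)

    def test_solid_semicircle_closed_form(self):
        R = 10.0
        spec = PartialTubeSpec(outer_radius=R, inner_radius=0.0, height=R)
        p = partial_tube_second_moment(spec)
        assert p.I_zzc == pytest.approx((np.pi / 8 - 8 / (9 * np.pi)) * R**4, rel=1e-8)

    def test_agrees_with_discretised_polygon(self):
        R, h = 31.5, 22.0
        r = 0.73 * R
        analytic = partial_tube_second_moment(
            PartialTubeSpec(outer_radius=R, inner_radius=r, height=h)
        )
        poly = polygon_second_moment(partial_tube_polygon(R, r, h))
        assert poly.I_zzc == pytest.approx(analytic.I_zzc, rel=1e-3)
        assert poly.area == pytest.approx(analytic.area, rel=1e-3)

    def test_monotone_in_height(self):
        R = 30.0
        hs = np.linspace(5.0, 2 * R, 12)
        iz = [
            partial_tube_second_moment(
                PartialTubeSpec(outer_radius=R, inner_radius=0.73 * R, height=h)
            ).I_zzc
            for h in hs
        ]
        assert np.all(np.diff(iz) > 0)

    def test_invalid_specs_raise(self):
        with pytest.raises(ValueError):
            PartialTubeSpec(outer_radius=10.0, inner_radius=11.0, height=5.0)
        with pytest.raises(ValueError):
            PartialTubeSpec(outer_radius=10.0, inner_radius=5.0, height=25.0)


class TestMeshSlicing:
    def test_station_count(self, short_pole_spec):
        mesh, _ = gen_cross_section_mesh(short_pole_spec, station_interval=25.0, n_arc=24)
        slices = slice_mesh(mesh, interval=50.0)
        # 500 mm pole at 50 mm intervals -> 11 stations
        assert len(slices) == 11

    def test_hollow_cylinder_properties(self):
        R, r = 30.0, 22.0
        mesh = make_hollow_cylinder(R, r, length=200.0)
        slices = slice_mesh(mesh, interval=50.0)
        assert all(len(s.inner) == 1 for s in slices)
        for s in slices:
            p = s.properties
            assert p.area == pytest.approx(np.pi * (R**2 - r**2), rel=2e-3)
            assert p.I_zzc == pytest.approx(np.pi / 4 * (R**4 - r**4), rel=2e-3)

    def test_node_thickenings_show_as_local_maxima(self, short_pole_spec):
        mesh, truth = gen_cross_section_mesh(
            short_pole_spec, station_interval=10.0, n_arc=32
        )
        table = mesh_section_table(mesh, interval=10.0)
        iz = table["Izzc_mm4"].to_numpy()
        x = table["axial_position_mm"].to_numpy()
        # nodes every 300 mm starting at 150 mm: a clear spike near 150 and 450
        for node_x in (150.0, 450.0):
            near = np.abs(x - node_x) <= 20.0
            far = np.abs(x - node_x) > 40.0
            assert iz[near].max() > 1.3 * np.median(iz[far])

    def test_mean_section_window(self, short_pole_spec):
        mesh, _ = gen_cross_section_mesh(short_pole_spec, station_interval=10.0, n_arc=32)
        table = mesh_section_table(mesh, interval=10.0)
        stats = mean_section_properties(table, window=(0.4, 0.6))
        assert stats["n_slices"] >= 5
        assert stats["Izzc_mm4_mean"] > 0
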