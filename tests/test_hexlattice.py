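"""Lattice geometry: basis, tilts, (d, h, c, L), cross-section patterns."""

import math

import numpy as np
import pytest

from thex.hexlattice import (
    CrossSectionPattern,
    EllipseSupport,
    HexLattice,
    RectSupport,
    TiltIndex,
    build_cross_section,
    enumerate_tilts,
    lattice_vector,
    read_pattern_csv,
    repetition_length,
    rescale_crop,
    shot_geometry,
    shot_offsets,
    tilt_norm,
    write_pattern_csv,
)

SQRT3 = math.sqrt(3.0)

ALL_TILTS_M1_LE_7 = [
    TiltIndex(m1, m2) for m1 in range(1, 8) for m2 in range(0, m1 + 1)
]


def brute_force_lattice(dk: float, n: int) -> np.ndarray:
    """All lattice points a*e1 + b*e2 with |a|,|b| <= n."""
    lat = HexLattice(dk)
    a, b = np.meshgrid(np.arange(-n, n + 1), np.arange(-n, n + 1))
    return a.ravel()[:, None] * lat.e1 + b.ravel()[:, None] * lat.e2


class TestHexLattice:
    def test_basis_lengths_and_angle(self):
        lat = HexLattice(dk=2.5)
        assert np.linalg.norm(lat.e1) == pytest.approx(2.5)
        assert np.linalg.norm(lat.e2) == pytest.approx(2.5)
        cosang = np.dot(lat.e1, lat.e2) / 2.5**2
        assert math.degrees(math.acos(cosang)) == pytest.approx(60.0)

    def test_cell_area(self):
        assert HexLattice(dk=1.0).cell_area == pytest.approx(SQRT3 / 2)
        assert HexLattice(dk=3.0).cell_area == pytest.approx(9 * SQRT3 / 2)

    def test_invalid_dk(self):
        with pytest.raises(ValueError, match="dk"):
            HexLattice(dk=0.0)


class TestTiltIndex:
    @pytest.mark.parametrize("m1,m2", [(0, 0), (1, 2), (-1, 0), (2, -1)])
    def test_dodecant_violations_rejected(self, m1, m2):
        with pytest.raises(ValueError, match="dodecant"):
            TiltIndex(m1, m2)

    def test_gcd_and_primitivity(self):
        assert TiltIndex(2, 1).is_primitive
        assert TiltIndex(4, 2).g == 2
        assert not TiltIndex(4, 2).is_primitive


class TestLatticeVector:
    def test_nearest_neighbor(self):
        _, d = lattice_vector(TiltIndex(1, 0), dk=1.0)
        assert d == pytest.approx(1.0)

    def test_21_is_sqrt7(self):
        v, d = lattice_vector(TiltIndex(2, 1), dk=1.0)
        assert d == pytest.approx(math.sqrt(7))
        assert np.linalg.norm(v) == pytest.approx(d)

    def test_71_is_sqrt57(self):
        _, d = lattice_vector(TiltIndex(7, 1), dk=1.0)
        assert d == pytest.approx(math.sqrt(57))
        assert round(d, 1) == 7.5  # exact sqrt(57) ~ 7.55, not the printed 7.6

    def test_distance_closure_against_brute_force(self):
        """Every dodecant distance (M1 <= 7) occurs in a brute-force patch,
        and every pairwise patch distance occurs among dodecant distances."""
        pts = brute_force_lattice(1.0, 9)
        dists = np.unique(np.round(np.linalg.norm(pts, axis=1), 9))
        dodecant = sorted(tilt_norm(t) for t in ALL_TILTS_M1_LE_7)
        for dv in dodecant:
            assert np.any(np.abs(dists - dv) < 1e-8), dv
        # pairwise distances of a small patch all appear among dodecant values
        patch = brute_force_lattice(1.0, 3)
        extended = sorted(
            tilt_norm(TiltIndex(m1, m2))
            for m1 in range(1, 13)
            for m2 in range(0, m1 + 1)
        )
        for i in range(len(patch)):
            dd = np.linalg.norm(patch - patch[i], axis=1)
            for val in dd[dd > 1e-12]:
                assert min(abs(val - e) for e in extended) < 1e-8


class TestEnumerateTilts:
    def test_dmax_one(self):
        assert enumerate_tilts(1.0) == [TiltIndex(1, 0)]

    def test_dmax_two(self):
        assert enumerate_tilts(2.0) == [TiltIndex(1, 0), TiltIndex(1, 1), TiltIndex(2, 0)]

    def test_dmax_study_range(self):
        tilts = enumerate_tilts(7.6)
        assert tilts[-1] == TiltIndex(7, 1)  # largest-d entry: sqrt(57) ~ 7.55
        norms = [tilt_norm(t) for t in tilts]
        assert norms == sorted(norms)

    def test_below_one_rejected(self):
        with pytest.raises(ValueError, match="no tilt"):
            enumerate_tilts(0.99)


def offset_period_oracle(tilt: TiltIndex, max_period: int = 600) -> int:
    """Brute-force period of the per-shot in-plane offset sequence."""
    geom = shot_geometry(tilt, dk=1.0)
    offs, _ = shot_offsets(geom, max_period)
    # The points of one shot line repeat at the within-row spacing d/g (for
    # g interleaved shots per lattice row), so the geometric configuration is
    # periodic in the offsets taken modulo d/g.
    mod = geom.d / geom.g
    seq = offs % mod
    for L in range(1, max_period // 2):
        diff = np.abs(seq[L:] - seq[:-L])
        if np.all(np.minimum(diff, mod - diff) < 1e-9):
            return L
    raise AssertionError("no period found")


class TestRepetitionLength:
    @pytest.mark.parametrize(
        "tilt,expected", [(TiltIndex(2, 1), 14), (TiltIndex(1, 0), 2), (TiltIndex(3, 1), 26)]
    )
    def test_known_values(self, tilt, expected):
        assert repetition_length(tilt) == expected

    @pytest.mark.parametrize("tilt", ALL_TILTS_M1_LE_7, ids=str)
    def test_matches_offset_period_oracle(self, tilt):
        assert repetition_length(tilt) == offset_period_oracle(tilt)


class TestShotGeometry:
    def test_10(self):
        g = shot_geometry(TiltIndex(1, 0), dk=1.0)
        assert g.c / g.d == pytest.approx(0.5)
        assert g.h == pytest.approx(SQRT3 / 2)
        assert g.L == 2

    def test_21(self):
        g = shot_geometry(TiltIndex(2, 1), dk=1.0)
        assert g.c / g.d == pytest.approx(5 / 14)
        assert g.h == pytest.approx(SQRT3 / (2 * math.sqrt(7)))
        assert g.phase_increment == pytest.approx(2 * math.pi * 5 / 14)
        assert g.L * (g.c / g.d) == pytest.approx(5.0)

    @pytest.mark.parametrize("tilt", ALL_TILTS_M1_LE_7, ids=str)
    def test_L_times_c_is_multiple_of_d(self, tilt):
        g = shot_geometry(tilt, dk=1.0)
        resid = (g.L * g.c) % g.d
        assert min(resid, g.d - resid) < 1e-9

    def test_scales_with_dk(self):
        g1 = shot_geometry(TiltIndex(2, 1), dk=1.0)
        g2 = shot_geometry(TiltIndex(2, 1), dk=2.0)
        assert g2.d == pytest.approx(2 * g1.d)
        assert g2.h == pytest.approx(2 * g1.h)
        assert g2.c == pytest.approx(2 * g1.c)
        assert g2.L == g1.L


class TestBuildCrossSection:
    def test_10_three_rows_four_cols(self):
        g = shot_geometry(TiltIndex(1, 0), dk=1.0)
        pat = build_cross_section(g, extent1=(0.0, 4.0), extent2=(0.0, 3 * g.h - 1e-6))
        assert len(pat) == 12
        assert pat.n_shots == 3
        # alternate rows offset by half a spacing
        row1 = np.sort(pat.points[pat.shot_id == 1, 0])
        row0 = np.sort(pat.points[pat.shot_id == 0, 0])
        assert np.allclose((row1 - row0) % 1.0, 0.5)

    def test_21_offsets_repeat_with_period_14(self):
        g = shot_geometry(TiltIndex(2, 1), dk=1.0)
        n_lines = 30
        pat = build_cross_section(
            g, extent1=(0.0, 50 * g.d), extent2=(-1e-9, n_lines * g.h - 1e-6)
        )
        offs = np.array(
            [pat.points[pat.shot_id == j, 0].min() % g.d for j in range(n_lines)]
        )
        assert np.allclose(offs[14:28], offs[:14], atol=1e-9)
        assert not np.allclose(offs[1:15], offs[:14], atol=1e-6)  # not shorter

    def test_degenerate_extent_rejected(self):
        g = shot_geometry(TiltIndex(1, 0), dk=1.0)
        with pytest.raises(ValueError, match="degenerate"):
            build_cross_section(g, extent1=(1.0, 1.0), extent2=(0.0, 2.0))

    @pytest.mark.parametrize("tilt", ALL_TILTS_M1_LE_7, ids=str)
    def test_fine_grid_embedding(self, tilt):
        """Every k1 is an integer multiple of d/L, every k2 of h."""
        g = shot_geometry(tilt, dk=1.0)
        pat = build_cross_section(g, extent1=(-8.0, 8.0), extent2=(-8.0, 8.0))
        fine = g.d / g.L
        r1 = pat.points[:, 0] / fine
        r2 = pat.points[:, 1] / g.h
        assert np.abs(r1 - np.round(r1)).max() < 1e-9 * max(1.0, np.abs(r1).max())
        assert np.abs(r2 - np.round(r2)).max() < 1e-9 * max(1.0, np.abs(r2).max())

    @pytest.mark.parametrize("tilt", [TiltIndex(1, 0), TiltIndex(2, 1), TiltIndex(4, 2)], ids=str)
    def test_pattern_is_exactly_the_mapped_hexagonal_lattice(self, tilt):
        """Union of shot lines == the lattice under the orthogonal map that
        sends v to the k1 axis (with the package's offset-sign convention)."""
        from scipy.spatial import cKDTree

        g = shot_geometry(tilt, dk=1.0)
        lo, hi = -6.0, 6.0
        pat = build_cross_section(g, extent1=(lo, hi), extent2=(lo, hi))
        v, d = lattice_vector(tilt, dk=1.0)
        vhat = v / d
        rot = np.array([[vhat[0], vhat[1]], [vhat[1], -vhat[0]]])
        brute = brute_force_lattice(1.0, 20) @ rot.T
        tol1 = 1e-9 * g.d
        tol2 = 1e-9 * g.h
        keep = (
            (brute[:, 0] >= lo - tol1)
            & (brute[:, 0] < hi - tol1)
            & (brute[:, 1] >= lo - tol2)
            & (brute[:, 1] < hi - tol2)
        )
        brute = brute[keep]
        assert len(pat) == len(brute)
        dist, _ = cKDTree(brute).query(pat.points)
        assert dist.max() < 1e-9

    def test_within_shot_spacing_is_d(self):
        g = shot_geometry(TiltIndex(3, 1), dk=1.0)
        pat = build_cross_section(g, extent1=(-20.0, 20.0), extent2=(0.0, 5 * g.h))
        for j in range(pat.n_shots):
            k1 = np.sort(pat.points[pat.shot_id == j, 0])
            if len(k1) > 1:
                assert np.allclose(np.diff(k1), g.d, atol=1e-9)


class TestShotOffsets:
    def test_non_primitive_grouping(self):
        g = shot_geometry(TiltIndex(2, 2), dk=1.0)
        offs, k2 = shot_offsets(g, 8)
        # two shots per lattice row, rows at spacing 2h
        assert np.allclose(k2[:4], [0, 0, 2 * g.h, 2 * g.h])
        within = np.sort(offs[:2])
        assert within[1] - within[0] == pytest.approx(g.d / 2)


class TestRescaleCrop:
    def _pattern(self):
        g = shot_geometry(TiltIndex(1, 0), dk=1.0)
        return build_cross_section(g, extent1=(-10.0, 10.0), extent2=(-10.0, 10.0))

    def test_identity(self):
        pat = self._pattern()
        out = rescale_crop(pat, 1.0, 1.0, support=None)
        assert np.array_equal(out.points, pat.points)
        assert np.array_equal(out.shot_id, pat.shot_id)

    def test_scale2_doubles_voronoi_area(self):
        from thex.analysis import density_uniformity

        pat = self._pattern()
        base = density_uniformity(pat).mean_area
        out = rescale_crop(pat, 1.0, 2.0)
        assert density_uniformity(out).mean_area == pytest.approx(2 * base, rel=1e-9)
        assert out.cell_area == pytest.approx(2 * pat.cell_area)

    def test_elliptical_crop_matches_brute_force(self):
        pat = self._pattern()
        ell = EllipseSupport(a=8.0, b=4.0)
        out = rescale_crop(pat, 1.0, 1.0, support=ell)
        inside = (pat.points[:, 0] / 8.0) ** 2 + (pat.points[:, 1] / 4.0) ** 2 <= 1 + 1e-9
        assert len(out) == int(inside.sum())

    def test_rect_crop_half_open(self):
        g = shot_geometry(TiltIndex(1, 0), dk=1.0)
        pat = build_cross_section(g, extent1=(-3.0, 3.0), extent2=(-3 * g.h, 3 * g.h))
        rect = RectSupport(0.0, 2.0, 0.0, 2 * g.h)
        out = rescale_crop(pat, 1.0, 1.0, support=rect)
        assert np.all(out.points[:, 0] >= -1e-9)
        assert np.all(out.points[:, 0] < 2.0 - 1e-12)  # upper edge excluded
        assert np.any(np.abs(out.points[:, 0]) < 1e-12)  # lower edge kept

    def test_empty_crop_rejected(self):
        pat = self._pattern()
        with pytest.raises(ValueError, match="no points survive"):
            rescale_crop(pat, 1.0, 1.0, support=RectSupport(100.0, 100.1, 100.0, 100.1))

    def test_shot_ids_compacted(self):
        pat = self._pattern()
        out = rescale_crop(pat, 1.0, 1.0, support=RectSupport(-5.0, 5.0, 0.4, 2.0))
        assert out.shot_id.min() == 0
        assert set(out.shot_id) == set(range(out.n_shots))


def test_density_conservation():
    """Tilting preserves one point per dk^2*sqrt(3)/2 of area."""
    for tilt in (TiltIndex(1, 0), TiltIndex(3, 2)):
        g = shot_geometry(tilt, dk=1.0)
        span = 14.0
        pat = build_cross_section(g, extent1=(-span, span), extent2=(-span, span))
        density = len(pat) / (2 * span) ** 2
        assert density == pytest.approx(1.0 / (SQRT3 / 2), rel=0.05)


def test_pattern_csv_round_trip(tmp_path):
    g = shot_geometry(TiltIndex(2, 1), dk=1.0)
    pat = build_cross_section(g, extent1=(-5.0, 5.0), extent2=(-5.0, 5.0))
    path = tmp_path / "pattern.csv"
    write_pattern_csv(pat, path)
    back = read_pattern_csv(path, g)
    assert np.allclose(back.points, pat.points, atol=1e-12)
    assert np.array_equal(back.shot_id, pat.shot_id)
    assert np.array_equal(back.within_shot_index, pat.within_shot_index)
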