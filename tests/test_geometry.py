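"""Reciprocal-space arithmetic, symmetry reduction and detector projection."""

import gemmi
import numpy as np
import pytest

from pinksfx import geometry as g
from pinksfx.errors import (
    GeometryInconsistencyError,
    InvalidInputError,
    UnsupportedSymmetryError,
)


def random_cells(n, seed=0):
    rng = np.random.default_rng(seed)
    cells = []
    while len(cells) < n:
        a, b, c = rng.uniform(20, 150, 3)
        al, be, ga = rng.uniform(70, 110, 3)
        try:
            cells.append(g.UnitCell(a, b, c, al, be, ga))
        except InvalidInputError:
            continue
    return cells


class TestWavelength:
    @pytest.mark.parametrize(
        "kev,ang", [(6.02, 2.059), (5.99, 2.069), (4.5, 2.755)]
    )
    def test_published_conversions(self, kev, ang):
        assert g.wavelength_from_energy(kev) == pytest.approx(ang, abs=1e-3)

    def test_round_trip(self):
        for e in (1.0, 6.02, 12.4):
            assert g.energy_from_wavelength(g.wavelength_from_energy(e)) == pytest.approx(e, abs=1e-9)

    def test_nonpositive_energy_rejected(self):
        with pytest.raises(InvalidInputError):
            g.wavelength_from_energy(0.0)


class TestReciprocalBasis:
    def test_orthogonal_cell_is_diagonal(self, thaumatin_cell):
        B = g.reciprocal_basis(thaumatin_cell)
        assert np.allclose(np.diag(B), [1 / 58.52, 1 / 58.52, 1 / 151.30])
        assert np.allclose(B, np.triu(B))
        assert np.linalg.norm(B @ [0, 0, 4]) == pytest.approx(4 / 151.30, rel=1e-12)

    def test_matches_metric_tensor_on_random_cells(self):
        rng = np.random.default_rng(1)
        for cell in random_cells(20, seed=2):
            B = g.reciprocal_basis(cell)
            g_star = cell.reciprocal_metric()
            for m in rng.integers(-8, 9, size=(50, 3)):
                if not m.any():
                    continue
                inv_d2 = float(m @ g_star @ m)
                assert np.dot(B @ m, B @ m) == pytest.approx(inv_d2, rel=1e-10)

    def test_d_spacing_against_gemmi(self):
        for cell in random_cells(5, seed=3):
            gcell = gemmi.UnitCell(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)
            for m in [(1, 0, 0), (0, 0, 4), (1, 2, 3), (-3, 1, -2)]:
                assert g.d_spacing(cell, m) == pytest.approx(
                    gcell.calculate_d(m), rel=1e-9
                )

    def test_axial_d_spacings(self, thaumatin_cell):
        assert g.d_spacing(thaumatin_cell, (1, 0, 0)) == pytest.approx(58.52)
        assert g.d_spacing(thaumatin_cell, (0, 0, 4)) == pytest.approx(151.30 / 4)

    def test_zero_miller_rejected(self, thaumatin_cell):
        with pytest.raises(InvalidInputError):
            g.d_spacing(thaumatin_cell, (0, 0, 0))

    def test_degenerate_cell_rejected(self):
        with pytest.raises(InvalidInputError):
            g.UnitCell(10, 10, 10, 1e-8, 90, 90)


class TestEdgeResolution:
    def test_published_edge_resolutions(self):
        assert g.edge_resolution(95.0, 373.65, g.wavelength_from_energy(4.5)) == pytest.approx(2.6, abs=0.05)
        assert g.edge_resolution(95.5, 373.65, g.wavelength_from_energy(5.99)) == pytest.approx(2.0, abs=0.05)

    def test_monotone_in_distance(self):
        lam = 2.0
        ds = [g.edge_resolution(d, 373.65, lam) for d in (50, 95, 200, 1000)]
        assert ds == sorted(ds)
        assert g.edge_resolution(1e9, 373.65, lam) > 1e5  # d -> inf with distance


class TestOrientation:
    def test_deterministic(self):
        assert np.array_equal(g.random_orientation(5), g.random_orientation(5))
        assert not np.array_equal(g.random_orientation(5), g.random_orientation(6))
        assert np.array_equal(
            g.random_orientation(5, substream=2), g.random_orientation(5, substream=2)
        )

    def test_proper_rotation(self):
        for seed in range(20):
            R = g.random_orientation(seed)
            assert np.allclose(R @ R.T, np.eye(3), atol=1e-10)
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)

    def test_uniform_over_sphere(self):
        # E|z| = 0.5 for a uniformly distributed axis image
        zs = [abs(g.random_orientation(0, substream=i)[2, 2]) for i in range(10_000)]
        assert np.mean(zs) == pytest.approx(0.5, abs=0.02)


def brute_force_absent(m, sym):
    """Structure-factor oracle: symmetry-expand random atoms, check |F| ~ 0."""
    rng = np.random.default_rng(42)
    xyz = rng.uniform(size=(3, 3))
    F = 0.0
    for rot, tran in zip(sym.rotations, sym.translations):
        for x in xyz:
            xs = rot @ x + tran
            F += np.exp(2j * np.pi * np.dot(m, xs))
    return abs(F) < 1e-8


class TestSymmetry:
    def test_unsupported_group_rejected(self):
        with pytest.raises(UnsupportedSymmetryError):
            g.SymmetrySpec.from_symbol("P212121")

    def test_operator_closure_and_identity(self, p41212):
        ops = {
            (tuple(r.ravel()), tuple(np.round(t * 12).astype(int)))
            for r, t in zip(p41212.rotations, p41212.translations)
        }
        assert (tuple(np.eye(3, dtype=int).ravel()), (0, 0, 0)) in ops
        for r1, t1 in zip(p41212.rotations, p41212.translations):
            for r2, t2 in zip(p41212.rotations, p41212.translations):
                r = r1 @ r2
                t = (r1 @ t2 + t1) % 1.0
                assert (tuple(r.ravel()), tuple(np.round(t * 12).astype(int) % 12)) in ops

    def test_screw_axis_absences(self, p41212):
        assert g.is_absent((0, 0, 2), p41212)
        assert not g.is_absent((0, 0, 4), p41212)
        assert g.is_absent((3, 0, 0), p41212)
        assert not g.is_absent((4, 0, 0), p41212)

    def test_p1_has_no_absences(self, p1):
        m = np.array([[1, 0, 0], [0, 0, 1], [2, 3, 5]])
        assert not g.is_absent(m, p1).any()

    def test_absences_match_structure_factor_oracle(self, p41212):
        rng = np.random.default_rng(8)
        box = rng.integers(-8, 9, size=(300, 3))
        box = box[box.any(axis=1)]
        for m in map(tuple, box):
            assert g.is_absent(m, p41212) == brute_force_absent(m, p41212), m

    def test_absences_match_gemmi(self, p41212):
        ops = gemmi.SpaceGroup("P 41 21 2").operations()
        h, k, l = np.mgrid[-8:9, -8:9, -8:9]
        ms = np.column_stack([h.ravel(), k.ravel(), l.ravel()])
        ms = ms[ms.any(axis=1)]
        mine = g.is_absent(ms, p41212)
        theirs = np.array([ops.is_systematically_absent(list(m)) for m in ms])
        assert np.array_equal(mine, theirs)


class TestAsuMapping:
    def test_idempotent(self, p41212):
        rng = np.random.default_rng(4)
        for m in rng.integers(-10, 11, size=(100, 3)):
            if not m.any():
                continue
            canon, _ = g.map_to_asu(tuple(m), p41212)
            canon2, minus2 = g.map_to_asu(canon, p41212)
            assert canon2 == canon
            assert minus2 is False

    def test_friedel_mate_flags(self, p41212):
        canon, _ = g.map_to_asu((3, 5, 7), p41212)
        mate = tuple(-x for x in canon)
        canon_m, minus = g.map_to_asu(mate, p41212)
        assert canon_m == canon
        assert minus is True

    def test_orbit_collapses_to_one_representative(self, p41212):
        rng = np.random.default_rng(5)
        for m in rng.integers(-10, 11, size=(50, 3)):
            if not m.any():
                continue
            reps = set()
            for equiv in p41212.equivalents(m):
                for sign in (1, -1):
                    reps.add(g.map_to_asu(tuple(sign * equiv), p41212)[0])
            assert len(reps) == 1

    def test_centric_reflections_detected(self, p41212):
        # (h,k,0) zones are centric in 4/mmm-derived groups
        assert g.is_centric((3, 5, 0), p41212)
        assert not g.is_centric((3, 5, 7), p41212)


def brute_force_unique_count(cell, sym, d_max, d_min, friedel_separate):
    """Exhaustive loop + ASU de-duplication oracle for small cells."""
    reps = {}
    lim = int(max(cell.a, cell.b, cell.c) / d_min) + 1
    for h in range(-lim, lim + 1):
        for k in range(-lim, lim + 1):
            for l in range(-lim, lim + 1):
                if h == k == l == 0:
                    continue
                d = g.d_spacing(cell, (h, k, l))
                if not d_min <= d <= d_max:
                    continue
                if g.is_absent((h, k, l), sym):
                    continue
                canon, _ = g.map_to_asu((h, k, l), sym)
                reps[canon] = g.is_centric(canon, sym)
    n_cen = sum(reps.values())
    n_ace = len(reps) - n_cen
    return n_ace * (2 if friedel_separate else 1) + n_cen


class TestEnumerateUnique:
    def test_matches_brute_force_on_tiny_p1(self, p1):
        cell = g.UnitCell(10, 10, 10)
        res = g.enumerate_unique(cell, p1, 100.0, 5.0, friedel_separate=True)
        assert res["count"] == brute_force_unique_count(cell, p1, 100.0, 5.0, True)

    @pytest.mark.parametrize("friedel", [True, False])
    def test_matches_brute_force_p41212(self, p41212, friedel):
        cell = g.UnitCell(20, 20, 30)
        res = g.enumerate_unique(cell, p41212, 50.0, 6.0, friedel_separate=friedel)
        assert res["count"] == brute_force_unique_count(cell, p41212, 50.0, 6.0, friedel)

    def test_published_thaumatin_counts(self, thaumatin_cell, p41212):
        for (dmax, dmin), expected in [
            ((24.8, 2.0), 33_976),
            ((24.8, 2.2), 25_539),
            ((25.25, 2.05), 31_565),
        ]:
            res = g.enumerate_unique(
                thaumatin_cell, p41212, dmax, dmin,
                friedel_separate=True, include_absent=True,
            )
            assert res["count"] == expected

    def test_counts_scale_with_inverse_d_cubed(self, thaumatin_cell, p41212):
        counts = {}
        for dmin in (2.0, 2.2):
            counts[dmin] = g.enumerate_unique(
                thaumatin_cell, p41212, 24.8, dmin, include_absent=True
            )["count"]
        assert counts[2.0] / counts[2.2] == pytest.approx((2.2 / 2.0) ** 3, rel=0.01)

    def test_resolution_window_respected(self, thaumatin_cell, p41212):
        res = g.enumerate_unique(thaumatin_cell, p41212, 10.0, 3.0)
        assert res["d"].max() <= 10.0 * (1 + 1e-9)
        assert res["d"].min() >= 3.0 * (1 - 1e-9)
        assert not g.is_absent(res["miller"], p41212).any()

    def test_empty_range_rejected(self, thaumatin_cell, p41212):
        with pytest.raises(InvalidInputError):
            g.enumerate_unique(thaumatin_cell, p41212, 2.0, 24.8)


class TestDetectorProjection:
    det = g.DetectorGeometry(distance=95.0, side_length=373.65, pixel_size=0.075)

    def test_beam_centre_limit(self):
        xy = g.project_to_detector((0.0, 0.0, 0.0), 2.0, self.det)
        assert xy == pytest.approx(self.det.beam_center)

    def test_two_theta_recovered(self):
        lam = 2.0
        for two_theta in np.radians([10, 30, 60]):
            # reciprocal vector at scattering angle two_theta in the x-z plane
            q = np.array([np.sin(two_theta), 0.0, np.cos(two_theta) - 1.0]) / lam
            xy = g.project_to_detector(q, lam, self.det)
            r = np.hypot(xy[0] - self.det.beam_center[0], xy[1] - self.det.beam_center[1])
            assert np.arctan2(r, self.det.distance) == pytest.approx(two_theta, rel=1e-9)

    def test_backscatter_misses(self):
        lam = 2.0
        two_theta = np.radians(120.0)
        q = np.array([np.sin(two_theta), 0.0, np.cos(two_theta) - 1.0]) / lam
        assert g.project_to_detector(q, lam, self.det) is None

    def test_off_ewald_vector_rejected(self):
        with pytest.raises(GeometryInconsistencyError):
            g.project_to_detector((0.3, 0.2, 0.1), 2.0, self.det)
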