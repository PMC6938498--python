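import math

import numpy as np
import pytest

from tactoidmc.fields import FieldSpec, fixture_spec, synth_field
from tactoidmc.geometry import make_spindle
from tactoidmc.initial import InitSpec, build_initial
from tactoidmc.mc import Configuration
from tactoidmc.order import (angular_deficit, detect_defects, global_Q,
                             local_Q_field, segment_length_in_box,
                             total_charge, loop_winding, nematic_angle_diff)


class TestGlobalQ:
    def test_perfect_order_along_y(self):
        u = np.tile([0.0, 1.0, 0.0], (20, 1))
        g = global_Q(u)
        assert g.S == pytest.approx(1.0)
        assert abs(g.n[1]) == pytest.approx(1.0)
        assert np.trace(g.Q) == pytest.approx(0.0, abs=1e-10)

    def test_fifty_fifty_mix_hand_worked(self):
        """Half x-hat, half y-hat: eigenvalues (1/4, 1/4, -1/2), S = 1/4."""
        u = np.array([[1.0, 0, 0]] * 10 + [[0, 1.0, 0]] * 10)
        g = global_Q(u)
        w = np.sort(np.linalg.eigvalsh(g.Q))
        assert w == pytest.approx([-0.5, 0.25, 0.25])
        assert g.S == pytest.approx(0.25)

    def test_isotropic_limit(self, rng):
        u = rng.normal(size=(10_000, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        assert global_Q(u).S <= 0.05

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            global_Q(np.zeros((0, 3)))


class TestSegmentClipping:
    def test_fully_inside(self):
        l = segment_length_in_box((0.1, 0.1, 0.1), (0.9, 0.1, 0.1),
                                  (0, 0, 0), (1, 1, 1))
        assert l == pytest.approx(0.8)

    def test_crossing_one_face_at_midpoint(self):
        l = segment_length_in_box((0.5, 0.5, 0.5), (1.5, 0.5, 0.5),
                                  (0, 0, 0), (1, 1, 1))
        assert l == pytest.approx(0.5)

    def test_against_numerical_arclength(self, rng):
        lo, hi = np.zeros(3), np.ones(3)
        t = np.linspace(0, 1, 10_001)
        for _ in range(10):
            p0 = rng.uniform(-0.5, 1.5, 3)
            p1 = rng.uniform(-0.5, 1.5, 3)
            pts = p0[None] + t[:, None] * (p1 - p0)[None]
            inside = np.all((pts >= lo) & (pts <= hi), axis=1)
            numeric = inside.mean() * np.linalg.norm(p1 - p0)
            exact = segment_length_in_box(p0, p1, lo, hi)
            assert abs(exact - numeric) < 1e-3 * max(1.0, numeric)


class TestLocalField:
    def test_aligned_configuration_is_uniformly_ordered(self, spindle90):
        cfg = build_initial(spindle90, InitSpec("along_major", 0.12, 3),
                            20.0, 1.0)
        f = local_Q_field(cfg, 10.0)
        occ = f.occupied
        assert np.all(f.Sk[occ] > 0.9)
        assert np.all(np.abs(f.nk[occ][:, 1]) > 0.95)

    def test_rod_split_equally_between_two_cells(self):
        # Ly = 80 gives an even row count: cell edges meet exactly at y = 0,
        # so a centered axial rod splits half-and-half between two rows
        g = make_spindle(80, 1.5, 6)
        pos = np.array([[0.0, 0.0, 3.0]])
        ort = np.array([[0.0, 1.0, 0.0]])
        cfg = Configuration(g, pos, ort, 20.0, 1.0)
        f = local_Q_field(cfg, 10.0)
        cells = np.argwhere(f.occupancy > 0)
        assert len(cells) == 2
        w = f.occupancy[f.occupancy > 0]
        assert w == pytest.approx([10.0, 10.0])
        q1, q2 = (f.Qk[tuple(c)] for c in cells)
        np.testing.assert_allclose(q1, q2, atol=1e-12)

    def test_weight_conservation(self, spindle90):
        cfg = build_initial(spindle90, InitSpec("tilt45", 0.16, 13), 20.0, 1.0)
        f = local_Q_field(cfg, 10.0)
        assert f.occupancy.sum() == pytest.approx(cfg.n * 20.0, rel=1e-6)

    def test_cell_size_out_of_range(self, spindle90):
        cfg = build_initial(spindle90, InitSpec("along_minor", 0.05, 1),
                            20.0, 1.0)
        with pytest.raises(ValueError):
            local_Q_field(cfg, 0.5)


class TestAngularDeficit:
    def test_uniform_field_vanishes(self, spindle90):
        f = synth_field(fixture_spec("H", spindle90), 10.0)
        delta = angular_deficit(f)
        assert np.nanmax(delta) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("charge", [0.5, -0.5])
    def test_plaquette_hand_value_at_defect(self, charge):
        """Neighbor directors at angles (0, 45, 90, 135) degrees around a
        half-integer defect give delta = pi/2 + pi/2 = pi, for either sign."""
        f = synth_field(fixture_spec("H", make_spindle(90, 1.5, 6)), 10.0)
        nk = f.nk.copy()
        ix, iy = 3, 4
        sgn = charge / abs(charge)
        for (dx, dy, ang) in [(1, 0, 0.0), (0, 1, sgn * 45.0),
                              (-1, 0, sgn * 90.0), (0, -1, sgn * 135.0)]:
            th = math.radians(ang)
            nk[ix + dx, iy + dy] = [math.cos(th), math.sin(th), 0.0]
        f.nk = nk
        delta = angular_deficit(f)
        assert delta[ix, iy] == pytest.approx(math.pi)

    def test_maximal_at_seeded_core(self, spindle90):
        """For an isolated interior defect the deficit peaks next to it."""
        spec = FieldSpec("seed", spindle90, ((5.0, 5.0),), (0.5,))
        f = synth_field(spec, 10.0)
        delta = angular_deficit(f)
        flat = np.nan_to_num(delta, nan=-1.0)
        ix, iy = np.unravel_index(np.argmax(flat), flat.shape)
        assert math.hypot(f.x_centers[ix] - 5.0,
                          f.y_centers[iy] - 5.0) <= 1.5 * 10.0

    def test_too_few_cells_raises(self):
        g = make_spindle(25, 1.5, 6)
        f = synth_field(fixture_spec("H", g), 20.0)
        with pytest.raises(ValueError):
            angular_deficit(f)


class TestDefectDetection:
    def test_seeded_half_defect(self, spindle90):
        spec = FieldSpec("seed", spindle90, ((5.0, 5.0),), (0.5,))
        f = synth_field(spec, 10.0)
        ds = [d for d in detect_defects(f) if d.charge > 0]
        assert len(ds) >= 1
        best = min(ds, key=lambda d: np.linalg.norm(d.position - [5, 5]))
        assert best.charge == pytest.approx(0.5)
        assert np.linalg.norm(best.position - [5, 5]) <= 10.0

    def test_radial_hedgehog_is_plus_one(self, circle90):
        spec = FieldSpec("hh", circle90, ((0.0, 0.0),), (1.0,),
                         background_angle=0.0)
        f = synth_field(spec, 10.0)
        ds = detect_defects(f)
        assert len(ds) == 1
        assert ds[0].charge == pytest.approx(1.0)
        assert np.linalg.norm(ds[0].position) < 10.0

    def test_uniform_field_empty(self, spindle90):
        f = synth_field(fixture_spec("H", spindle90), 10.0)
        assert detect_defects(f) == []

    def test_loop_without_defect_has_zero_winding(self, spindle90):
        spec = FieldSpec("seed", spindle90, ((0.0, -30.0),), (0.5,))
        f = synth_field(spec, 10.0)
        # a small square loop far from the singularity
        loop = [(2, 5), (3, 5), (3, 6), (2, 6)]
        assert loop_winding(f, loop) == pytest.approx(0.0, abs=1e-9)

    def test_gauge_invariance_under_director_sign_flips(self, spindle90, rng):
        f = synth_field(fixture_spec("Bpar", spindle90), 10.0)
        base = [(round(d.position[0], 6), round(d.position[1], 6), d.charge)
                for d in detect_defects(f)]
        delta0 = angular_deficit(synth_field(fixture_spec("Bpar", spindle90),
                                             10.0))
        flips = rng.choice([-1.0, 1.0], size=f.nk.shape[:2])
        f.nk = f.nk * flips[..., None]
        flipped = [(round(d.position[0], 6), round(d.position[1], 6), d.charge)
                   for d in detect_defects(f)]
        assert flipped == base
        delta1 = angular_deficit(f)
        np.testing.assert_allclose(np.nan_to_num(delta1),
                                   np.nan_to_num(delta0), atol=1e-9)

    def test_deficit_and_winding_maxima_colocalize(self, circle90):
        spec = FieldSpec("hh", circle90, ((0.0, 0.0),), (1.0,),
                         background_angle=0.0)
        f = synth_field(spec, 10.0)
        delta = angular_deficit(f)
        flat = np.nan_to_num(delta, nan=-1.0)
        ix, iy = np.unravel_index(np.argmax(flat), flat.shape)
        peak = np.array([f.x_centers[ix], f.y_centers[iy]])
        d0 = detect_defects(f)[0]
        assert np.linalg.norm(peak - d0.position) <= 1.5 * 10.0

    def test_scalar_order_bounds(self, spindle90):
        cfg = build_initial(spindle90, InitSpec("hedgehog", 0.16, 2),
                            20.0, 1.0)
        f = local_Q_field(cfg, 10.0)
        occ = f.occupied
        assert np.all(f.Sk[occ] >= -0.5 - 1e-9)
        assert np.all(f.Sk[occ] <= 1.0 + 1e-9)


class TestTotalCharge:
    def test_bipolar_fixture_sums_to_one(self):
        g = make_spindle(300, 1.5, 6)
        f = synth_field(fixture_spec("Bpar", g), 10.0)
        assert total_charge(detect_defects(f)) == pytest.approx(1.0)

    def test_m6_fixture_sums_to_one(self):
        g = make_spindle(240, 1.5, 6)
        f = synth_field(fixture_spec("M6", g), 10.0)
        ds = detect_defects(f)
        assert sorted(d.charge for d in ds) == [-0.5, -0.5, 0.5, 0.5, 0.5, 0.5]
        assert total_charge(ds) == pytest.approx(1.0)

    def test_empty_list(self):
        assert total_charge([]) == 0.0


class TestNematicAngleDiff:
    @pytest.mark.parametrize("a,b,expect", [
        (0.0, 0.3, 0.3),
        (0.0, math.pi, 0.0),             # head-tail equivalent
        (0.1, 0.1 + math.pi / 2, math.pi / 2),  # fold boundary -> +pi/2
        (0.0, 2.0, 2.0 - math.pi),
    ])
    def test_folding(self, a, b, expect):
        assert nematic_angle_diff(a, b) == pytest.approx(expect)
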