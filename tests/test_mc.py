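import numpy as np
import pytest

from tactoidmc.geometry import make_spindle
from tactoidmc.initial import InitSpec, build_initial
from tactoidmc.mc import (Configuration, MCParams, Rod, min_distance_segments,
                          overlap, run_sweeps, trial_move)


def _rod(r, u, L=20.0, d=1.0):
    return Rod(r=np.array(r, float), u=np.array(u, float), L=L, d=d)


class TestSegmentDistance:
    def test_parallel_offset(self):
        d = min_distance_segments((0, 0, 0), (1, 0, 0), (0, 1, 1), (1, 1, 1))
        assert d == pytest.approx(np.sqrt(2))

    def test_perpendicular_crossing(self):
        d = min_distance_segments((0, 0, 0), (2, 0, 0), (1, -1, 1), (1, 1, 1))
        assert d == pytest.approx(1.0)

    def test_symmetry_and_degenerate_points(self):
        a = min_distance_segments((0, 0, 0), (0, 0, 0), (1, 1, 1), (1, 1, 1))
        assert a == pytest.approx(np.sqrt(3))

    def test_matches_grid_search_oracle(self, rng):
        """Closed-form minimum vs brute-force sampling of both parameters."""
        t = np.linspace(0.0, 1.0, 1001)
        for _ in range(5):
            a0, a1, b0, b1 = rng.uniform(-3, 3, size=(4, 3))
            pa = a0[None] + t[:, None] * (a1 - a0)[None]
            pb = b0[None] + t[:, None] * (b1 - b0)[None]
            diff = pa[:, None, :] - pb[None, :, :]
            brute = np.sqrt((diff**2).sum(-1)).min()
            exact = min_distance_segments(a0, a1, b0, b1)
            assert exact <= brute + 1e-12
            assert brute - exact < 1e-3


class TestOverlap:
    def test_identical_rods_overlap(self):
        r = _rod((0, 0, 0), (1, 0, 0))
        assert overlap(r, r)

    @pytest.mark.parametrize("gap,expect", [(1.001, False), (0.999, True)])
    def test_parallel_at_contact_distance(self, gap, expect):
        r1 = _rod((0, 0, 0), (1, 0, 0))
        r2 = _rod((0, gap, 0), (1, 0, 0))
        assert overlap(r1, r2) is expect


class TestTrialMove:
    def _lone_rod_config(self):
        g = make_spindle(90, 1.5, 6)
        return Configuration(g, np.array([[0.0, 0.0, 3.0]]),
                             np.array([[0.0, 1.0, 0.0]]), 20.0, 1.0)

    def test_free_rod_small_move_accepted(self, rng):
        cfg = self._lone_rod_config()
        accepted = sum(
            trial_move(cfg, 0, MCParams(dr_max=0.01, dtheta_max=0.01), rng)
            for _ in range(50))
        assert accepted == 50

    def test_wall_violation_rejected_and_state_unchanged(self, rng):
        cfg = self._lone_rod_config()
        # park the rod flush against the depth limit; huge vertical moves
        # will mostly propose wall violations
        before_pos = cfg.pos.copy()
        before_ort = cfg.ort.copy()
        rejected = 0
        for _ in range(100):
            if not trial_move(cfg, 0, MCParams(dr_max=6.0, dtheta_max=0.01),
                              rng):
                rejected += 1
        assert rejected > 0
        cfg.validate()
        if rejected == 100:
            np.testing.assert_array_equal(cfg.pos, before_pos)
            np.testing.assert_array_equal(cfg.ort, before_ort)

    def test_vanishing_amplitudes_accept_everything(self, spindle90, rng):
        cfg = build_initial(spindle90, InitSpec("along_minor", 0.16, 5),
                            20.0, 1.0)
        acc = sum(trial_move(cfg, int(rng.integers(cfg.n)),
                             MCParams(dr_max=1e-9, dtheta_max=1e-9), rng)
                  for _ in range(1000))
        assert acc == 1000

    def test_index_out_of_range(self, rng):
        cfg = self._lone_rod_config()
        with pytest.raises(IndexError):
            trial_move(cfg, 5, MCParams(), rng)


class TestRunSweeps:
    def test_zero_sweeps_single_frame(self, spindle90):
        cfg = build_initial(spindle90, InitSpec("along_minor", 0.16, 7),
                            20.0, 1.0)
        traj = run_sweeps(cfg, MCParams(sweeps=0, seed=1))
        assert len(traj) == 1
        assert traj.frames[0].sweep == 0

    def test_same_seed_identical_trajectories(self, spindle90):
        p = MCParams(sweeps=60, sample_every=20, seed=42)
        runs = []
        for _ in range(2):
            cfg = build_initial(spindle90, InitSpec("along_minor", 0.16, 7),
                                20.0, 1.0)
            runs.append(run_sweeps(cfg, p))
        for f1, f2 in zip(runs[0].frames, runs[1].frames):
            np.testing.assert_array_equal(f1.pos, f2.pos)
            np.testing.assert_array_equal(f1.ort, f2.ort)

    def test_invariants_every_frame_50_rods(self):
        """Hard-core + hard-wall hold on every sampled frame, checked with
        the all-pairs oracle (which also cross-validates the cell list)."""
        g = make_spindle(60, 1.5, 6)
        cfg = build_initial(g, InitSpec("along_major", 0.0875, 3), 20.0, 1.0)
        assert 40 <= cfg.n <= 60
        traj = run_sweeps(cfg, MCParams(sweeps=500, sample_every=25, seed=9))
        assert len(traj) == 21
        for sweep, frame_cfg in traj.configurations(g, 20.0, 1.0):
            frame_cfg.validate()   # raises on any overlap or wall violation

    def test_acceptance_fraction_reasonable(self, spindle90):
        cfg = build_initial(spindle90, InitSpec("along_minor", 0.16, 8),
                            20.0, 1.0)
        traj = run_sweeps(cfg, MCParams(sweeps=50, sample_every=50, seed=3))
        assert 0.0 < traj.meta["acceptance"] < 1.0

    def test_dilute_gas_uniform_density_in_circle(self):
        """Center-of-mass density in a dilute circular system is uniform
        over the eroded disk within 3 sigma of counting noise per bin."""
        g = make_spindle(44, 1.0, 6)
        cfg = build_initial(g, InitSpec("along_minor", 0.004, 21), 4.0, 1.0)
        n = cfg.n
        assert n >= 8
        samples = []

        def grab(sweep, c):
            if sweep > 2000:          # discard the ordered start
                samples.append(c.pos[:, :2].copy())

        run_sweeps(cfg, MCParams(sweeps=30_000, sample_every=500, seed=4,
                                 dr_max=2.0, dtheta_max=0.8),
                   observers=[grab])
        pts = np.concatenate(samples)
        r = np.hypot(pts[:, 0], pts[:, 1])
        # support of the center distribution: largest observed radius
        # (the analytic bound depends on the rod's in-plane projection)
        r_sup = r.max() * 1.001
        nbins = 4
        edges = np.sqrt(np.linspace(0, r_sup**2, nbins + 1))  # equal areas
        counts, _ = np.histogram(r, edges)
        total = counts.sum()
        expect = total / nbins
        # correlated samples: effective sample size reduced; allow 3 sigma
        # with a conservative inflation factor of 2 for autocorrelation
        sigma = np.sqrt(expect) * 2.0
        assert np.all(np.abs(counts - expect) < 3 * sigma + 3)

    def test_refuses_invalid_start(self, spindle90):
        pos = np.array([[0.0, 0.0, 3.0], [0.0, 0.5, 3.0]])
        ort = np.array([[1.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        cfg = Configuration(spindle90, pos, ort, 20.0, 1.0)
        with pytest.raises(ValueError):
            run_sweeps(cfg, MCParams(sweeps=10, seed=1))
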