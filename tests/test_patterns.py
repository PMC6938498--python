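import numpy as np
import pytest

from tactoidmc.fields import fixture_spec, synth_field
from tactoidmc.geometry import make_spindle
from tactoidmc.mc import Frame, Trajectory
from tactoidmc.order import Defect, detect_defects
from tactoidmc.patterns import (EquilibrationCriteria, classify_pathway,
                                classify_pattern, equilibration_time,
                                locale_of, majority_filter, NEVER,
                                pathway_statistics, PathwayLabel)

from tests.test_fields import GALLERY


class TestLocale:
    @pytest.mark.parametrize("pos,expect", [
        ((0.0, 45.0), "cusp"),
        ((30.0, 0.0), "boundary"),
        ((0.0, 0.0), "interior"),
    ])
    def test_examples(self, spindle90, pos, expect):
        d = Defect(position=np.array(pos), charge=0.5)
        assert locale_of(d, spindle90, cusp_tol=10.0, boundary_tol=10.0) \
            == expect

    def test_bad_tolerances(self, spindle90):
        d = Defect(position=np.array([0.0, 0.0]), charge=0.5)
        with pytest.raises(ValueError):
            locale_of(d, spindle90, cusp_tol=0.0, boundary_tol=1.0)


class TestClassifier:
    @pytest.mark.parametrize("pattern", sorted(GALLERY))
    def test_full_fixture_suite_zero_noise(self, pattern):
        Ly, aspect = GALLERY[pattern]
        f = synth_field(fixture_spec(pattern, make_spindle(Ly, aspect, 6.0)),
                        10.0)
        assert str(classify_pattern(f, L=20.0)) == pattern

    @pytest.mark.parametrize("pattern", ["Bpar", "Dh", "M6"])
    def test_mirror_symmetry_invariance(self, pattern):
        """Flipping the field x -> -x and y -> -y must not change the label
        (the detection grid is symmetric, so array reversal realizes the
        mirrored field)."""
        Ly, aspect = GALLERY[pattern]
        f = synth_field(fixture_spec(pattern, make_spindle(Ly, aspect, 6.0)),
                        10.0)
        base = str(classify_pattern(f, L=20.0))
        f.nk = f.nk[::-1, ::-1].copy()
        f.nk[..., 0] *= -1.0
        f.nk[..., 1] *= -1.0
        f.Sk = f.Sk[::-1, ::-1].copy()
        f.occupancy = f.occupancy[::-1, ::-1].copy()
        f.inside_mask = f.inside_mask[::-1, ::-1].copy()
        assert str(classify_pattern(f, L=20.0)) == base == pattern

    def test_director_sign_flip_invariance(self, rng):
        Ly, aspect = GALLERY["Dh"]
        f = synth_field(fixture_spec("Dh", make_spindle(Ly, aspect, 6.0)),
                        10.0)
        flips = rng.choice([-1.0, 1.0], size=f.nk.shape[:2])
        f.nk = f.nk * flips[..., None]
        assert str(classify_pattern(f, L=20.0)) == "Dh"

    def test_unanalyzable_field_raises(self):
        g = make_spindle(25, 1.5, 6)
        f = synth_field(fixture_spec("H", g), 20.0)
        with pytest.raises(ValueError):
            classify_pattern(f, L=20.0)


class TestMajorityFilter:
    def test_suppresses_transients(self):
        assert majority_filter([2, 2, 4, 2, 2, 2], 5) == [2, 2, 2, 2, 2, 2]

    def test_short_series_raises(self):
        with pytest.raises(ValueError):
            majority_filter([1, 2], 5)


class TestPathwayClassifier:
    def test_melt_through_six_defects(self):
        assert str(classify_pathway([2, 6, 6, 6, 2, 2], window=3)) == "melt"

    def test_slide_through_four_defects(self):
        assert str(classify_pathway([2, 4, 4, 2, 2], window=3)) == "slide"

    def test_turn_rotating_two_defect_sequence(self):
        labels = ["Dh", "Dstarstar", "Dstarstar", "Bpar"]
        assert str(classify_pathway([2, 2, 2, 2], labels, window=3)) == "turn"

    def test_no_rotation_is_other(self):
        labels = ["Bpar", "Bpar", "Bpar", "Bpar"]
        assert str(classify_pathway([2, 2, 2, 2], labels, window=3)) == "other"


def _traj_from_orientations(ort_per_frame):
    frames = [Frame(1000 * k, np.zeros((len(o), 3)), np.asarray(o, float))
              for k, o in enumerate(ort_per_frame)]
    return Trajectory(frames=frames, meta={})


class TestEquilibrationTime:
    def _aligned(self, n=60):
        return np.tile([0.0, 1.0, 0.0], (n, 1))

    def _disordered(self, rng, n=60):
        u = rng.normal(size=(n, 3))
        return u / np.linalg.norm(u, axis=1, keepdims=True)

    def test_already_equilibrated_returns_zero(self):
        traj = _traj_from_orientations([self._aligned()] * 12)
        crit = EquilibrationCriteria(hold_window=10)
        assert equilibration_time(traj, crit) == 0.0

    def test_never_ordering_returns_sentinel(self, rng):
        traj = _traj_from_orientations([self._disordered(rng)
                                        for _ in range(12)])
        assert equilibration_time(traj) == NEVER

    def test_threshold_crossing_time(self, rng):
        frames = [self._disordered(rng) for _ in range(5)] \
            + [self._aligned() for _ in range(15)]
        traj = _traj_from_orientations(frames)
        crit = EquilibrationCriteria(hold_window=10)
        assert equilibration_time(traj, crit) == 5000.0


class TestPathwayStatistics:
    def test_single_run_frequencies_are_indicator(self, spindle90):
        table = pathway_statistics(lambda g, s: PathwayLabel("melt"),
                                   [spindle90], n_runs=1)
        row = table.iloc[0]
        assert set(row) <= {0.0, 1.0}
        assert row.sum() == pytest.approx(1.0)

    def test_frequencies_sum_to_one_and_errors_are_other(self, spindle90):
        def flaky(geom, seed):
            if seed % 3 == 0:
                raise RuntimeError("boom")
            return PathwayLabel("turn" if seed % 2 else "slide")

        table = pathway_statistics(flaky, {"g": spindle90}, n_runs=10,
                                   seeds=list(range(10)))
        row = table.loc["g"]
        assert row.sum() == pytest.approx(1.0)
        assert row["other"] > 0
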