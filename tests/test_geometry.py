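"""Spherical projection and msd minimisation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trajgeom import (
    DegeneratePathError,
    DirectionResult,
    Path,
    find_center,
    mean_spherical_distance,
    representative_center,
    spherical_distance,
    unit_vectors,
)

SQ2 = np.sqrt(2.0) / 2.0
SQ3 = 1.0 / np.sqrt(3.0)
THREE_AXIS_MSD = np.arccos(SQ3)  # each axis at equal angle from (1,1,1)/sqrt(3)


def unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


@st.composite
def unit_vector_sets(draw, d=3, max_m=12):
    m = draw(st.integers(min_value=1, max_value=max_m))
    raw = draw(
        st.lists(
            st.lists(
                st.floats(-1, 1, allow_nan=False, width=32), min_size=d, max_size=d
            ).filter(lambda row: np.linalg.norm(row) > 1e-3),
            min_size=m,
            max_size=m,
        )
    )
    return np.array([unit(row) for row in raw])


class TestPathValidation:
    def test_rejects_short_and_flat_paths(self):
        with pytest.raises(ValueError, match="at least 3 points"):
            Path(points=np.zeros((2, 3)))
        with pytest.raises(ValueError, match="dimension"):
            Path(points=np.arange(3.0)[:, None])

    def test_rejects_non_increasing_window_index(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            Path(points=np.random.default_rng(0).normal(size=(3, 2)),
                 window_index=[0, 2, 2])


class TestUnitVectors:
    @pytest.mark.parametrize(
        "points, expected, dropped",
        [
            ([(0, 0, 0), (3, 0, 0), (5, 0, 0)], [(1, 0, 0), (1, 0, 0)], 0),
            ([(0, 0), (1, 1), (2, 2)], [(SQ2, SQ2), (SQ2, SQ2)], 0),
            ([(0, 0, 0), (0, 0, 0), (1, 0, 0)], [(1, 0, 0)], 1),
        ],
    )
    def test_projection_examples(self, points, expected, dropped):
        s = unit_vectors(Path(points=np.array(points, dtype=float)))
        np.testing.assert_allclose(s.vectors, np.array(expected, dtype=float), atol=1e-12)
        assert s.dropped_count == dropped
        assert s.m + s.dropped_count == len(points) - 1

    def test_all_displacements_degenerate(self):
        with pytest.raises(DegeneratePathError, match="degenerate"):
            unit_vectors(Path(points=np.zeros((4, 3))))


class TestSphericalDistance:
    @pytest.mark.parametrize(
        "u, v, expected",
        [
            ((1, 0, 0), (0, 1, 0), np.pi / 2),
            ((1, 0, 0), (1, 0, 0), 0.0),
            ((1, 0, 0), (-1, 0, 0), np.pi),
        ],
    )
    def test_examples(self, u, v, expected):
        assert spherical_distance(np.array(u, float), np.array(v, float)) == pytest.approx(expected)

    def test_rejects_non_unit_input(self):
        with pytest.raises(ValueError, match="unit vector"):
            spherical_distance(np.array([2.0, 0, 0]), np.array([1.0, 0, 0]))

    @settings(deadline=None, max_examples=50)
    @given(unit_vector_sets(max_m=3))
    def test_symmetry_and_triangle_inequality(self, vecs):
        u = vecs[0]
        v = vecs[len(vecs) // 2]
        w = vecs[-1]
        duv = spherical_distance(u, v)
        assert duv == pytest.approx(spherical_distance(v, u))
        assert 0.0 <= duv <= np.pi
        assert spherical_distance(u, w) <= duv + spherical_distance(v, w) + 1e-9


class TestMeanSphericalDistance:
    def test_examples(self):
        assert mean_spherical_distance(
            np.array([1.0, 0, 0]), np.array([[1.0, 0, 0], [1.0, 0, 0]])
        ) == pytest.approx(0.0)
        assert mean_spherical_distance(
            np.array([0, 0, 1.0]), np.array([[1.0, 0, 0], [0, 1.0, 0]])
        ) == pytest.approx(np.pi / 2)
        assert mean_spherical_distance(
            unit([1, 1, 1]), np.eye(3)
        ) == pytest.approx(THREE_AXIS_MSD)

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            mean_spherical_distance(np.array([1.0, 0, 0]), np.empty((0, 3)))


class TestFindCenter:
    def test_single_vector(self):
        res = find_center(np.array([[1.0, 0, 0]]))
        np.testing.assert_allclose(res.center, [1, 0, 0], atol=1e-9)
        assert res.msd == pytest.approx(0.0, abs=1e-12)
        assert res.converged

    def test_three_axis_symmetric_set(self):
        res = find_center(np.eye(3))
        np.testing.assert_allclose(res.center, [SQ3] * 3, atol=1e-6)
        assert res.msd == pytest.approx(THREE_AXIS_MSD, abs=1e-6)

    def test_orthogonal_pair_flat_minimum(self):
        # every point of the connecting geodesic attains pi/4; the
        # starting-point convention selects the midpoint
        res = find_center(np.array([[1.0, 0, 0], [0, 1.0, 0]]))
        assert res.msd == pytest.approx(np.pi / 4, abs=1e-12)
        np.testing.assert_allclose(res.center, [SQ2, SQ2, 0.0], atol=1e-9)

    def test_antipodal_pair_falls_back_to_first_vector(self):
        # objective is constant pi/2 everywhere: no improvement possible
        res = find_center(np.array([[1.0, 0, 0], [-1.0, 0, 0]]))
        assert res.msd == pytest.approx(np.pi / 2)
        np.testing.assert_allclose(res.center, [1, 0, 0], atol=1e-9)
        assert not res.converged

    @settings(deadline=None, max_examples=40)
    @given(unit_vector_sets())
    def test_monotone_improvement_and_range(self, vecs):
        res = find_center(vecs)
        assert res.msd <= res.start_msd + 1e-12
        assert 0.0 <= res.msd <= np.pi
        assert np.linalg.norm(res.center) == pytest.approx(1.0, abs=1e-9)

    def test_rotation_invariance(self, rng):
        from scipy.stats import ortho_group

        vecs = rng.normal(size=(8, 3)) + np.array([4.0, 0, 0])
        vecs /= np.linalg.norm(vecs, axis=1)[:, None]
        base = find_center(vecs)
        for Q in ortho_group.rvs(3, size=3, random_state=7):
            rotated = find_center(vecs @ Q.T)
            assert rotated.msd == pytest.approx(base.msd, abs=1e-6)
            assert spherical_distance(rotated.center, unit(Q @ base.center)) < 1e-3

    def test_collinear_path_zero_msd(self):
        t = np.linspace(0, 9, 10)
        path = Path(points=np.outer(t, [2.0, -1.0, 0.5]) + np.array([3.0, 3.0, 3.0]))
        res = find_center(unit_vectors(path))
        assert res.msd < 1e-9

    def test_agrees_with_coarse_grid_oracle(self, grid_oracle, rng):
        for _ in range(5):
            m = rng.integers(2, 13)
            vecs = rng.normal(size=(m, 3))
            vecs /= np.linalg.norm(vecs, axis=1)[:, None]
            res = find_center(vecs)
            oracle = grid_oracle(vecs, resolution_deg=0.5)
            assert res.msd <= oracle + 1e-3
            assert abs(res.msd - oracle) < 2e-3


class TestRepresentativeCenter:
    def test_identical_centers(self):
        v = unit([1, 2, 3])
        res = representative_center([v, v, v])
        np.testing.assert_allclose(res.center, v, atol=1e-9)
        assert res.msd == pytest.approx(0.0, abs=1e-9)

    def test_three_axis_centers(self):
        res = representative_center(np.eye(3))
        np.testing.assert_allclose(res.center, [SQ3] * 3, atol=1e-6)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            representative_center([])


def test_direction_result_enforces_invariants():
    with pytest.raises(ValueError, match="unit vector"):
        DirectionResult(center=np.array([2.0, 0, 0]), msd=0.1, start_msd=0.2,
                        steps_used=1, converged=True)
    with pytest.raises(ValueError, match="starting msd"):
        DirectionResult(center=np.array([1.0, 0, 0]), msd=0.3, start_msd=0.2,
                        steps_used=1, converged=True)
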