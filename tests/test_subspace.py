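import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import subspace_angles

from instasub import (
    SyntheticConfig,
    angle_course,
    chance_angles,
    cross_context_angles,
    generate_session,
    instantaneous_subspaces,
    principal_angles,
)
from instasub.subspace import random_frame
from tests.conftest import SMALL


def _frame(rng, n, k=3):
    return random_frame(n, rng, k)


class TestPrincipalAngles:
    def test_self_is_zero(self, rng):
        A = _frame(rng, 8)
        assert np.allclose(principal_angles(A, A), 0.0, atol=1e-6)

    def test_disjoint_coordinate_triples_are_orthogonal(self):
        A = np.eye(6)[:, :3]
        B = np.eye(6)[:, 3:]
        assert np.allclose(principal_angles(A, B), 90.0)

    def test_matches_scipy_oracle(self, rng):
        """Agreement with scipy's independent implementation in 5 dims.

        Two 3D subspaces of a 5D space always share one direction, so the
        first angle is structurally zero there; cosines are compared at 1e-8
        (angle agreement is limited by the oracle's conditioning at 0)."""
        for _ in range(25):
            A, B = _frame(rng, 5), _frame(rng, 5)
            mine = principal_angles(A, B)
            oracle = np.degrees(np.sort(subspace_angles(A, B)))
            assert np.allclose(np.cos(np.radians(mine)),
                               np.cos(np.radians(oracle)), atol=1e-8)
            assert np.allclose(mine, oracle, atol=1e-5)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_symmetry_and_rotation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        A, B = _frame(rng, 7), _frame(rng, 7)
        assert np.allclose(principal_angles(A, B), principal_angles(B, A), atol=1e-9)
        R = _frame(rng, 3, 3)  # random 3x3 orthogonal
        assert np.allclose(
            principal_angles(A @ R, B), principal_angles(A, B), atol=1e-8
        )

    def test_non_orthonormal_input_rejected(self, rng):
        A = _frame(rng, 6)
        with pytest.raises(ValueError, match="orthonormal"):
            principal_angles(2.0 * A, A)


class TestInstantaneousSubspaces:
    def test_three_components_capture_all_variance(self, small_tensors):
        """The 4 centered condition means are rank <= 3, so the 3 retained
        components conserve the total variance at every time step."""
        te, _ = small_tensors
        series = instantaneous_subspaces(te)
        cm = series.condition_means  # (T, 4, N)
        centered = cm - cm.mean(axis=1, keepdims=True)
        total = (centered**2).sum(axis=(1, 2)) / 4.0
        got = series.explained_variance.sum(axis=1)
        assert np.allclose(got, total, atol=1e-10 * max(1.0, total.max()))

    def test_bases_orthonormal(self, small_tensors):
        te, _ = small_tensors
        series = instantaneous_subspaces(te)
        g = np.einsum("tnk,tnm->tkm", series.bases, series.bases)
        assert np.allclose(g, np.eye(3)[None], atol=1e-9)

    def test_rank_deficient_completion_deterministic(self, small_tensors):
        te, _ = small_tensors
        flat = {o: np.ones_like(te.tensors[o]) for o in ("sphere", "button", "coax", "perp")}
        clone = type(te)(
            tensors=flat, events=te.events, offsets=te.offsets, stats=te.stats,
            unit_ids=te.unit_ids, sigma_ms=te.sigma_ms, sqrt_applied=False,
        )
        s1 = instantaneous_subspaces(clone)
        s2 = instantaneous_subspaces(clone)
        assert np.array_equal(s1.bases, s2.bases)
        assert np.allclose(s1.explained_variance, 0.0)

    def test_planted_basis_recovered_noise_free(self, small_session):
        _, _, gt = small_session
        tensor = gt.to_aligned_tensor("execution", sqrt=False)
        series = instantaneous_subspaces(tensor)
        # columns after instruction onset, where condition dependence is live
        for t in (gt.column_of("I", 300), gt.column_of("G", 0), gt.T - 1):
            a = principal_angles(series.bases[t], gt.bases["execution"][t])
            assert a[0] < 2.0

    def test_too_few_units_rejected(self, small_tensors):
        from instasub.preprocess import subset_units

        te, _ = small_tensors
        with pytest.raises(ValueError, match="3 units"):
            instantaneous_subspaces(subset_units(te, [0, 1]))


class TestAngleCourse:
    def test_static_subspace_stays_near_zero(self):
        cfg = SyntheticConfig(**{**SMALL, "subspace_rotation_rate": 0.0,
                                 "noise_sd": 0.0, "cd_onset": None})
        _, gt = generate_session(cfg, "execution")
        tensor = gt.to_aligned_tensor("execution")
        course = angle_course(tensor, "M", n_folds=2, trials_per_object=1, seed=0)
        assert course.angles_mean[:, 0].max() < 1.0

    def test_bounds_and_ordering(self, small_tensors):
        te, _ = small_tensors
        course = angle_course(te, "G", n_folds=3, trials_per_object=8, seed=1)
        a = course.angles_mean
        assert (a >= 0).all() and (a <= 90.0 + 1e-9).all()
        assert (a[:, 0] <= a[:, 1] + 1e-9).all() and (a[:, 1] <= a[:, 2] + 1e-9).all()
        assert (course.angles_sd >= 0).all()

    def test_unknown_reference_rejected(self, small_tensors):
        te, _ = small_tensors
        with pytest.raises(ValueError, match="reference"):
            angle_course(te, "X")

    def test_degenerate_cross_context_call_matches_within(self, small_tensors):
        te, _ = small_tensors
        cross = cross_context_angles(te, te, "M", n_folds=2, trials_per_object=8, seed=3)
        within = angle_course(te, "M", n_folds=2, trials_per_object=8, seed=3,
                              rng_label="xangles", moving_context="observation")
        assert np.allclose(cross.angles_mean, within.angles_mean)


class TestChanceAngles:
    def test_single_subspace_in_3d(self):
        mean, sd, m3 = chance_angles(3, n_draws=50, seed=0)
        assert mean == pytest.approx(0.0, abs=1e-9)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_monotone_in_ambient_dimension(self):
        means = [chance_angles(n, n_draws=300, seed=1)[0] for n in (5, 10, 50)]
        assert means[0] < means[1] < means[2]

    def test_small_dimension_rejected(self):
        with pytest.raises(ValueError):
            chance_angles(2)

    @pytest.mark.parametrize("n_dim", [4, 7])
    def test_matches_independent_sampler(self, n_dim):
        """Mean first angle agrees with an independently coded Monte-Carlo
        sampler (via scipy.linalg.subspace_angles).  In 4 dims the angle is
        structurally zero (3D subspaces always intersect); 7 dims is the
        generic positive-angle case."""
        mean, sd, _ = chance_angles(n_dim, n_draws=400, seed=2)
        rng = np.random.default_rng(99)
        vals = []
        for _ in range(400):
            A = np.linalg.qr(rng.standard_normal((n_dim, 3)))[0]
            B = np.linalg.qr(rng.standard_normal((n_dim, 3)))[0]
            vals.append(np.degrees(np.min(subspace_angles(A, B))))
        se = np.std(vals) / np.sqrt(len(vals)) + sd / np.sqrt(400)
        assert abs(mean - np.mean(vals)) < 3 * se + 1e-5
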