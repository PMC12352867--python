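import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from instasub import (
    clip_segments,
    cumulative_separation,
    instantaneous_subspaces,
    project_segment,
    separation_grid,
)
from instasub.core_io import OBJECTS
from instasub.segments import TrajectorySegment


def _latents_from(points):
    """Static configurations: each object's 'trajectory' repeats one point."""
    return {o: np.tile(np.asarray(p, float), (100, 1)) for o, p in zip(OBJECTS, points)}


class TestCumulativeSeparation:
    def test_identical_segments_give_zero(self):
        lat = _latents_from([[1, 2, 3]] * 4)
        assert cumulative_separation(lat).CS == 0.0

    def test_unit_square_hand_value(self):
        """Four static points on a unit square: the six pairwise distances
        are {1,1,1,1,sqrt2,sqrt2}, so CS = 4 + 2*sqrt(2)."""
        square = [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]]
        res = cumulative_separation(_latents_from(square))
        assert res.CS == pytest.approx(4 + 2 * np.sqrt(2), abs=1e-12)
        assert np.allclose(sorted(res.d_ij[0]), [1, 1, 1, 1, np.sqrt(2), np.sqrt(2)])

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.1, 10.0))
    def test_homogeneity_and_rotation_invariance(self, seed, c):
        rng = np.random.default_rng(seed)
        lat = {o: rng.standard_normal((100, 3)) for o in OBJECTS}
        base = cumulative_separation(lat).CS
        scaled = cumulative_separation({o: c * v for o, v in lat.items()}).CS
        assert scaled == pytest.approx(c * base, rel=1e-9)
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        rotated = cumulative_separation({o: v @ q for o, v in lat.items()}).CS
        assert rotated == pytest.approx(base, rel=1e-9)

    def test_unequal_lengths_rejected(self):
        lat = _latents_from([[0, 0, 0]] * 4)
        lat["perp"] = lat["perp"][:50]
        with pytest.raises(ValueError):
            cumulative_separation(lat)

    def test_cs_is_time_average_of_total_distance(self, rng):
        lat = {o: rng.standard_normal((100, 3)) for o in OBJECTS}
        res = cumulative_separation(lat)
        assert res.CS == pytest.approx(res.D.mean())
        assert np.allclose(res.D, res.d_ij.sum(axis=1))


class TestClipSegments:
    def test_row0_is_event_column(self, small_tensors):
        te, _ = small_tensors
        segs = clip_segments(te, "M")
        col = te.column_of("M", 0)
        for o in OBJECTS:
            expected = te.tensors[o][:, :, col].mean(axis=1)
            assert np.allclose(segs[o].data[0], expected)

    def test_averaged_equals_mean_of_single_trials(self, small_tensors):
        te, _ = small_tensors
        avg = clip_segments(te, "H", level="trial-averaged")
        single = clip_segments(te, "H", level="single-trial")
        for o in OBJECTS:
            assert np.allclose(avg[o].data, single[o].data.mean(axis=0))

    def test_zero_tensor_gives_zero_segments(self, small_tensors):
        te, _ = small_tensors
        clone = type(te)(
            tensors={o: np.zeros_like(te.tensors[o]) for o in OBJECTS},
            events=te.events, offsets=te.offsets, stats=te.stats,
            unit_ids=te.unit_ids, sigma_ms=te.sigma_ms, sqrt_applied=False,
        )
        segs = clip_segments(clone, "I")
        assert all(np.all(s.data == 0) for s in segs.values())

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="100"):
            TrajectorySegment("I", "sphere", "trial-averaged", np.zeros((50, 4)))


class TestProjectSegment:
    def test_center_maps_to_origin(self, rng):
        center = rng.standard_normal(8)
        seg = TrajectorySegment("I", "sphere", "trial-averaged",
                                np.tile(center, (100, 1)))
        basis = np.linalg.qr(rng.standard_normal((8, 3)))[0]
        lat = project_segment(seg, basis, center)
        assert np.allclose(lat, 0.0)

    def test_projection_is_non_expansive(self, rng):
        x = rng.standard_normal((100, 8))
        seg = TrajectorySegment("I", "sphere", "trial-averaged", x)
        basis = np.linalg.qr(rng.standard_normal((8, 3)))[0]
        lat = project_segment(seg, basis, np.zeros(8))
        assert (np.linalg.norm(lat, axis=1) <= np.linalg.norm(x, axis=1) + 1e-9).all()

    def test_own_pca_preserves_most_variance(self, rng):
        x = rng.standard_normal((100, 8))
        x -= x.mean(0)
        seg = TrajectorySegment("I", "sphere", "trial-averaged", x)
        _, _, vt = np.linalg.svd(x, full_matrices=False)
        best = (project_segment(seg, vt[:3].T, np.zeros(8)) ** 2).sum()
        other = np.linalg.qr(rng.standard_normal((8, 3)))[0]
        assert best >= (project_segment(seg, other, np.zeros(8)) ** 2).sum()

    def test_dimension_mismatch_rejected(self, rng):
        seg = TrajectorySegment("I", "sphere", "trial-averaged",
                                rng.standard_normal((100, 8)))
        with pytest.raises(ValueError):
            project_segment(seg, np.eye(5)[:, :3], np.zeros(5))


def test_separation_grid_diagonal_dominance(small_tensors):
    """Projecting each segment into its own-time subspace separates the four
    objects at least as well, on average, as projecting into the other
    events' subspaces (the matrix-diagonal structure of the planted data)."""
    te, _ = small_tensors
    grid = separation_grid(te)
    assert grid.shape == (4, 4)
    diag = np.diag(grid.values.astype(float))
    off = grid.values[~np.eye(4, dtype=bool)].astype(float)
    assert diag.mean() > off.mean()


def test_observation_separation_smaller_than_execution(small_tensors):
    te, to = small_tensors
    ge, go = separation_grid(te), separation_grid(to)
    assert np.diag(go.values.astype(float)).sum() < np.diag(ge.values.astype(float)).sum()
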