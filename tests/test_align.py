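import numpy as np
import pytest
from scipy import stats as sps

from instasub import (
    CCAOutcome,
    SegmentSource,
    bootstrap_cca,
    cca_align,
    compare_outcomes,
    permutation_null_cca,
    within_group_cca,
)
from instasub.align import check_cca_eligibility


def _cca_oracle(L_A, L_B):
    """Textbook CCA via eigen-decomposition of the covariance products,
    independent of the QR+SVD route."""
    X = L_A.T - L_A.T.mean(0)
    Y = L_B.T - L_B.T.mean(0)
    Sxx = X.T @ X
    Syy = Y.T @ Y
    Sxy = X.T @ Y
    M = np.linalg.solve(Sxx, Sxy) @ np.linalg.solve(Syy, Sxy.T)
    ev = np.linalg.eigvals(M)
    return np.sort(np.sqrt(np.clip(ev.real, 0, 1)))[::-1]


class TestCcaAlign:
    def test_self_alignment_is_perfect(self, rng):
        L = rng.standard_normal((3, 400))
        cc, *_ = cca_align(L, L)
        assert np.allclose(cc, 1.0, atol=1e-10)

    def test_invariance_to_invertible_transform(self, rng):
        L = rng.standard_normal((3, 400))
        G = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        cc, *_ = cca_align(L, G @ L)
        assert np.allclose(cc, 1.0, atol=1e-10)

    def test_matches_covariance_eigen_oracle(self, rng):
        for _ in range(10):
            base = rng.standard_normal((3, 400))
            L_A = base + 0.5 * rng.standard_normal((3, 400))
            L_B = rng.standard_normal((3, 3)) @ base + 0.5 * rng.standard_normal((3, 400))
            cc, *_ = cca_align(L_A, L_B)
            assert np.allclose(cc, _cca_oracle(L_A, L_B), atol=1e-10)

    def test_sorted_descending_and_bounded(self, rng):
        cc, *_ = cca_align(rng.standard_normal((3, 400)), rng.standard_normal((3, 400)))
        assert cc[0] >= cc[1] >= cc[2] >= -1.0
        assert cc[0] <= 1.0

    def test_aligned_latents_reproduce_coefficients(self, rng):
        L_A = rng.standard_normal((3, 400))
        L_B = rng.standard_normal((3, 400))
        cc, M_A, M_B, La, Lb = cca_align(L_A, L_B)
        S = La @ Lb.T
        assert np.allclose(np.diag(S), cc, atol=1e-8)
        off = S - np.diag(np.diag(S))
        assert np.max(np.abs(off)) < 1e-8

    def test_rank_deficient_input_rejected(self, rng):
        L = rng.standard_normal((3, 400))
        L[2] = L[0] + L[1]
        with pytest.raises(np.linalg.LinAlgError, match="rank"):
            cca_align(L, rng.standard_normal((3, 400)))

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            cca_align(rng.standard_normal((3, 400)), rng.standard_normal((3, 300)))


class TestBootstrap:
    def test_identical_dataset_same_resample_gives_unity(self, small_tensors):
        te, _ = small_tensors
        src = SegmentSource(te, "H", label="A")
        out = bootstrap_cca(src, src, label="self", trials_per_object=8,
                            n_iter=5, seed=0, shared_resample=True)
        assert np.allclose(out.coefficients, 1.0, atol=1e-8)

    def test_within_group_high_alignment(self, small_tensors):
        te, _ = small_tensors
        src = SegmentSource(te, "H")
        out = within_group_cca(src, trials_per_object=8, n_iter=10, seed=1)
        assert out.mean[0] > 0.9
        assert (np.diff(out.coefficients, axis=1) <= 1e-12).all()

    def test_permutation_null_below_genuine(self, small_tensors):
        te, to = small_tensors
        src_e, src_o = SegmentSource(te, "H"), SegmentSource(to, "H")
        genuine = bootstrap_cca(src_e, src_o, trials_per_object=8, n_iter=20, seed=2)
        null = permutation_null_cca(src_e, src_o, trials_per_object=8, n_iter=20, seed=3)
        assert null.coefficients[:, 0].mean() < genuine.mean[0]

    def test_eligibility_rule(self, small_tensors):
        te, _ = small_tensors
        src = SegmentSource(te, "H", label="tiny")
        with pytest.raises(ValueError, match="excluded"):
            check_cca_eligibility(src, trials_per_object=20)
        check_cca_eligibility(src, trials_per_object=8)  # exactly enough

    def test_mismatched_events_rejected(self, small_tensors):
        te, to = small_tensors
        with pytest.raises(ValueError, match="event"):
            bootstrap_cca(SegmentSource(te, "H"), SegmentSource(to, "M"))


class TestCompareOutcomes:
    @staticmethod
    def _outcome(label, loc, rng, n=60):
        cc = np.sort(np.clip(rng.normal(loc, 0.02, (n, 3)), 0, 1), axis=1)[:, ::-1]
        return CCAOutcome(label=label, segment_event="H", coefficients=cc)

    def test_identical_distributions_not_significant(self, rng):
        a = self._outcome("a", 0.7, np.random.default_rng(0))
        b = self._outcome("b", 0.7, np.random.default_rng(0))
        report = compare_outcomes([a, b])
        kw = report[report["test"] == "kruskal-wallis"]
        assert (kw["p_value"] > 0.05).all()

    def test_large_offset_is_significant(self, rng):
        a = self._outcome("a", 0.9, rng)
        b = self._outcome("b", 0.3, rng)
        report = compare_outcomes([a, b])
        assert (report["p_value"] < 0.001).all()

    def test_kw_statistic_matches_direct_computation(self):
        """Three tiny groups with hand-checkable ranks."""
        g = [np.array([1.0, 2, 3, 4, 5]), np.array([2.0, 3, 4, 5, 6]),
             np.array([10.0, 11, 12, 13, 14])]
        outcomes = [
            CCAOutcome(label=str(i), segment_event="H",
                       coefficients=np.tile(v[:, None], (1, 3)))
            for i, v in enumerate(g)
        ]
        report = compare_outcomes(outcomes)
        kw = report[(report["test"] == "kruskal-wallis")
                    & (report["coefficient"] == "CC1")]
        expect_stat, expect_p = sps.kruskal(*g)
        assert kw["statistic"].iloc[0] == pytest.approx(expect_stat)
        assert kw["p_value"].iloc[0] == pytest.approx(expect_p)

    def test_mismatched_events_rejected(self, rng):
        a = self._outcome("a", 0.5, rng)
        b = CCAOutcome(label="b", segment_event="M",
                       coefficients=a.coefficients.copy())
        with pytest.raises(ValueError):
            compare_outcomes([a, b])
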