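import numpy as np
import pytest

from msiflnp import (
    AssociationMatrix,
    MsifLnpParams,
    SimilarityMatrix,
    build_kernels,
    build_network,
    cross_iterate,
    fuse,
    neighbor_constraint_kernel,
    selective_column_normalize,
    svd_denoise,
)
from msiflnp.fusion import KernelSet

from oracles import eig_low_rank


def _sim(values, kind="fused"):
    values = np.asarray(values, dtype=float)
    return SimilarityMatrix(values, [f"e{i}" for i in range(len(values))], kind)


class TestSelectiveColumnNormalize:
    def test_columns_sum_to_one(self):
        out = selective_column_normalize(_sim([[1, 2], [1, 0]])).values
        np.testing.assert_allclose(out, [[0.5, 1.0], [0.5, 0.0]])

    def test_identity_unchanged(self):
        out = selective_column_normalize(_sim(np.eye(3))).values
        np.testing.assert_array_equal(out, np.eye(3))

    def test_zero_column_stays_zero_without_nan(self):
        out = selective_column_normalize(_sim([[1, 0], [1, 0]])).values
        np.testing.assert_allclose(out, [[0.5, 0.0], [0.5, 0.0]])
        assert np.isfinite(out).all()

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            selective_column_normalize(_sim([[1, -0.1], [0, 1]]))


class TestNeighborConstraintKernel:
    def test_full_neighborhood_is_row_normalization(self):
        S = _sim([[1, 0.5], [0.25, 1]])
        out = neighbor_constraint_kernel(S, 2).values
        np.testing.assert_allclose(out, [[2 / 3, 1 / 3], [0.2, 0.8]])

    def test_single_neighbor_with_unit_diagonal_gives_identity(self):
        rng = np.random.default_rng(0)
        V = rng.random((5, 5)) * 0.9
        np.fill_diagonal(V, 1.0)
        out = neighbor_constraint_kernel(_sim(V), 1).values
        np.testing.assert_array_equal(out, np.eye(5))

    def test_top_k_with_self_always_kept(self):
        S = _sim([[1, 0.2, 0.1], [0.2, 1, 0.6], [0.1, 0.6, 1]])
        out = neighbor_constraint_kernel(S, 2).values
        # row 1: self (1.0) plus its strongest other neighbor (0.6)
        np.testing.assert_allclose(out[1], [0.0, 0.625, 0.375])

    def test_all_zero_row_stays_zero(self):
        out = neighbor_constraint_kernel(_sim([[0, 0], [1, 1]]), 2).values
        assert not out[0].any()

    @pytest.mark.parametrize("k", [0, 4])
    def test_out_of_range_neighbors(self, k):
        with pytest.raises(ValueError, match="n_neighbors"):
            neighbor_constraint_kernel(_sim(np.eye(3)), k)


def _kernel_set(MS, LMS):
    ids = [f"e{i}" for i in range(len(MS[0]))]
    return KernelSet(
        [SimilarityMatrix(np.asarray(m, float), ids, "initial_kernel") for m in MS],
        [SimilarityMatrix(np.asarray(m, float), ids, "neighbor_kernel") for m in LMS],
        "microbe",
        1,
    )


class TestCrossIterate:
    def test_identity_is_a_fixed_point(self):
        I = np.eye(3)
        kernels = _kernel_set([I] * 3, [I] * 3)
        for out in cross_iterate(kernels, 4):
            np.testing.assert_allclose(out.values, I)
        np.testing.assert_allclose(fuse(kernels, 4).values, I)

    def test_zero_iterations_returns_neighbor_kernels(self):
        rng = np.random.default_rng(1)
        LMS = [rng.random((3, 3)) for _ in range(3)]
        kernels = _kernel_set([rng.random((3, 3)) for _ in range(3)], LMS)
        for out, original in zip(cross_iterate(kernels, 0), LMS):
            np.testing.assert_array_equal(out.values, original)

    def test_matches_straight_line_oracle_on_2x2(self):
        rng = np.random.default_rng(2)
        MS = [rng.random((2, 2)) for _ in range(3)]
        LMS = [rng.random((2, 2)) for _ in range(3)]
        # independent straight-line evaluation of two update rounds
        expected = list(LMS)
        for _ in range(2):
            expected = [
                MS[l] @ ((expected[(l + 1) % 3] + expected[(l + 2) % 3]) / 2) @ MS[l].T
                for l in range(3)
            ]
        kernels = _kernel_set(MS, LMS)
        got = cross_iterate(kernels, 2)
        for g, e in zip(got, expected):
            np.testing.assert_allclose(g.values, e, atol=1e-12)
        np.testing.assert_allclose(
            fuse(kernels, 2).values, sum(expected) / 3, atol=1e-12
        )

    def test_preserves_nonnegativity(self, small_assoc):
        kernels = build_kernels(small_assoc, "microbe", 2)
        for x in range(4):
            for out in cross_iterate(kernels, x):
                assert (out.values >= -1e-15).all()

    def test_mismatched_dimensions_rejected(self):
        two = SimilarityMatrix(np.eye(2), ["a", "b"], "neighbor_kernel")
        three = SimilarityMatrix(np.eye(3), ["a", "b", "c"], "neighbor_kernel")
        ms = SimilarityMatrix(np.eye(2), ["a", "b"], "initial_kernel")
        kernels = KernelSet([ms] * 3, [two, two, three], "microbe", 1)
        with pytest.raises(ValueError, match="dimension"):
            cross_iterate(kernels, 1)


class TestSvdDenoise:
    def test_full_rank_reconstruction_is_identity(self):
        rng = np.random.default_rng(3)
        K = _sim(rng.random((5, 5)))
        net = svd_denoise(K, 1.0)
        assert net.rank_kept == 5
        assert np.linalg.norm(net.reconstruction - K.values) <= 1e-8

    def test_rank_one_matrix_reconstructs_exactly(self):
        u = np.array([1.0, 2.0, 3.0])
        K = _sim(np.outer(u, u))
        net = svd_denoise(K, 0.34)  # ceil(0.34*3) = 2 >= true rank 1
        assert np.linalg.norm(net.reconstruction - K.values) <= 1e-8

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_eigendecomposition_oracle(self, seed):
        rng = np.random.default_rng(seed)
        K = _sim(rng.random((4, 4)))
        net = svd_denoise(K, 0.5)  # rank 2
        oracle = eig_low_rank(K.values, 2)
        np.testing.assert_allclose(net.reconstruction, oracle, atol=1e-6)

    def test_error_nonincreasing_in_rank(self):
        rng = np.random.default_rng(5)
        V = rng.random((6, 6))
        errors = [
            np.linalg.norm(svd_denoise(_sim(V), r / 6).reconstruction - V)
            for r in range(1, 7)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(errors, errors[1:]))
        assert errors[-1] <= 1e-8

    def test_negative_entries_clipped_and_reported(self):
        V = np.array([[1.0, 0.0, 0.2], [0.0, 1.0, 0.8], [0.3, 0.7, 0.1]])
        net = svd_denoise(_sim(V), 1 / 3)
        assert (net.denoised.values >= 0).all()
        if (net.reconstruction < 0).any():
            assert net.clipped_mass_fraction > 0

    def test_keep_fraction_bounds(self):
        with pytest.raises(ValueError, match="keep_fraction"):
            svd_denoise(_sim(np.eye(2)), 0.0)


class TestKernelInvariants:
    """The exact structural guarantees of the two kernel families."""

    @pytest.mark.parametrize("axis,k", [("microbe", 5), ("disease", 3)])
    def test_initial_and_neighbor_kernels(self, planted, axis, k):
        assoc, _ = planted
        kernels = build_kernels(assoc, axis, k)
        for ms, source_kind in zip(kernels.initial_kernels, ("cosine", "gip", "linear_neighborhood")):
            V = ms.values
            sums = V.sum(axis=0)
            nonzero = sums > 1e-12
            np.testing.assert_allclose(sums[nonzero], 1.0, atol=1e-8)
            assert (V >= 0).all()
        for lms in kernels.neighbor_kernels:
            V = lms.values
            sums = V.sum(axis=1)
            nonzero = sums > 1e-12
            np.testing.assert_allclose(sums[nonzero], 1.0, atol=1e-8)
            assert ((V > 0).sum(axis=1) <= k).all()
            assert (V >= 0).all()


class TestBuildNetwork:
    def test_output_dimension_per_axis(self, planted, synthetic_params):
        assoc, _ = planted
        km = build_network(assoc, "microbe", synthetic_params)
        kd = build_network(assoc, "disease", synthetic_params)
        assert km.denoised.values.shape == (assoc.n_microbes,) * 2
        assert kd.denoised.values.shape == (assoc.n_diseases,) * 2
        assert (km.denoised.values >= 0).all()
        assert (kd.denoised.values >= 0).all()
        assert km.rank_kept == int(np.ceil(0.5 * assoc.n_microbes))

    def test_deterministic_given_inputs(self, planted, synthetic_params):
        assoc, _ = planted
        a = build_network(assoc, "microbe", synthetic_params)
        b = build_network(assoc, "microbe", synthetic_params)
        assert (a.denoised.values == b.denoised.values).all()
        assert (a.singular_values == b.singular_values).all()

    def test_within_block_similarity_exceeds_between(self, planted, synthetic_params):
        assoc, truth = planted
        K = build_network(assoc, "microbe", synthetic_params).denoised.values
        bm = truth.block_of_microbe
        same = bm[:, None] == bm[None, :]
        off_diag = ~np.eye(len(bm), dtype=bool)
        assert K[same & off_diag].mean() > K[~same].mean()

    def test_singular_values_nonincreasing(self, planted, synthetic_params):
        assoc, _ = planted
        s = build_network(assoc, "disease", synthetic_params).singular_values
        assert (np.diff(s) <= 1e-12).all()
        assert (s >= 0).all()
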