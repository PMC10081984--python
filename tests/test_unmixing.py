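import numpy as np
import pytest

from stbss import (
    DEFAULT_MIXING,
    Ball,
    ExactLag,
    InvalidParameterError,
    KernelSpec,
    MultivariateField,
    RankDeficiencyError,
    Ring,
    f0_kernel,
    joint_diagonalize,
    lacf_batch,
    latent_scores,
    mdi,
    mix_field,
    model_preset,
    pca_baseline,
    preset_kernels,
    pseudo_eigenvalues,
    random_guess,
    simulate_domain,
    simulate_latent,
    stamuse,
    stsobi,
    whiten,
)
from tests.conftest import random_locations


def _sim(n_sp=5, model="model3", seed=3, A=None):
    locs = simulate_domain(n_sp, seed)
    latent = simulate_latent(locs, model_preset(model), seed + 1)
    field = mix_field(latent, np.eye(3) if A is None else A)
    return field, locs


class TestWhiten:
    def test_diagonal_covariance_gives_diagonal_whitener(self, rng):
        # orthogonal-design values with exact sample covariance diag(4, 9)
        z = np.array([[1.0, 1.0], [1.0, -1.0], [-1.0, 1.0], [-1.0, -1.0]])
        x = z * np.array([2.0, 3.0])
        locs = random_locations(rng, 4)
        _, whitener, mean, _ = whiten(MultivariateField(x), locs)
        assert np.allclose(whitener, np.diag([0.5, 1.0 / 3.0]), atol=1e-12)
        assert np.allclose(mean, 0.0, atol=1e-15)

    def test_whitened_f0_covariance_is_identity(self, rng):
        field, locs = _sim()
        xw, _, _, locs_cc = whiten(field, locs)
        cov = lacf_batch(xw, locs_cc, [f0_kernel()])[0].matrix
        assert np.abs(cov - np.eye(3)).max() < 1e-10
        assert np.abs(xw.values.mean(axis=0)).max() < 1e-10

    def test_constant_column_raises_rank_error(self, rng):
        locs = random_locations(rng, 20)
        x = rng.standard_normal((20, 3))
        x[:, 1] = 7.0
        with pytest.raises(RankDeficiencyError, match="eigenvalue"):
            whiten(MultivariateField(x), locs)


class TestJointDiagonalize:
    def test_diagonal_inputs_give_trivial_rotation(self):
        mats = [np.diag([3.0, 1.0, 2.0]), np.diag([0.5, -1.0, 4.0])]
        U = joint_diagonalize(mats)
        # U must be a signed permutation: one +-1 per row/column
        assert np.allclose(np.abs(U) @ np.abs(U.T), np.eye(3), atol=1e-12)
        assert np.allclose(np.sort(np.abs(U).ravel())[-3:], 1.0)

    def test_single_matrix_matches_eigendecomposition(self, rng):
        M = rng.standard_normal((4, 4))
        M = (M + M.T) / 2
        U = joint_diagonalize([M], tol=1e-14)
        D = U.T @ M @ U
        assert np.abs(D - np.diag(np.diag(D))).max() < 1e-10
        assert np.allclose(
            np.sort(np.diag(D)), np.sort(np.linalg.eigvalsh(M)), atol=1e-10
        )

    def test_commuting_pair_exactly_jointly_diagonalized(self, rng):
        Q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        M1 = Q @ np.diag([1.0, 2.0, 3.0, 4.0]) @ Q.T
        M2 = Q @ np.diag([-1.0, 0.5, 2.0, 0.1]) @ Q.T
        # independent oracle: shared eigenbasis of a random combination
        c = rng.uniform(0.5, 2.0)
        _, V = np.linalg.eigh(M1 + c * M2)
        for M in (M1, M2):
            D = V.T @ M @ V
            assert np.abs(D - np.diag(np.diag(D))).max() < 1e-8
        U = joint_diagonalize([M1, M2])
        for M in (M1, M2):
            D = U.T @ M @ U
            assert np.abs(D - np.diag(np.diag(D))).max() < 1e-8

    def test_orthogonality(self, rng):
        mats = [rng.standard_normal((5, 5)) for _ in range(4)]
        mats = [(M + M.T) / 2 for M in mats]
        U = joint_diagonalize(mats)
        assert np.abs(U.T @ U - np.eye(5)).max() < 1e-12

    def test_non_symmetric_input_rejected(self):
        M = np.array([[1.0, 2.0], [0.0, 1.0]])
        with pytest.raises(InvalidParameterError, match="symmetric"):
            joint_diagonalize([M])


class TestPseudoEigenvalues:
    def test_diagonal_matrices_with_identity_rotation(self):
        mats = [np.diag([1.0, 2.0]), np.diag([3.0, -4.0])]
        lam = pseudo_eigenvalues(np.eye(2), mats)
        assert np.allclose(lam, np.array([[1.0, 3.0], [2.0, -4.0]]))

    def test_column_sums_equal_traces(self, rng):
        mats = [rng.standard_normal((4, 4)) for _ in range(3)]
        mats = [(M + M.T) / 2 for M in mats]
        Q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        lam = pseudo_eigenvalues(Q, mats)
        for l, M in enumerate(mats):
            assert lam[:, l].sum() == pytest.approx(np.trace(M), rel=1e-10)

    def test_matches_direct_quadratic_forms(self, rng):
        M = rng.standard_normal((3, 3))
        M = (M + M.T) / 2
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        lam = pseudo_eigenvalues(Q, [M])
        for i in range(3):
            assert lam[i, 0] == pytest.approx(Q[:, i] @ M @ Q[:, i], rel=1e-12)


class TestStamuse:
    def test_exact_diagonalization_residuals(self):
        field, locs = _sim()
        spec = preset_kernels("stAMUSE.st")[0]
        res = stamuse(field, locs, spec)
        cov = lacf_batch(field, locs, [f0_kernel()])[0].matrix
        lac = lacf_batch(field, locs, [spec])[0].matrix
        left = res.W @ cov @ res.W.T
        right = res.W @ lac @ res.W.T
        assert np.abs(left - np.eye(3)).max() < 1e-8
        assert np.abs(right - np.diag(np.diag(right))).max() < 1e-8
        # diagonal entries ordered decreasingly
        assert (np.diff(res.diag_values) <= 1e-12).all()

    def test_recovers_identity_mixing(self):
        field, locs = _sim(n_sp=7, model="model3", seed=11)
        res = stamuse(field, locs, preset_kernels("stAMUSE.t")[0])
        assert mdi(res.W, np.eye(3)).value < 0.25

    def test_univariate_reduction(self, rng):
        locs = random_locations(rng, 200)
        x = 3.0 * rng.standard_normal((200, 1)) + 5.0
        res = stamuse(MultivariateField(x), locs, KernelSpec(Ball(2.0), Ball(2.0)))
        sd = x.std()  # divisor-n, matching the f0 LACF
        assert abs(abs(res.W[0, 0]) - 1.0 / sd) < 1e-10

    def test_result_invariants(self):
        field, locs = _sim(seed=21)
        res = stamuse(field, locs, preset_kernels("stAMUSE.s")[0])
        assert np.abs(res.U.T @ res.U - np.eye(3)).max() < 1e-8
        assert np.abs(res.W - res.U.T @ res.whitener).max() < 1e-10
        # sign convention: largest-absolute element of each row positive
        for row in res.W:
            assert row[np.argmax(np.abs(row))] > 0


class TestStsobi:
    def test_single_kernel_equals_stamuse_up_to_sign_and_order(self):
        field, locs = _sim(seed=5)
        spec = preset_kernels("stAMUSE.st")[0]
        r1 = stamuse(field, locs, spec)
        r2 = stsobi(field, locs, [spec])
        s1 = latent_scores(r1, field).values
        s2 = latent_scores(r2, field).values
        # match columns up to sign and order via correlation
        C = np.abs(np.corrcoef(s1.T, s2.T)[:3, 3:])
        assert np.allclose(np.sort(C.max(axis=1)), 1.0, atol=1e-6)
        assert np.allclose(np.sort(C.max(axis=0)), 1.0, atol=1e-6)

    def test_component_order_by_squared_pseudo_eigenvalues(self):
        field, locs = _sim(seed=9)
        res = stsobi(field, locs, preset_kernels("stSOBI.st"))
        scores = np.sum(res.pseudo_eigs**2, axis=1)
        assert (np.diff(scores) <= 1e-12).all()

    def test_affine_equivariance_of_mdi(self, rng):
        field, locs = _sim(n_sp=4, seed=13, A=DEFAULT_MIXING)
        specs = preset_kernels("stSOBI.st")
        base = mdi(stsobi(field, locs, specs).W @ DEFAULT_MIXING, np.eye(3)).value
        for _ in range(5):
            M = rng.standard_normal((3, 3)) + 2 * np.eye(3)
            a = rng.standard_normal(3)
            transformed = MultivariateField(field.values @ M.T + a)
            W_t = stsobi(transformed, locs, specs).W
            val = mdi(W_t @ M @ DEFAULT_MIXING, np.eye(3)).value
            assert val == pytest.approx(base, abs=1e-6)

    def test_scale_invariance_of_scores(self):
        field, locs = _sim(seed=17)
        res = stsobi(field, locs, preset_kernels("stSOBI.st"))
        scaled = MultivariateField(field.values * np.array([10.0, 0.2, 3.0]))
        res_s = stsobi(scaled, locs, preset_kernels("stSOBI.st"))
        s1 = latent_scores(res, field).values
        s2 = latent_scores(res_s, scaled).values
        C = np.abs(np.corrcoef(s1.T, s2.T)[:3, 3:])
        assert np.allclose(np.sort(C.max(axis=1)), 1.0, atol=1e-6)

    def test_empty_kernel_identifies_offending_spec(self):
        field, locs = _sim(n_sp=3)
        bad = KernelSpec(Ring(90.0, 99.0), ExactLag(0.0))
        from stbss import EmptyKernelError

        with pytest.raises(EmptyKernelError, match="ring"):
            stsobi(field, locs, [preset_kernels("stAMUSE.t")[0], bad])


class TestLatentScores:
    def test_training_scores_centered_and_white(self):
        field, locs = _sim(seed=19)
        res = stsobi(field, locs, preset_kernels("stSOBI.t"))
        scores = latent_scores(res, field)
        assert np.abs(scores.values.mean(axis=0)).max() < 1e-10
        cov = lacf_batch(scores, locs, [f0_kernel()])[0].matrix
        assert np.abs(cov - np.eye(3)).max() < 1e-8

    def test_identity_transform_is_passthrough(self, rng):
        x = rng.standard_normal((10, 2))
        from stbss import UnmixingResult

        res = UnmixingResult(
            W=np.eye(2), mean=np.zeros(2), whitener=np.eye(2), U=np.eye(2),
            pseudo_eigs=np.zeros((2, 1)), kernel_list=[f0_kernel()], method="stAMUSE",
        )
        out = latent_scores(res, MultivariateField(x))
        assert np.array_equal(out.values, x)

    def test_dimension_mismatch(self):
        field, locs = _sim()
        res = stsobi(field, locs, preset_kernels("stSOBI.t"))
        with pytest.raises(InvalidParameterError):
            latent_scores(res, MultivariateField(np.zeros((5, 2))))


class TestPcaBaseline:
    def test_diagonal_covariance_gives_identity_loadings(self, rng):
        z = np.array([[1.0] * 3, [1, -1, 1], [-1, 1, 1], [-1, -1, 1],
                      [1, 1, -1], [1, -1, -1], [-1, 1, -1], [-1, -1, -1]])
        x = z * np.sqrt(np.array([9.0, 4.0, 1.0]))
        locs = random_locations(rng, 8)
        res = pca_baseline(MultivariateField(x), locs)
        assert np.allclose(np.abs(res.W), np.eye(3), atol=1e-12)
        assert np.allclose(res.diag_values, [9.0, 4.0, 1.0], atol=1e-12)

    def test_orthogonal_loadings(self):
        field, locs = _sim(seed=23)
        res = pca_baseline(field, locs)
        assert np.abs(res.W @ res.W.T - np.eye(3)).max() < 1e-10

    def test_bss_unmixing_is_rotated_rescaled_pca(self):
        # W = U^T V D^{-1/2} V^T with (V, D) the covariance eigensystem
        field, locs = _sim(seed=29)
        res = stsobi(field, locs, preset_kernels("stSOBI.st"))
        cov = lacf_batch(field, locs, [f0_kernel()])[0].matrix
        d, V = np.linalg.eigh(cov)
        reconstructed = res.U.T @ (V / np.sqrt(d)) @ V.T
        assert np.abs(res.W - reconstructed).max() < 1e-8


class TestRandomGuess:
    def test_deterministic_given_seed(self):
        field, locs = _sim()
        W1 = random_guess(field, locs, 7).W
        W2 = random_guess(field, locs, 7).W
        assert np.array_equal(W1, W2)
        W3 = random_guess(field, locs, 8).W
        assert not np.allclose(W1, W3)

    def test_whitening_preserved(self):
        field, locs = _sim()
        res = random_guess(field, locs, 1)
        cov = lacf_batch(field, locs, [f0_kernel()])[0].matrix
        assert np.abs(res.W @ cov @ res.W.T - np.eye(3)).max() < 1e-8


class TestIdentifiability:
    def test_iid_components_are_not_separable(self):
        # spatio-temporally white latent fields have zero LACF at every
        # non-trivial kernel: no estimator can beat a random rotation
        from stbss import Product, WhiteNoise

        locs = simulate_domain(5, 101)
        models = [Product(WhiteNoise(1.0), WhiteNoise(1.0))] * 3
        latent = simulate_latent(locs, models, 102)
        field = mix_field(latent, DEFAULT_MIXING)
        res = stsobi(field, locs, preset_kernels("stSOBI.st"))
        assert mdi(res.W, DEFAULT_MIXING).value > 0.3
        assert np.abs(res.pseudo_eigs).max() < 0.1


class TestSerialization:
    def test_result_round_trip_and_table_layout(self):
        field, locs = _sim()
        res = stsobi(field, locs, preset_kernels("stSOBI.st2"))
        d = res.to_dict()
        assert np.allclose(np.array(d["W"]), res.W)
        table = res.pseudo_eig_table()
        assert list(table.columns) == ["Type", "Par", "Lag", "z1", "z2", "z3"]
        assert len(table) == 15
        assert set(table["Type"]) == {"Ball", "Ring"}
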