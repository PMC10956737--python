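"""Teacher: encoders, self-expression, DCCA algebra, training contracts."""

import numpy as np
import pytest
from scipy.linalg import eigh

from hifutherm.teacher import (
    EncoderParams,
    SelfExpressiveMatrix,
    TeacherConfig,
    aggregate_projections,
    apply_self_expression,
    common_space,
    dcca_loss,
    encode_modality,
    mtke_total_loss,
    projection_matrix,
    ridge_maps,
    self_expressive_loss,
    teacher_head,
    train_teacher,
    _dcca_output_grad,
    _full_dcca,
)

rng = np.random.default_rng(2024)


def _zero_encoder(hw=4, d=2):
    layers = [(np.zeros((hw, hw)), np.zeros(hw)),
              (np.zeros((hw, hw)), np.zeros(hw)),
              (np.zeros((hw, d)), np.zeros(d))]
    return EncoderParams(layers, modality="UBI")


class TestEncoder:
    def test_zero_parameters_give_zero_embedding(self):
        x = rng.standard_normal((5, 2, 2))
        f = encode_modality(x, _zero_encoder())
        assert f.shape == (5, 2)
        assert np.all(f == 0.0)

    def test_unit_network_passes_positive_scalar(self):
        # 1x1 patches, all weights 1, biases 0, ReLU: 2.0 -> 2.0 -> 2.0 -> 2.0
        layers = [(np.ones((1, 1)), np.zeros(1))] * 3
        f = encode_modality(np.array([[[2.0]]]), EncoderParams(layers))
        assert float(f[0, 0]) == pytest.approx(2.0)

    def test_output_shape_is_samples_by_dprime(self):
        params = EncoderParams([
            (rng.standard_normal((9, 6)), np.zeros(6)),
            (rng.standard_normal((6, 6)), np.zeros(6)),
            (rng.standard_normal((6, 4)), np.zeros(4)),
        ])
        assert encode_modality(rng.standard_normal((7, 3, 3)), params).shape == (7, 4)

    def test_shape_mismatch_names_modality(self):
        with pytest.raises(ValueError, match="UBI"):
            encode_modality(rng.standard_normal((3, 3, 3)), _zero_encoder(hw=4))


class TestSelfExpression:
    def test_zero_matrix_gives_zero_output(self):
        f = rng.standard_normal((4, 3))
        assert np.all(apply_self_expression(np.zeros((4, 4)), f) == 0.0)

    def test_swap_of_equal_rows_is_identity(self):
        f = np.tile(rng.standard_normal(3), (2, 1))
        Z = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert np.allclose(apply_self_expression(Z, f), f)

    def test_matches_triple_loop_oracle(self):
        Z = rng.standard_normal((3, 3))
        np.fill_diagonal(Z, 0.0)
        f = rng.standard_normal((3, 2))
        expected = np.zeros((3, 2))
        for i in range(3):
            for j in range(2):
                for k in range(3):
                    expected[i, j] += Z[i, k] * f[k, j]
        assert np.abs(apply_self_expression(Z, f) - expected).max() < 1e-12

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            apply_self_expression(np.eye(3), rng.standard_normal((3, 2)))

    def test_masked_parameterisation_is_exactly_zero_diagonal(self):
        Z = SelfExpressiveMatrix(rng.standard_normal((5, 5)))
        assert np.all(np.diagonal(Z.matrix) == 0.0)

    def test_loss_zero_Z_reduction(self):
        fs = [rng.standard_normal((4, 3)) for _ in range(2)]
        expected = sum(float(np.sum(f * f)) for f in fs)
        assert self_expressive_loss(np.zeros((4, 4)), fs) == pytest.approx(expected)

    def test_loss_perfect_self_expression_of_duplicates(self):
        f = np.tile(rng.standard_normal(3), (2, 1))
        Z = np.array([[0.0, 1.0], [1.0, 0.0]])
        # reconstruction term vanishes; ||Z||_F^2 = 2
        assert self_expressive_loss(Z, [f]) == pytest.approx(2.0)


class TestProjection:
    def test_orthonormal_columns_give_idempotent_projector(self):
        O = np.linalg.qr(rng.standard_normal((6, 3)))[0]
        P = projection_matrix(O, 0.0)
        assert np.allclose(P, O @ O.T, atol=1e-12)
        assert np.allclose(P @ P, P, atol=1e-12)

    def test_diagonal_example(self):
        P = projection_matrix(np.array([[1.0, 0.0], [0.0, 2.0]]), 1.0)
        assert np.allclose(P, np.diag([0.5, 0.8]), atol=1e-12)

    def test_svd_route_agrees_with_solve(self):
        O = rng.standard_normal((8, 3))
        a = projection_matrix(O, 1e-2, method="solve")
        b = projection_matrix(O, 1e-2, method="svd")
        assert np.abs(a - b).max() < 1e-10

    def test_singular_scatter_guidance(self):
        O = np.zeros((4, 2))
        with pytest.raises(np.linalg.LinAlgError, match="r_m > 0"):
            projection_matrix(O, 0.0)

    def test_aggregate_reductions_and_symmetry(self):
        P1 = projection_matrix(rng.standard_normal((5, 2)), 1e-3)
        assert np.array_equal(aggregate_projections([P1]), P1)
        assert np.allclose(aggregate_projections([np.eye(4) / 2] * 3), 1.5 * np.eye(4))
        Ps = [projection_matrix(rng.standard_normal((5, 2)), 1e-3) for _ in range(3)]
        P = aggregate_projections(Ps)
        assert np.abs(P - P.T).max() == 0.0


class TestCommonSpace:
    def test_identity_input(self):
        D, s = common_space(np.eye(4), 2)
        assert np.allclose(s, [1.0, 1.0])
        assert np.allclose(D.T @ D, np.eye(2), atol=1e-12)

    def test_diagonal_input_by_inspection(self):
        D, s = common_space(np.diag([3.0, 2.0, 1.0]), 2)
        assert np.allclose(s, [3.0, 2.0])
        assert np.allclose(np.abs(D), np.eye(3)[:, :2], atol=1e-12)

    def test_matches_full_svd_oracle_up_to_sign(self):
        A = rng.standard_normal((10, 4))
        P = A @ A.T  # symmetric PSD
        D, s = common_space(P, 3)
        w, V = eigh(P)
        w, V = w[::-1], V[:, ::-1]
        assert np.allclose(s, w[:3], atol=1e-8)
        for k in range(3):
            assert min(np.abs(D[:, k] - V[:, k]).max(),
                       np.abs(D[:, k] + V[:, k]).max()) < 1e-8

    def test_rank_bounds(self):
        with pytest.raises(ValueError):
            common_space(np.eye(3), 4)

    def test_dcca_loss_values(self):
        assert dcca_loss(np.ones(5)) == -5.0
        _, s = common_space(np.diag([3.0, 2.0, 1.0]), 2)
        assert dcca_loss(s) == pytest.approx(-5.0)

    def test_loss_gradient_wrt_P_matches_finite_differences(self):
        # with a simple spectrum, d(-sum s_i)/dP = -D D^T
        A = rng.standard_normal((6, 6))
        P = A @ A.T
        r = 3
        D, _ = common_space(P, r)
        g = -D @ D.T
        eps = 1e-5
        num = np.zeros_like(P)
        for i in range(6):
            for j in range(6):
                Pp, Pm = P.copy(), P.copy()
                Pp[i, j] += eps
                Pp[j, i] += eps
                Pm[i, j] -= eps
                Pm[j, i] -= eps
                fp = -common_space(Pp, r)[1].sum()
                fm = -common_space(Pm, r)[1].sum()
                num[i, j] = (fp - fm) / (2 * eps)
        # the symmetric +-eps perturbation doubles every sensitivity
        assert np.abs(num - 2.0 * g).max() < 1e-4

    def test_output_gradient_matches_finite_differences(self):
        O = rng.standard_normal((7, 3))
        r_m = 1e-3
        D = np.linalg.qr(rng.standard_normal((7, 3)))[0][:, :2]
        C = D @ D.T
        g = _dcca_output_grad(O, r_m, C)
        eps = 1e-6
        num = np.zeros_like(O)
        for i in range(7):
            for j in range(3):
                Op, Om = O.copy(), O.copy()
                Op[i, j] += eps
                Om[i, j] -= eps
                fp = np.trace(D.T @ projection_matrix(Op, r_m) @ D)
                fm = np.trace(D.T @ projection_matrix(Om, r_m) @ D)
                num[i, j] = (fp - fm) / (2 * eps)
        assert np.abs(g - num).max() < 1e-6


class TestHeadAndTotalLoss:
    def test_bias_only_head(self):
        D = rng.standard_normal((5, 3))
        assert np.allclose(teacher_head(D, np.zeros(3), 37.0), 37.0)

    def test_hand_computed_head(self):
        D = np.array([[0.5], [-0.5]])
        assert np.allclose(teacher_head(D, np.array([2.0]), 0.0), [1.0, -1.0])

    def test_head_shape_contract(self):
        with pytest.raises(ValueError):
            teacher_head(rng.standard_normal((4, 3)), np.zeros(2), 0.0)

    def test_total_loss_reduces_to_dcca_term(self):
        f = np.zeros((3, 2))
        y = np.array([1.0, 2.0, 3.0])
        s = np.array([2.0, 1.0])
        val = mtke_total_loss(np.zeros((3, 3)), [f, f], s, y, y)
        assert val == pytest.approx(-3.0)

    def test_total_loss_decomposition(self):
        S, d = 6, 3
        Z = rng.standard_normal((S, S))
        np.fill_diagonal(Z, 0.0)
        fs = [rng.standard_normal((S, d)) for _ in range(3)]
        s = np.abs(rng.standard_normal(4))
        y = rng.standard_normal(S)
        y_hat = rng.standard_normal(S)
        lams = (0.7, 1.3, 0.5, 2.0)
        fused = mtke_total_loss(Z, fs, s, y, y_hat, lams)
        parts = (self_expressive_loss(Z, fs, lams[0], lams[1])
                 + lams[2] * dcca_loss(s)
                 + lams[3] * float(np.mean((y - y_hat) ** 2)))
        assert fused == pytest.approx(parts, abs=1e-12)


class TestTraining:
    def test_same_seed_gives_identical_trajectory(self, tiny_split, tiny_teacher_config):
        train, val = tiny_split
        a = train_teacher(train, val, tiny_teacher_config, seed=21)
        b = train_teacher(train, val, tiny_teacher_config, seed=21)
        assert a.log.equals(b.log)
        assert np.array_equal(a.Z, b.Z)
        assert np.array_equal(a.D, b.D)

    def test_validation_mse_improves_on_noiseless_data(self, noiseless_patches):
        from hifutherm.synthdata import split_dataset

        keep = np.flatnonzero(noiseless_patches.frame_index % 3 == 0)
        train, val = split_dataset(noiseless_patches.take(keep), 0.7, seed=2)
        art = train_teacher(train, val, TeacherConfig(epochs=60, c=1, d_prime=16, r=8),
                            seed=3)
        assert art.log["val_mse"].iloc[-1] < art.log["val_mse"].iloc[0]

    def test_artifacts_are_frozen_and_structured(self, tiny_teacher, tiny_teacher_config):
        assert not tiny_teacher.Z.flags.writeable
        assert not tiny_teacher.D.flags.writeable
        assert np.all(np.diagonal(tiny_teacher.Z) == 0.0)
        r = tiny_teacher.D.shape[1]
        assert np.abs(tiny_teacher.D.T @ tiny_teacher.D - np.eye(r)).max() < 1e-8
        assert len(tiny_teacher.log) == tiny_teacher_config.epochs
        assert np.all(np.diff(tiny_teacher.singular_values) <= 1e-12)

    def test_chain_identity_residual_vs_trace(self):
        # residual form vs trace form of the common-space objective; the
        # ridge contribution scales with r_m, so a vanishing ridge makes
        # the two formulations agree to numerical precision
        outs = [rng.standard_normal((12, 4)) for _ in range(3)]
        st = _full_dcca(outs, 1e-9, r=3)
        lhs = sum(np.linalg.norm(st.common - O @ R) ** 2
                  for O, R in zip(outs, ridge_maps(st)))
        rhs = 3 * 3 - np.trace(st.common.T @ st.aggregate @ st.common)
        assert abs(lhs - rhs) <= 1e-8

    def test_svd_common_space_maximises_trace(self):
        outs = [rng.standard_normal((10, 3)) for _ in range(3)]
        st = _full_dcca(outs, 1e-3, r=2)
        best = np.trace(st.common.T @ st.aggregate @ st.common)
        for _ in range(20):
            Q = np.linalg.qr(rng.standard_normal((10, 2)))[0]
            assert np.trace(Q.T @ st.aggregate @ Q) <= best + 1e-10

    def test_nonfinite_loss_is_named(self, tiny_split, tiny_teacher_config):
        from hifutherm.synthdata import MultimodalPatchSet

        train, val = tiny_split
        bad = MultimodalPatchSet(patches=train.patches.copy(),
                                 labels=train.labels.copy(),
                                 frame_index=train.frame_index,
                                 probe_index=train.probe_index)
        bad.patches[0, 0, 0, 0] = np.inf
        with np.errstate(invalid="ignore"):
            with pytest.raises(FloatingPointError, match="non-finite"):
                train_teacher(bad, val, tiny_teacher_config, seed=0)
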