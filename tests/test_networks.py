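"""SAE/GCN branches: forward contracts, losses, joint-representation blending."""

import numpy as np
import pytest

from smmsn.autodiff import Tensor
from smmsn.networks import (GcnState, gcn_forward, init_gcn, init_sae,
                            joint_representation, reconstruction_loss,
                            sae_forward)
from smmsn.preprocess import PreprocessConfig, SimilarityGraph, normalize_adjacency
from smmsn.selfsup import TrainConfig, _pretrain_saes

from conftest import make_view


def leaky(x, slope):
    return np.where(x > 0, x, slope * x)


class TestSae:
    def test_shapes_and_latent_stack(self, rng):
        v = make_view(rng.standard_normal((10, 7)))
        state = init_sae(7, (5, 3), rng)
        latents, xhat = sae_forward(v, state)
        assert [z.shape for z in latents] == [(10, 5), (10, 3)]
        assert xhat.shape == (10, 7)

    def test_zero_weights_give_zero_reconstruction(self, rng):
        v = make_view(rng.standard_normal((4, 6)))
        state = init_sae(6, (3,), rng)
        for W, b in state.encoder + state.decoder:
            W.data[:] = 0.0
            b.data[:] = 0.0
        _, xhat = sae_forward(v, state)
        np.testing.assert_array_equal(xhat.data, 0.0)
        # Frobenius loss collapses to ||X||^2 / (2N)
        loss = reconstruction_loss([v], [xhat])
        assert float(loss.data) == pytest.approx((v.X**2).sum() / (2 * 4))

    def test_forward_matches_manual_stack(self, rng):
        X = rng.standard_normal((5, 4))
        state = init_sae(4, (3, 2), rng, slope=0.2)
        latents, xhat = sae_forward(X, state)
        z = X
        for W, b in state.encoder:
            z = leaky(z @ W.data + b.data, 0.2)
        np.testing.assert_allclose(latents[-1].data, z, rtol=1e-12)
        for i, (W, b) in enumerate(state.decoder):
            z = z @ W.data + b.data
            if i < len(state.decoder) - 1:
                z = leaky(z, 0.2)
        np.testing.assert_allclose(xhat.data, z, rtol=1e-12)

    def test_feature_mismatch_is_error(self, rng):
        state = init_sae(4, (3,), rng)
        with pytest.raises(ValueError, match="features"):
            sae_forward(rng.standard_normal((5, 6)), state)


class TestReconstructionLoss:
    def test_perfect_reconstruction_is_zero(self, rng):
        X = rng.standard_normal((6, 3))
        assert float(reconstruction_loss([X], [Tensor(X)]).data) == 0.0

    def test_hand_arithmetic(self):
        X = np.array([[1.0], [1.0]])
        loss = reconstruction_loss([X], [Tensor(np.zeros((2, 1)))])
        assert float(loss.data) == pytest.approx(0.5)  # (1/4) * 2

    def test_view_permutation_invariance(self, rng):
        Xs = [rng.standard_normal((4, d)) for d in (3, 5)]
        Rs = [Tensor(rng.standard_normal((4, d))) for d in (3, 5)]
        a = float(reconstruction_loss(Xs, Rs).data)
        b = float(reconstruction_loss(Xs[::-1], Rs[::-1]).data)
        assert a == pytest.approx(b)

    def test_shape_mismatch_is_error(self, rng):
        with pytest.raises(ValueError):
            reconstruction_loss([rng.standard_normal((3, 2))],
                                [Tensor(np.zeros((3, 3)))])


class TestJointRepresentation:
    def test_boundaries_and_midpoint(self):
        G, Z = np.array([[2.0]]), np.array([[4.0]])
        np.testing.assert_array_equal(joint_representation(G, Z, 0.0), G)
        np.testing.assert_array_equal(joint_representation(G, Z, 1.0), Z)
        np.testing.assert_array_equal(joint_representation(G, Z, 0.5), [[3.0]])

    def test_linear_in_both_arguments(self, rng):
        G, Z = rng.standard_normal((4, 3)), rng.standard_normal((4, 3))
        eps = 0.3
        # doubling G adds exactly one more (1-eps)*G contribution
        np.testing.assert_allclose(
            joint_representation(2 * G, Z, eps),
            joint_representation(G, Z, eps) + (1 - eps) * G, atol=1e-12)
        # doubling Z adds exactly one more eps*Z contribution
        np.testing.assert_allclose(
            joint_representation(G, 2 * Z, eps),
            joint_representation(G, Z, eps) + eps * Z, atol=1e-12)
        # eps = 0.5 is the elementwise mean
        np.testing.assert_allclose(
            joint_representation(G, Z, 0.5), (G + Z) / 2, atol=1e-12)

    def test_shape_mismatch_is_error(self):
        with pytest.raises(ValueError):
            joint_representation(np.zeros((2, 2)), np.zeros((3, 2)), 0.5)


class TestGcn:
    def make_graph(self, n, rng, k=2):
        from smmsn.preprocess import build_knn_graph, heat_kernel_similarity
        v = make_view(rng.standard_normal((n, 3)))
        S = heat_kernel_similarity(v, PreprocessConfig())
        return build_knn_graph(S, PreprocessConfig(k_neighbors=k))

    def test_identity_adjacency_epsilon0_equals_mlp(self, rng):
        """With A_norm = I and eps = 0 the GCN is a plain weight-shared MLP."""
        X = rng.standard_normal((5, 4))
        state = init_gcn(4, 2, (6, 3), rng, epsilon=0.0, slope=0.1)
        out = gcn_forward(np.eye(5), X, None, state)
        # independent MLP oracle
        h = X
        for i, W in enumerate(state.weights):
            h = h @ W.data
            if i < len(state.weights) - 1:
                h = leaky(h, 0.1)
        np.testing.assert_allclose(out.data, h, atol=1e-6)

    def test_epsilon0_equals_plain_gcn_oracle(self, rng):
        g = self.make_graph(8, rng)
        X = rng.standard_normal((8, 3))
        state = init_gcn(3, 2, (4,), rng, epsilon=0.0)
        latents = [Tensor(rng.standard_normal((8, 4)))]  # must be ignored
        out = gcn_forward(g, X, latents, state)
        A = g.A_norm
        h = leaky(A @ X @ state.weights[0].data, state.slope)
        h = A @ h @ state.weights[1].data
        np.testing.assert_allclose(out.data, h, atol=1e-10)

    def test_injection_blends_encoder_activations(self, rng):
        g = self.make_graph(6, rng)
        X = rng.standard_normal((6, 3))
        state = init_gcn(3, 2, (4,), rng, epsilon=0.5)
        Z = Tensor(rng.standard_normal((6, 4)))
        out = gcn_forward(g, X, [Z], state)
        A = g.A_norm
        G1 = leaky(A @ X @ state.weights[0].data, state.slope)
        H = 0.5 * G1 + 0.5 * Z.data
        expected = A @ H @ state.weights[1].data
        np.testing.assert_allclose(out.data, expected, atol=1e-10)

    def test_output_shape_is_n_by_c(self, rng):
        g = self.make_graph(7, rng)
        X = rng.standard_normal((7, 5))
        state = init_gcn(5, 3, (4, 2), rng)
        out = gcn_forward(g, X, None, state)
        assert out.shape == (7, 3)

    def test_latent_count_mismatch_is_error(self, rng):
        g = self.make_graph(5, rng)
        state = init_gcn(3, 2, (4, 2), rng)
        with pytest.raises(ValueError, match="activations"):
            gcn_forward(g, rng.standard_normal((5, 3)),
                        [Tensor(np.zeros((5, 4)))], state)


def test_pretraining_loss_trend_non_increasing(rng):
    """Reconstruction-only pretraining should steadily reduce L_res: means over
    consecutive 10-epoch windows must not increase."""
    X = rng.standard_normal((20, 8)).astype(np.float32)
    cfg = TrainConfig(n_clusters=2, pretrain_epochs=60, pretrain_lr=1e-3,
                      encoder_dims=(6, 3))
    states = [init_sae(8, cfg.encoder_dims, rng)]
    losses = _pretrain_saes([X], states, cfg)
    windows = [np.mean(losses[i:i + 10]) for i in range(0, 60, 10)]
    assert all(b <= a + 1e-9 for a, b in zip(windows, windows[1:]))
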