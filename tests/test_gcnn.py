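"""Graph attention, Laplacian/spectral operators and the training loop."""

import numpy as np
import pytest

from neuromode.gcnn import (
    GraphModel,
    attention_coefficients,
    init_model,
    laplacian,
    rank_edges,
    spectral_conv,
    spectral_decomposition,
    train,
    update_adjacency,
    update_features,
)
from neuromode.simulate import make_planted_graph_batch


def sym_uniform(rng, n, unit_diag=True):
    a = rng.uniform(0, 1, (n, n))
    a = 0.5 * (a + a.T)
    if unit_diag:
        np.fill_diagonal(a, 1.0)
    return a


class TestAttention:
    def test_rows_sum_to_one(self, rng):
        a = sym_uniform(rng, 5)
        h = rng.standard_normal((5, 3))
        w = rng.standard_normal(6)
        alpha = attention_coefficients(h, w, a)
        np.testing.assert_allclose(alpha.sum(axis=1), 1.0, atol=1e-9)

    def test_identical_features_uniform_attention(self, rng):
        # projection input: identical node features give identical scores
        a = sym_uniform(rng, 4)
        h = np.tile([1.0, -2.0], (4, 1))
        w = rng.standard_normal(6)
        proj = rng.standard_normal((3, 2))
        alpha = attention_coefficients(h, w, a, mode="projection", projection=proj)
        np.testing.assert_allclose(alpha, 0.25, atol=1e-9)
        # adjacency input: symmetry additionally needs equal adjacency row
        # sums (z = A h scales with the row sum)
        a_const = np.ones((4, 4))
        alpha2 = attention_coefficients(h, rng.standard_normal(4), a_const)
        np.testing.assert_allclose(alpha2, 0.25, atol=1e-9)

    def test_three_node_hand_instance(self):
        # oracle: direct evaluation of the printed scoring rule
        a = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.7], [0.2, 0.7, 1.0]])
        h = np.array([[1.0], [2.0], [-1.0]])
        w = np.array([0.3, -0.4])
        z = a @ h
        slope = 0.2
        raw = 0.3 * z[:, 0][:, None] + (-0.4) * z[:, 0][None, :]
        scores = np.where(raw >= 0, raw, slope * raw)
        expo = np.exp(scores)
        oracle = expo / expo.sum(axis=1, keepdims=True)
        alpha = attention_coefficients(h, w, a, leaky_slope=slope)
        np.testing.assert_allclose(alpha, oracle, atol=1e-12)

    def test_empty_neighborhood_falls_back_to_self_edge(self, rng):
        a = sym_uniform(rng, 3, unit_diag=False)
        a[0, :] = 0.0
        a[:, 0] = 0.0
        h = rng.standard_normal((3, 2))
        w = rng.standard_normal(4)
        alpha = attention_coefficients(h, w, a)
        assert alpha[0, 0] == pytest.approx(1.0)

    def test_permutation_equivariance(self, rng):
        a = sym_uniform(rng, 6)
        h = rng.standard_normal((6, 2))
        w = rng.standard_normal(4)
        perm = rng.permutation(6)
        p = np.eye(6)[perm]
        alpha = attention_coefficients(h, w, a)
        alpha_p = attention_coefficients(p @ h, w, p @ a @ p.T)
        np.testing.assert_allclose(alpha_p, p @ alpha @ p.T, atol=1e-9)
        a_upd = update_adjacency(alpha, a)
        a_upd_p = update_adjacency(alpha_p, p @ a @ p.T)
        np.testing.assert_allclose(a_upd_p, p @ a_upd @ p.T, atol=1e-9)


class TestAdjacencyUpdate:
    def test_identity_coefficients_preserve_symmetric_adjacency(self, rng):
        a = sym_uniform(rng, 4)
        np.testing.assert_allclose(update_adjacency(np.eye(4), a), a, atol=1e-12)

    def test_identity_adjacency_gives_symmetrised_alpha(self, rng):
        alpha = rng.uniform(0, 1, (4, 4))
        alpha /= alpha.sum(axis=1, keepdims=True)
        out = update_adjacency(alpha, np.eye(4))
        np.testing.assert_allclose(out, 0.5 * (alpha + alpha.T), atol=1e-12)

    def test_matches_brute_force_product(self, rng):
        alpha = rng.uniform(0, 1, (4, 4))
        a = sym_uniform(rng, 4)
        prod = np.array(
            [[sum(alpha[i, k] * a[k, j] for k in range(4)) for j in range(4)] for i in range(4)]
        )
        np.testing.assert_allclose(
            update_adjacency(alpha, a), 0.5 * (prod + prod.T), atol=1e-12
        )


class TestFeatureUpdate:
    def test_zero_features_map_to_sigma_zero(self, rng):
        a = sym_uniform(rng, 3)
        alpha = np.full((3, 3), 1 / 3)
        out = update_features(np.zeros((3, 2)), alpha, a)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_single_node_graph(self):
        out = update_features(np.array([[2.0]]), np.array([[1.0]]), np.array([[1.0]]))
        np.testing.assert_allclose(out, 2.0)  # elu(2) = 2

    def test_three_node_hand_instance(self):
        a = np.array([[1.0, 0.2, 0.0], [0.2, 1.0, 0.5], [0.0, 0.5, 1.0]])
        alpha = np.array([[0.5, 0.3, 0.2], [0.1, 0.6, 0.3], [0.2, 0.2, 0.6]])
        h = np.array([[1.0, -1.0], [0.5, 2.0], [-2.0, 0.0]])
        z = a @ h
        pre = alpha.sum(axis=1)[:, None] * z
        oracle = np.where(pre >= 0, pre, np.expm1(pre))
        np.testing.assert_allclose(update_features(h, alpha, a), oracle, atol=1e-12)


class TestLaplacian:
    def test_row_sums_zero_and_psd(self, rng):
        a = sym_uniform(rng, 6)
        lap = laplacian(a)
        np.testing.assert_allclose(lap.sum(axis=1), 0.0, atol=1e-9)
        u, lam = spectral_decomposition(lap)
        assert lam.min() > -1e-9
        # smallest eigenvalue 0 with constant eigenvector
        np.testing.assert_allclose(lam[0], 0.0, atol=1e-9)
        v = u[:, 0]
        np.testing.assert_allclose(np.abs(v), np.abs(v[0]), atol=1e-9)

    def test_path_graph_eigenvalues(self):
        a = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
        _, lam = spectral_decomposition(laplacian(a))
        np.testing.assert_allclose(np.sort(lam), [0.0, 1.0, 3.0], atol=1e-9)

    def test_complete_graph_eigenvalues(self):
        n = 5
        a = np.ones((n, n)) - np.eye(n)
        _, lam = spectral_decomposition(laplacian(a))
        np.testing.assert_allclose(np.sort(lam), [0.0] + [float(n)] * (n - 1), atol=1e-9)

    def test_asymmetric_adjacency_rejected(self, rng):
        a = rng.uniform(0, 1, (3, 3))
        with pytest.raises(ValueError):
            laplacian(a)

    def test_orthonormal_reconstruction(self, rng):
        lap = laplacian(sym_uniform(rng, 8))
        u, lam = spectral_decomposition(lap)
        assert np.abs(u.T @ u - np.eye(8)).max() < 1e-8
        assert np.abs(u @ np.diag(lam) @ u.T - lap).max() < 1e-8


class TestSpectralConv:
    def test_unit_filter_is_identity(self, rng):
        lap = laplacian(sym_uniform(rng, 6))
        u, lam = spectral_decomposition(lap)
        x = rng.standard_normal((6, 3))
        np.testing.assert_allclose(spectral_conv(x, u, np.ones(6)), x, atol=1e-9)

    def test_eigenvalue_filter_applies_laplacian(self, rng):
        lap = laplacian(sym_uniform(rng, 5))
        u, lam = spectral_decomposition(lap)
        x = rng.standard_normal((5, 2))
        np.testing.assert_allclose(spectral_conv(x, u, lam), lap @ x, atol=1e-9)

    def test_matches_triple_product_oracle(self, rng):
        lap = laplacian(sym_uniform(rng, 4))
        u, lam = spectral_decomposition(lap)
        g = rng.standard_normal(4)
        x = rng.standard_normal((4, 2))
        oracle = u @ np.diag(g) @ u.T @ x
        np.testing.assert_allclose(spectral_conv(x, u, g), oracle, atol=1e-10)

    def test_dimension_mismatch_rejected(self, rng):
        u = np.eye(4)
        with pytest.raises(ValueError):
            spectral_conv(rng.standard_normal((3, 2)), u, np.ones(4))


class TestModel:
    def test_same_seed_identical_model(self):
        a = init_model(6, seed=42)
        b = init_model(6, seed=42)
        np.testing.assert_array_equal(a.adjacency, b.adjacency)
        np.testing.assert_array_equal(a.params["w"], b.params["w"])

    def test_adjacency_contract(self):
        m = init_model(10, seed=0)
        assert np.all((m.adjacency >= 0) & (m.adjacency <= 1))
        np.testing.assert_allclose(m.adjacency, m.adjacency.T)

    def test_default_two_gcn_layers(self):
        assert init_model(4).n_gcn_layers == 2
        assert len(init_model(4).params["g"]) == 2

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(3)
        for mode in ("projection", "adjacency"):
            m = GraphModel(
                n_nodes=4, n_features=2, n_hidden=3, attention_mode=mode, seed=1
            )
            h = rng.standard_normal((6, 4, 2))
            y = np.array([0, 1, 0, 1, 0, 1])
            _, grads = m.loss_and_grads(h, y)
            eps = 1e-5
            arrays = [("w", m.params["w"], grads["w"]),
                      ("dense_w", m.params["dense_w"], grads["dense_w"])]
            arrays += [(f"g{i}", g, dg) for i, (g, dg) in enumerate(zip(m.params["g"], grads["g"]))]
            if mode == "projection":
                arrays.append(("proj", m.params["proj"], grads["proj"]))
            for name, arr, ana in arrays:
                flat = arr.ravel()
                num = np.zeros_like(flat)
                for i in range(flat.size):
                    orig = flat[i]
                    flat[i] = orig + eps
                    lp = m.loss(h, y)
                    flat[i] = orig - eps
                    lm = m.loss(h, y)
                    flat[i] = orig
                    num[i] = (lp - lm) / (2 * eps)
                scale = max(np.abs(num).max(), np.abs(ana).max(), 1e-10)
                rel = np.abs(num - ana.ravel()).max() / scale
                assert rel < 1e-4, f"{mode}/{name}: rel err {rel}"

    def test_loss_non_increasing_on_separable_batch(self):
        x, y = make_planted_graph_batch(n_samples=60, n_nodes=16,
                                        informative_nodes=(0, 1), seed=0)
        m = GraphModel(n_nodes=16, n_features=1, seed=0)
        r = train(m, x, y, epochs=12, seed=1)
        first10 = r.losses[:10]
        assert np.all(np.diff(first10) <= 1e-6)

    def test_label_shuffle_gives_chance_accuracy(self):
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x, y = make_planted_graph_batch(n_samples=80, n_nodes=16, seed=seed)
            y = rng.permutation(y)
            m = GraphModel(n_nodes=16, n_features=1, seed=seed)
            r = train(m, x, y, epochs=60, seed=seed + 1)
            accs.append(r.val_accuracy)
        # 3 binomial SEs of the mean around 0.5 at 10 runs x 20 val samples
        se = np.sqrt(0.25 / (10 * 20))
        assert abs(np.mean(accs) - 0.5) < 3 * se + 0.05

    def test_non_finite_loss_raises_with_diagnostics(self):
        x, y = make_planted_graph_batch(n_samples=20, n_nodes=8, seed=0)
        m = GraphModel(n_nodes=8, n_features=1, seed=0)
        m.params["dense_w"][:] = np.nan
        with pytest.raises(FloatingPointError):
            train(m, x, y, epochs=2, seed=1)


class TestRankEdges:
    def test_all_edges_of_triangle(self, rng):
        a = sym_uniform(rng, 3)
        edges = rank_edges(a, k=10)
        assert len(edges) == 3

    def test_top_weight_normalised_to_one(self, rng):
        a = sym_uniform(rng, 6)
        edges = rank_edges(a, k=4)
        assert edges["weight_normalized"].iloc[0] == pytest.approx(1.0)
        assert np.all(np.diff(edges["weight_normalized"]) <= 1e-12)

    def test_channel_names_used(self, rng):
        a = sym_uniform(rng, 3)
        edges = rank_edges(a, k=1, channel_names=["Fp1", "Fp2", "F3"])
        assert set(edges[["node_i", "node_j"]].iloc[0]) <= {"Fp1", "Fp2", "F3"}

    def test_norm_rules(self, rng):
        a = sym_uniform(rng, 5)
        s = rank_edges(a, k=3, norm_rule="sum")
        assert s["weight_normalized"].sum() == pytest.approx(1.0)
        mm = rank_edges(a, k=3, norm_rule="minmax")
        assert mm["weight_normalized"].iloc[0] == pytest.approx(1.0)
        assert mm["weight_normalized"].iloc[-1] == pytest.approx(0.0)


class TestGraphBatchIO:
    def test_round_trip(self, tmp_path):
        from neuromode.gcnn import load_graph_batch, save_graph_batch

        x, y = make_planted_graph_batch(n_samples=12, n_nodes=6, seed=0)
        save_graph_batch(tmp_path / "x.npz", tmp_path / "y.tsv", x, y)
        x2, y2 = load_graph_batch(tmp_path / "x.npz", tmp_path / "y.tsv")
        np.testing.assert_array_equal(x2, x)
        np.testing.assert_array_equal(y2, y)
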