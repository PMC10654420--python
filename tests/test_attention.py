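"""Attention layers: row stochasticity, oracle equivalence, variants."""

import numpy as np
import pytest

import seqrefine.autodiff as ad
from conftest import random_rotation
from seqrefine.model import (
    ModelConfig,
    ModelParams,
    attention_bias,
    attention_layer,
    attention_layer_dense,
    attention_layer_local,
    attention_layer_streaming,
    featurize,
    forward,
    predict_profile,
)
from seqrefine.types import PartialSequence, ResidueGraph


def random_instance(n, k, d, seed, mode="global_pseudo"):
    """Random graph features + params of width d (k neighbors per node)."""
    rng = np.random.default_rng(seed)
    k_eff = min(k, n - 1)
    nbr = np.stack([
        rng.permutation(np.delete(np.arange(n), i))[:k_eff] for i in range(n)
    ]) if n > 1 else np.zeros((1, 0), dtype=np.int64)
    H = rng.normal(size=(n, d))
    E = rng.normal(size=(n, k_eff, d))
    params = ModelParams(ModelConfig(d=d, n_layers=1, k=k, attention_mode=mode,
                                     seed=seed))
    return H, E, nbr.astype(np.int64), params


class TestAttentionBias:
    def test_constant_beta_equals_edges_gives_constant_bias(self):
        """If every edge feature equals beta the bias matrix is constant."""
        H, E, nbr, params = random_instance(7, 3, 8, 0)
        p = params.arrays()
        E_const = np.broadcast_to(p["L0_beta"], E.shape).copy()
        B = attention_bias(E_const, nbr, p["L0_wb"], p["L0_beta"])
        assert np.abs(B - B[0, 0]).max() < 1e-12

    def test_zero_weight_gives_zero_bias(self):
        H, E, nbr, params = random_instance(7, 3, 8, 1)
        p = params.arrays()
        B = attention_bias(E, nbr, np.zeros(8), p["L0_beta"])
        assert np.abs(B).max() == 0.0

    def test_streaming_matches_materialized_bias(self):
        """Implicit streaming softmax equals the dense-bias computation."""
        H, E, nbr, params = random_instance(7, 3, 8, 2)
        p = params.arrays()
        H1, E1 = attention_layer(H, E, nbr, p, "L0")
        H1s, E1s = attention_layer_streaming(H, E, nbr, p, "L0", chunk=2)
        np.testing.assert_allclose(H1s, H1, atol=1e-12)
        np.testing.assert_allclose(E1s, E1, atol=1e-12)


class TestAttentionLayer:
    def test_rows_sum_to_one(self):
        for seed in range(5):
            H, E, nbr, params = random_instance(9, 4, 8, seed)
            _, _, A = attention_layer(H, E, nbr, params.arrays(), "L0",
                                      return_attention=True)
            np.testing.assert_allclose(A.sum(axis=1), 1.0, atol=1e-6)

    def test_single_node_graph(self):
        """N=1: attention collapses to self, edge aggregation term is zero."""
        H, E, nbr, params = random_instance(1, 0, 8, 3)
        H1, E1, A = attention_layer(H, E, nbr, params.arrays(), "L0",
                                    return_attention=True)
        np.testing.assert_allclose(A, [[1.0]])
        assert np.isfinite(H1).all()
        assert E1.shape == (1, 0, 8)

    def test_complete_graph_matches_dense_oracle(self):
        """Pseudo-edge layer equals the conventional dense layer when the
        sparse graph is complete (self-pairs carrying beta)."""
        for seed in range(10):
            n = int(np.random.default_rng(seed).integers(2, 12))
            H, E, nbr, params = random_instance(n, n - 1, 8, seed)
            p = params.arrays()
            H1, E1 = attention_layer(H, E, nbr, p, "L0")
            E_full = np.zeros((n, n, 8))
            rows = np.arange(n)[:, None]
            E_full[rows, nbr] = E
            E_full[np.arange(n), np.arange(n)] = p["L0_beta"]
            H1d, E1d = attention_layer_dense(H, E_full, p, "L0")
            np.testing.assert_allclose(H1, H1d, atol=1e-6)
            np.testing.assert_allclose(E1, E1d[rows, nbr], atol=1e-6)

    def test_permutation_equivariance(self):
        H, E, nbr, params = random_instance(8, 3, 8, 4)
        p = params.arrays()
        H1, E1 = attention_layer(H, E, nbr, p, "L0")
        rng = np.random.default_rng(5)
        perm = rng.permutation(8)
        inv = np.argsort(perm)
        H1p, E1p = attention_layer(H[perm], E[perm], inv[nbr][perm], p, "L0")
        np.testing.assert_allclose(H1p, H1[perm], atol=1e-9)
        np.testing.assert_allclose(E1p, E1[perm], atol=1e-9)


class TestLocalVariant:
    def test_attention_matches_explicit_oracle(self):
        """Local attention weights equal a per-row explicit softmax over
        neighbor scores computed independently."""
        n, k, d = 7, 4, 8
        H, E, nbr, params = random_instance(n, k, d, 6)
        p = params.arrays()
        _, _, A = attention_layer_local(H, E, nbr, p, "L0", return_attention=True)
        Q, K = H @ p["L0_wq"], H @ p["L0_wk"]
        for i in range(n):
            scores = np.array([
                Q[i] @ K[j] / np.sqrt(d) + p["L0_wb"] @ E[i, slot]
                for slot, j in enumerate(nbr[i])
            ])
            expected = np.exp(scores - scores.max())
            expected /= expected.sum()
            np.testing.assert_allclose(A[i], expected, atol=1e-10)

    def test_rows_sum_to_one_over_neighbors(self):
        H, E, nbr, params = random_instance(9, 4, 8, 7)
        _, _, A = attention_layer_local(H, E, nbr, params.arrays(), "L0",
                                        return_attention=True)
        assert A.shape == (9, 4)
        np.testing.assert_allclose(A.sum(axis=1), 1.0, atol=1e-6)

    def test_non_neighbor_perturbation_has_no_effect_locally(self):
        """Local layer ignores non-neighbors; the global layer does not."""
        H, E, nbr, params = random_instance(10, 3, 8, 8)
        p = params.arrays()
        i = 0
        non_neighbors = set(range(10)) - set(nbr[i]) - {i}
        j = sorted(non_neighbors)[0]
        H_pert = H.copy()
        H_pert[j] += 1.0
        H1l, _ = attention_layer_local(H, E, nbr, p, "L0")
        H1l_p, _ = attention_layer_local(H_pert, E, nbr, p, "L0")
        np.testing.assert_allclose(H1l_p[i], H1l[i], atol=1e-12)
        H1g, _ = attention_layer(H, E, nbr, p, "L0")
        H1g_p, _ = attention_layer(H_pert, E, nbr, p, "L0")
        assert np.abs(H1g_p[i] - H1g[i]).max() > 1e-9


class TestForward:
    def test_output_rows_stochastic_and_deterministic(self, toy_structure,
                                                      small_params, masked_partial):
        prof1 = predict_profile(toy_structure, masked_partial, small_params)
        prof2 = predict_profile(toy_structure, masked_partial, small_params)
        np.testing.assert_array_equal(prof1.probs, prof2.probs)  # bitwise
        np.testing.assert_allclose(prof1.probs.sum(axis=1), 1.0, atol=1e-6)

    def test_full_pipeline_rigid_invariance(self, toy_structure, small_params,
                                            masked_partial):
        prof = predict_profile(toy_structure, masked_partial, small_params)
        rng = np.random.default_rng(11)
        for _ in range(5):
            s2 = toy_structure.transformed(random_rotation(rng),
                                           rng.normal(size=3) * 12)
            prof2 = predict_profile(s2, masked_partial, small_params)
            assert np.abs(prof.probs - prof2.probs).max() < 1e-5

    def test_streaming_path_matches_materialized(self, small_params):
        """Above the streaming threshold the forward result is unchanged."""
        from seqrefine.synthetic import ToySpec, generate_backbone
        spec = ToySpec(n_residues=40, motif_plan=[("helix", 20), ("strand", 20)],
                       seed=9)
        s = generate_backbone(spec)
        partial = PartialSequence.fully_masked(40)
        graph = featurize(s, partial, small_params)
        prof_stream = forward(graph, small_params, stream_threshold=10)
        prof_mat = forward(graph, small_params, stream_threshold=1000)
        np.testing.assert_allclose(prof_stream.probs, prof_mat.probs, atol=1e-10)

    def test_dense_mode_full_pipeline(self, toy_structure, masked_partial):
        params = ModelParams(ModelConfig(d=16, n_layers=2, k=8,
                                         attention_mode="global_dense", seed=3))
        graph = featurize(toy_structure, masked_partial, params)
        n = toy_structure.n_residues
        assert graph.edge_features.shape == (n, n, 16)
        prof = forward(graph, params)
        np.testing.assert_allclose(prof.probs.sum(axis=1), 1.0, atol=1e-6)

    def test_no_nans_over_many_parameter_draws(self):
        """Random params at init scale never produce non-finite output."""
        rng = np.random.default_rng(12)
        for seed in range(30):
            n = int(rng.integers(2, 10))
            H, E, nbr, params = random_instance(n, min(4, n - 1), 8, seed)
            graph = ResidueGraph(nbr, np.ones_like(nbr, dtype=bool), H, E)
            prof = forward(graph, params)
            assert np.isfinite(prof.probs).all()


class TestGradientFlow:
    def test_loss_gradient_matches_finite_differences(self):
        """Autodiff gradient of the training loss agrees with central
        finite differences on a sampled subset of every parameter group."""
        from seqrefine.alphabet import encode_sequence
        from seqrefine.corruption import CorruptionConfig, corrupt_sequence, nll_loss
        from seqrefine.graph import (build_knn_graph, compute_edge_features,
                                     compute_node_features, embed_graph)
        from seqrefine.synthetic import ToySpec, couple_sequence, generate_backbone

        cfg = ModelConfig(d=8, n_layers=2, k=4, d_seq=6, n_vector_channels=5,
                          seed=7)
        params = ModelParams(cfg)
        s = generate_backbone(ToySpec(8, [("helix", 4), ("coil", 4)], seed=5))
        tokens = encode_sequence(couple_sequence(s, 3))
        partial = corrupt_sequence(tokens, CorruptionConfig(seed=0),
                                   np.random.default_rng(0))
        nbr = build_knn_graph(s, cfg.k)
        raw_n = compute_node_features(s)
        raw_e = compute_edge_features(s, nbr, cfg.n_rbf, cfg.d_min, cfg.d_max,
                                      cfg.w_offset)

        def loss_value():
            graph = embed_graph(raw_n, raw_e, partial, params, nbr, grad=True)
            probs = forward(graph, params, grad=True)
            return nll_loss(probs, tokens, np.ones(8, bool))

        loss_value().backward()
        rng = np.random.default_rng(1)
        for name, t in params.tensors.items():
            flat = t.data.ravel()
            grad = (t.grad.ravel() if t.grad is not None
                    else np.zeros(flat.size))
            for i in rng.choice(flat.size, size=min(2, flat.size),
                                replace=False):
                eps = 1e-6
                orig = flat[i]
                flat[i] = orig + eps
                lp = float(loss_value().data)
                flat[i] = orig - eps
                lm = float(loss_value().data)
                flat[i] = orig
                fd = (lp - lm) / (2 * eps)
                denom = max(abs(fd), abs(grad[i]), 1e-6)
                assert abs(fd - grad[i]) / denom < 1e-3, name


class TestCheckpoint:
    def test_save_load_roundtrip(self, small_params, tmp_path):
        path = tmp_path / "model.npz"
        small_params.save(path)
        loaded = ModelParams.load(path)
        assert loaded.config == small_params.config
        for k, t in small_params.tensors.items():
            np.testing.assert_array_equal(loaded.tensors[k].data, t.data)
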