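import numpy as np
import pytest

from edice.model import (
    ModelConfig,
    ModelParams,
    SignalSlice,
    contextual_embeddings,
    decode,
    embed_assays,
    embed_cells,
    impute_slice,
    impute_track,
    load_checkpoint,
    sab_params_of,
    save_checkpoint,
    self_attention_block,
)


def brute_force_sab(h, p, n_heads, layer_norm=False):
    """Independent oracle: per-head loops, explicit softmax, FFN, residuals."""
    n, d = h.shape
    dh = d // n_heads
    q = h @ p["Wq"] + p["bq"]
    k = h @ p["Wk"] + p["bk"]
    v = h @ p["Wv"] + p["bv"]
    ctx = np.zeros((n, d))
    for head in range(n_heads):
        sl = slice(head * dh, (head + 1) * dh)
        scores = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                scores[i, j] = q[i, sl] @ k[j, sl] / np.sqrt(dh)
        for i in range(n):
            e = np.exp(scores[i] - scores[i].max())
            w = e / e.sum()
            for j in range(n):
                ctx[i, sl] += w[j] * v[j, sl]
    h1 = h + ctx @ p["Wo"] + p["bo"]
    ffn = np.maximum(h1 @ p["ffn_W1"] + p["ffn_b1"], 0) @ p["ffn_W2"] + p["ffn_b2"]
    return h1 + ffn


def random_sab_params(config, rng):
    d, hid = config.embed_dim, config.attn_hidden
    p = {}
    for name in ("q", "k", "v", "o"):
        p[f"W{name}"] = rng.normal(0, 0.5, (d, d))
        p[f"b{name}"] = rng.normal(0, 0.2, d)
    p["ffn_W1"] = rng.normal(0, 0.5, (d, hid))
    p["ffn_b1"] = rng.normal(0, 0.2, hid)
    p["ffn_W2"] = rng.normal(0, 0.5, (hid, config.attn_out))
    p["ffn_b2"] = rng.normal(0, 0.2, config.attn_out)
    return p


def make_slice(values, observed=None, visible=None):
    values = np.asarray(values, dtype=float)
    observed = np.ones(values.shape, dtype=bool) if observed is None else observed
    visible = observed if visible is None else visible
    return SignalSlice(values * visible, observed, visible)


class TestModelConfig:
    def test_head_divisibility_enforced(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(embed_dim=10, n_heads=4, attn_out=10)

    def test_layer_norm_off_by_default(self):
        assert ModelConfig().layer_norm is False

    def test_published_defaults(self):
        cfg = ModelConfig()
        assert (cfg.embed_dim, cfg.n_heads, cfg.attn_hidden, cfg.attn_out) == (256, 4, 128, 256)
        assert (cfg.decoder_hidden, cfg.decoder_layers, cfg.dropout_rate) == (2048, 2, 0.3)


class TestEmbedCells:
    def test_fully_masked_cell_equals_global_embedding(self, tiny_params, tiny_config):
        visible = np.ones((3, 4), dtype=bool)
        visible[1] = False
        sl = make_slice(np.ones((3, 4)), visible=visible)
        out = embed_cells(sl, tiny_params)
        np.testing.assert_allclose(out[1], tiny_params.arrays["u_cell"][1])

    def test_zero_weights_bias_collapse(self, tiny_config):
        params = ModelParams.initialize(3, 4, tiny_config, seed=0)
        params.arrays["cell_map_W"][:] = 0
        params.arrays["cell_map_b"][:] = 0.7
        sl = make_slice(np.full((3, 4), 2.0))
        out = embed_cells(sl, params)
        for i in range(3):
            np.testing.assert_allclose(
                out[i], 0.7 / 4 + params.arrays["u_cell"][i], atol=1e-12)

    def test_hand_computed_dense_algebra(self, tiny_config):
        # independent dense-algebra oracle with 1/n_obs scaling
        rng = np.random.default_rng(9)
        params = ModelParams.initialize(2, 3, ModelConfig(
            embed_dim=4, n_heads=2, attn_hidden=3, attn_out=4,
            decoder_hidden=5, decoder_layers=1, dropout_rate=0.0), seed=1)
        visible = np.array([[True, True, False], [True, False, False]])
        values = np.abs(rng.normal(size=(2, 3))) * visible
        sl = SignalSlice(values, np.ones((2, 3), bool), visible)
        out = embed_cells(sl, params)
        W, b, u = (params.arrays["cell_map_W"], params.arrays["cell_map_b"],
                   params.arrays["u_cell"])
        for i, n_obs in enumerate([2, 1]):
            expected = np.maximum(values[i] @ W + b, 0) / n_obs + u[i]
            np.testing.assert_allclose(out[i], expected, rtol=1e-9)


class TestEmbedAssays:
    def test_fully_masked_assay_equals_global_embedding(self, tiny_params):
        visible = np.ones((3, 4), dtype=bool)
        visible[:, 2] = False
        sl = make_slice(np.ones((3, 4)), visible=visible)
        out = embed_assays(sl, tiny_params)
        np.testing.assert_allclose(out[2], tiny_params.arrays["u_assay"][2])

    def test_transpose_symmetry_with_swapped_params(self, tiny_config):
        """Transposing the slice and swapping parameter roles reproduces embed_cells."""
        params = ModelParams.initialize(3, 3, ModelConfig(
            embed_dim=8, n_heads=2, attn_hidden=6, attn_out=8,
            decoder_hidden=10, decoder_layers=1, dropout_rate=0.0), seed=3)
        swapped = params.copy()
        swapped.arrays["assay_map_W"] = params.arrays["cell_map_W"].copy()
        swapped.arrays["assay_map_b"] = params.arrays["cell_map_b"].copy()
        swapped.arrays["u_assay"] = params.arrays["u_cell"].copy()
        rng = np.random.default_rng(4)
        visible = rng.random((3, 3)) < 0.8
        values = np.abs(rng.normal(size=(3, 3))) * visible
        sl = SignalSlice(values, np.ones((3, 3), bool), visible)
        sl_t = SignalSlice(values.T, np.ones((3, 3), bool), visible.T)
        np.testing.assert_allclose(embed_cells(sl, params), embed_assays(sl_t, swapped))

    def test_hand_computed(self, tiny_params):
        rng = np.random.default_rng(2)
        visible = np.ones((3, 4), dtype=bool)
        values = np.abs(rng.normal(size=(3, 4)))
        sl = SignalSlice(values, np.ones((3, 4), bool), visible)
        out = embed_assays(sl, tiny_params)
        W, b, u = (tiny_params.arrays["assay_map_W"], tiny_params.arrays["assay_map_b"],
                   tiny_params.arrays["u_assay"])
        for j in range(4):
            expected = np.maximum(values[:, j] @ W + b, 0) / 3 + u[j]
            np.testing.assert_allclose(out[j], expected, rtol=1e-9)


class TestSelfAttentionBlock:
    def test_zero_update_residual_identity(self):
        cfg = ModelConfig(embed_dim=8, n_heads=2, attn_hidden=6, attn_out=8,
                          decoder_hidden=4, decoder_layers=1, dropout_rate=0.0)
        rng = np.random.default_rng(0)
        p = random_sab_params(cfg, rng)
        p["Wv"][:] = 0; p["bv"][:] = 0; p["Wo"][:] = 0; p["bo"][:] = 0
        p["ffn_W2"][:] = 0; p["ffn_b2"][:] = 0
        h = rng.normal(size=(4, 8))
        np.testing.assert_allclose(self_attention_block(h, p, cfg), h)

    def test_single_token_degenerate_softmax(self):
        cfg = ModelConfig(embed_dim=8, n_heads=2, attn_hidden=6, attn_out=8,
                          decoder_hidden=4, decoder_layers=1, dropout_rate=0.0)
        rng = np.random.default_rng(1)
        p = random_sab_params(cfg, rng)
        h = rng.normal(size=(1, 8))
        out = self_attention_block(h, p, cfg)
        np.testing.assert_allclose(out, brute_force_sab(h, p, 2), rtol=1e-9)

    @pytest.mark.parametrize("n,seed", [(3, 0), (2, 1), (5, 2), (4, 3)])
    def test_matches_brute_force_oracle(self, n, seed):
        cfg = ModelConfig(embed_dim=8, n_heads=2, attn_hidden=5, attn_out=8,
                          decoder_hidden=4, decoder_layers=1, dropout_rate=0.0)
        rng = np.random.default_rng(seed)
        p = random_sab_params(cfg, rng)
        h = rng.normal(size=(n, 8))
        np.testing.assert_allclose(self_attention_block(h, p, cfg),
                                   brute_force_sab(h, p, 2), rtol=1e-6)

    def test_permutation_equivariance(self):
        cfg = ModelConfig(embed_dim=8, n_heads=4, attn_hidden=6, attn_out=8,
                          decoder_hidden=4, decoder_layers=1, dropout_rate=0.0)
        rng = np.random.default_rng(5)
        p = random_sab_params(cfg, rng)
        h = rng.normal(size=(5, 8))
        perm = rng.permutation(5)
        np.testing.assert_allclose(self_attention_block(h[perm], p, cfg),
                                   self_attention_block(h, p, cfg)[perm], rtol=1e-9)


class TestDecode:
    def test_constant_network(self, tiny_config):
        params = ModelParams.initialize(3, 4, tiny_config, seed=0)
        for layer in range(tiny_config.decoder_layers):
            params.arrays[f"decoder_W{layer}"][:] = 0
            params.arrays[f"decoder_b{layer}"][:] = 0
        params.arrays["decoder_Wout"][:] = 0
        params.arrays["decoder_bout"][:] = 1.5
        rng = np.random.default_rng(0)
        assert decode(rng.normal(size=8), rng.normal(size=8), params) == pytest.approx(1.5)

    def test_hand_evaluated_relu_chain(self):
        cfg = ModelConfig(embed_dim=2, n_heads=1, attn_hidden=2, attn_out=2,
                          decoder_hidden=1, decoder_layers=1, dropout_rate=0.0)
        params = ModelParams.initialize(2, 2, cfg, seed=0)
        params.arrays["decoder_W0"] = np.array([[1.0], [2.0], [-1.0], [0.5]])
        params.arrays["decoder_b0"] = np.array([0.25])
        params.arrays["decoder_Wout"] = np.array([[3.0]])
        params.arrays["decoder_bout"] = np.array([-1.0])
        c, a = np.array([1.0, 0.5]), np.array([2.0, 4.0])
        hidden = max(1 * 1 + 0.5 * 2 + 2 * -1 + 4 * 0.5 + 0.25, 0)  # = 2.25
        assert decode(c, a, params, cfg) == pytest.approx(3 * hidden - 1.0)

    def test_eval_mode_deterministic_despite_dropout(self):
        cfg = ModelConfig(embed_dim=8, n_heads=2, attn_hidden=6, attn_out=8,
                          decoder_hidden=10, decoder_layers=2, dropout_rate=0.3)
        params = ModelParams.initialize(2, 2, cfg, seed=0)
        rng = np.random.default_rng(0)
        c, a = rng.normal(size=8), rng.normal(size=8)
        assert decode(c, a, params) == decode(c, a, params)


class TestImputeSlice:
    def test_empty_targets(self, tiny_params):
        sl = make_slice(np.ones((3, 4)))
        assert len(impute_slice(sl, [], tiny_params)) == 0

    def test_out_of_range_target(self, tiny_params):
        sl = make_slice(np.ones((3, 4)))
        with pytest.raises(IndexError):
            impute_slice(sl, [(3, 0)], tiny_params)

    def test_factorization_contract_shared_cell_embedding(self, tiny_params):
        """Predictions factor through per-(cell, assay) contextual embeddings."""
        rng = np.random.default_rng(0)
        sl = make_slice(np.abs(rng.normal(size=(3, 4))))
        preds = impute_slice(sl, [(1, 0), (1, 3)], tiny_params)
        emb = contextual_embeddings(sl, tiny_params)
        for pred, j in zip(preds, (0, 3)):
            assert pred == pytest.approx(
                decode(emb.cell_embeddings[1], emb.assay_embeddings[j], tiny_params),
                rel=1e-9)

    def test_masked_entries_have_zero_influence(self, tiny_params):
        """Criterion: corrupting invisible entries never changes predictions."""
        rng = np.random.default_rng(0)
        visible = np.ones((3, 4), dtype=bool)
        visible[0, 1] = visible[2, 3] = False
        values = np.abs(rng.normal(size=(3, 4))) * visible
        sl = make_slice(values, visible=visible)
        base = impute_slice(sl, [(0, 1), (1, 1)], tiny_params)
        corrupted = make_slice(values, visible=visible)
        corrupted.values = values + 100.0 * ~visible  # bypasses the invariant
        np.testing.assert_array_equal(impute_slice(corrupted, [(0, 1), (1, 1)], tiny_params),
                                      base)

    def test_slice_invariant_enforced(self):
        visible = np.zeros((2, 2), dtype=bool)
        with pytest.raises(ValueError, match="0"):
            SignalSlice(np.ones((2, 2)), np.ones((2, 2), bool), visible)


class TestImputeTrack:
    def test_shape_and_determinism(self, small_tensor, tiny_config):
        params = ModelParams.initialize(4, 3, ModelConfig(
            embed_dim=8, n_heads=2, attn_hidden=6, attn_out=8,
            decoder_hidden=10, decoder_layers=2, dropout_rate=0.3), seed=0)
        out1 = impute_track(small_tensor, (1, 2), params)
        out2 = impute_track(small_tensor, (1, 2), params)
        assert out1.shape == (small_tensor.n_bins,)
        np.testing.assert_array_equal(out1, out2)

    def test_constant_tensor_constant_imputation(self, small_binning):
        from edice.data_io import SignalTensor

        values = np.full((3, 2, 200), 0.8, dtype=np.float32)
        tensor = SignalTensor(values, np.ones((3, 2), bool), small_binning,
                              ["a", "b", "c"], ["x", "y"])
        params = ModelParams.initialize(3, 2, ModelConfig(
            embed_dim=8, n_heads=2, attn_hidden=6, attn_out=8,
            decoder_hidden=10, decoder_layers=1, dropout_rate=0.0), seed=0)
        track = impute_track(tensor, (0, 1), params)
        assert np.ptp(track) < 1e-5  # identical slices, identical outputs


class TestCheckpoint:
    def test_round_trip(self, tmp_path, tiny_params):
        path = tmp_path / "model.ckpt.npz"
        save_checkpoint(path, tiny_params, cell_ids=["a", "b", "c"],
                        assay_ids=["w", "x", "y", "z"])
        loaded, meta = load_checkpoint(path)
        assert loaded.allclose(tiny_params)
        assert loaded.config == tiny_params.config
        assert meta["cell_ids"] == ["a", "b", "c"]

    def test_sab_params_extraction(self, tiny_params, tiny_config):
        p = sab_params_of(tiny_params, "cell")
        assert set(p) >= {"Wq", "Wk", "Wv", "Wo", "ffn_W1", "ffn_W2"}
        h = np.random.default_rng(0).normal(size=(3, 8))
        out = self_attention_block(h, p, tiny_config)
        np.testing.assert_allclose(out, brute_force_sab(h, p, tiny_config.n_heads), rtol=1e-6)
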