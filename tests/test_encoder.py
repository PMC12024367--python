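"""Encoder forward map: batch-norm, attention, latent contracts, gradients."""

import numpy as np
import pytest

import spectrafuse as sf
from spectrafuse.encoder import (
    EncoderConfig,
    EncoderParams,
    RunningStats,
    attention_matrix,
    backward,
    batch_normalize,
    dual_path_attention,
    encode,
    forward,
    unimodal_encode,
)
from spectrafuse.trainer import contrastive_loss, contrastive_loss_grad


class TestBatchNormalize:
    def test_standardizes_a_simple_column(self):
        # mu = 2, biased variance = 2/3 -> hand values
        X = np.array([[1.0], [2.0], [3.0]])
        out = batch_normalize(X, gamma=np.ones(1), beta=np.zeros(1), eps=1e-12)
        expected = np.array([-1.22474487, 0.0, 1.22474487])
        assert np.allclose(out.ravel(), expected, atol=1e-7)

    def test_constant_column_maps_to_beta(self):
        X = np.full((4, 1), 7.3)
        out = batch_normalize(X, gamma=np.array([5.0]), beta=np.array([-1.5]))
        assert np.allclose(out, -1.5, atol=1e-6)

    def test_affine_parameters_applied_after_standardization(self):
        X = np.array([[1.0], [2.0], [3.0]])
        base = batch_normalize(X, np.ones(1), np.zeros(1), eps=1e-12)
        scaled = batch_normalize(X, np.array([2.0]), np.array([1.0]), eps=1e-12)
        assert np.allclose(scaled, 2.0 * base + 1.0)

    def test_singleton_batch_rejected_in_train_mode(self):
        with pytest.raises(ValueError, match="batch size"):
            batch_normalize(np.ones((1, 3)), np.ones(3), np.zeros(3))

    def test_running_stats_updated_in_train_used_in_eval(self):
        X = np.array([[0.0], [2.0]])  # mu=1, biased var=1
        stats = RunningStats(mean=np.zeros(1), var=np.ones(1))
        batch_normalize(X, np.ones(1), np.zeros(1), mode="train",
                        running_stats=stats, momentum=0.5)
        assert np.allclose(stats.mean, [0.5])
        assert np.allclose(stats.var, [1.0])  # 0.5*1 + 0.5*1
        out = batch_normalize(np.array([[0.5]]), np.ones(1), np.zeros(1),
                              mode="eval", running_stats=stats, eps=0.0)
        assert np.allclose(out, [[0.0]])


class TestDualPathAttention:
    def test_constant_value_vector_is_fixed_point(self, rng):
        q, k = rng.normal(size=(2, 10))
        v = np.full(10, 3.7)
        assert np.allclose(dual_path_attention(q, k, v), v, atol=1e-12)

    def test_zero_query_gives_uniform_attention_and_mean_output(self, rng):
        k = rng.normal(size=8)
        v = rng.normal(size=8)
        out = dual_path_attention(np.zeros(8), k, v)
        assert np.allclose(out, np.full(8, v.mean()), atol=1e-12)
        A = attention_matrix(np.zeros(8), k)
        assert np.allclose(A, 1.0 / 8.0, atol=1e-12)

    def test_single_token_returns_value(self):
        assert dual_path_attention(np.array([2.0]), np.array([-1.0]),
                                   np.array([5.0])) == pytest.approx(5.0)

    def test_attention_rows_sum_to_one(self, rng):
        q, k = rng.normal(size=(2, 40))
        A = attention_matrix(q, k)
        assert np.allclose(A.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(A >= 0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes differ"):
            dual_path_attention(np.zeros(4), np.zeros(4), np.zeros(3))


def _toy_batch(cfg, n, seed=0):
    rng = np.random.default_rng(seed)
    return (rng.normal(size=(n, cfg.d_ftir)), rng.normal(size=(n, cfg.d_chem)))


class TestEncode:
    def test_default_latent_width_is_40(self):
        cfg = EncoderConfig()  # d1=32, d2=8
        params = EncoderParams.init(cfg, "both")
        assert params.latent_width == 40
        rng = np.random.default_rng(0)
        lat = encode(rng.normal(size=(3, 1801)), rng.normal(size=(3, 36)),
                     params)
        assert lat.values.shape == (3, 40)

    @pytest.mark.parametrize("n", [1, 2, 5])
    def test_eval_mode_width_for_any_batch_size(self, toy_enc_config, n):
        params = EncoderParams.init(toy_enc_config, "both")
        Xf, Xc = _toy_batch(toy_enc_config, n)
        assert encode(Xf, Xc, params).values.shape == (n, 6)

    @pytest.mark.parametrize("n", [2, 3, 7])
    def test_train_mode_width_for_batches_of_two_or_more(self, toy_enc_config, n):
        params = EncoderParams.init(toy_enc_config, "both")
        Xf, Xc = _toy_batch(toy_enc_config, n)
        assert encode(Xf, Xc, params, mode="train").values.shape == (n, 6)

    def test_eval_encoding_is_batch_invariant_and_deterministic(
        self, toy_enc_config
    ):
        params = EncoderParams.init(toy_enc_config, "both")
        Xf, Xc = _toy_batch(toy_enc_config, 6, seed=4)
        full = encode(Xf, Xc, params).values
        again = encode(Xf, Xc, params).values
        assert np.array_equal(full, again)
        solo = encode(Xf[2:3], Xc[2:3], params).values
        assert np.allclose(solo[0], full[2], atol=1e-6)
        shuffled = encode(Xf[::-1], Xc[::-1], params).values
        assert np.allclose(shuffled[::-1], full, atol=1e-6)

    def test_identical_heads_collapse_to_single_head(self, toy_enc_config):
        import dataclasses

        cfg_multi = toy_enc_config
        cfg_single = dataclasses.replace(cfg_multi, n_heads=1)
        single = EncoderParams.init(cfg_single, "both")
        multi = EncoderParams.init(cfg_multi, "both")
        for key, arr in single.arrays.items():
            if key.startswith("head0."):
                for h in range(cfg_multi.n_heads):
                    multi.arrays[key.replace("head0.", f"head{h}.")] = arr.copy()
            else:
                multi.arrays[key] = arr.copy()
        Xf, Xc = _toy_batch(cfg_multi, 4, seed=2)
        assert np.allclose(
            encode(Xf, Xc, single).values, encode(Xf, Xc, multi).values,
            atol=1e-10,
        )

    def test_unimodal_widths_are_d1_and_d2(self):
        cfg = EncoderConfig(d_ftir=50, d_chem=36)
        rng = np.random.default_rng(0)
        ftir = EncoderParams.init(cfg, "ftir_only")
        chem = EncoderParams.init(cfg, "chem_only")
        assert unimodal_encode(rng.normal(size=(3, 50)), "ftir",
                               ftir).values.shape == (3, 32)
        assert unimodal_encode(rng.normal(size=(3, 36)), "chem",
                               chem).values.shape == (3, 8)

    def test_unimodal_encode_rejects_fused_params(self, toy_enc_config):
        params = EncoderParams.init(toy_enc_config, "both")
        with pytest.raises(ValueError, match="modality_set"):
            unimodal_encode(np.zeros((2, toy_enc_config.d_ftir)), "ftir", params)

    def test_shape_mismatch_rejected(self, toy_enc_config):
        params = EncoderParams.init(toy_enc_config, "both")
        with pytest.raises(ValueError, match="expected"):
            encode(np.zeros((2, 5)), np.zeros((2, 3)), params)


class TestCheckpoint:
    def test_save_load_round_trip(self, toy_enc_config, tmp_path):
        params = EncoderParams.init(toy_enc_config, "both")
        path = tmp_path / "ckpt.npz"
        params.save(path)
        loaded = EncoderParams.load(path)
        assert loaded.modality_set == "both"
        assert loaded.config == toy_enc_config
        for key, arr in params.arrays.items():
            assert np.array_equal(arr, loaded.arrays[key])

    def test_shape_validation_on_construction(self, toy_enc_config):
        params = EncoderParams.init(toy_enc_config, "both")
        bad = {k: v.copy() for k, v in params.arrays.items()}
        bad["out.gamma"] = np.ones(3)  # wrong width
        with pytest.raises(ValueError, match="out.gamma"):
            EncoderParams(toy_enc_config, "both", bad)


class TestGradients:
    def test_backprop_matches_finite_differences(self, toy_enc_config):
        """Analytic gradients through the full encoder + contrastive loss."""
        params = EncoderParams.init(toy_enc_config, "both", seed=3)
        rng = np.random.default_rng(0)
        Xf = rng.normal(size=(5, toy_enc_config.d_ftir))
        Xc = rng.normal(size=(5, toy_enc_config.d_chem))
        y = np.array([0, 1, 0, 1, 1])
        inputs = {"ftir": Xf, "chem": Xc}

        Y, cache = forward(params, inputs, mode="train")
        _, dY = contrastive_loss_grad(Y, y)
        grads = backward(params, cache, dY)

        def loss_at(p):
            Yp, _ = forward(p, inputs, mode="train")
            return contrastive_loss(Yp, y)

        eps = 1e-6
        rng2 = np.random.default_rng(99)
        for key in params.trainable_keys():
            arr = params.arrays[key]
            for flat in rng2.choice(arr.size, size=min(3, arr.size),
                                    replace=False):
                idx = np.unravel_index(flat, arr.shape)
                orig = arr[idx]
                arr[idx] = orig + eps
                lp = loss_at(params)
                arr[idx] = orig - eps
                lm = loss_at(params)
                arr[idx] = orig
                fd = (lp - lm) / (2 * eps)
                g = grads[key][idx]
                if max(abs(fd), abs(g)) < 1e-6:
                    continue  # gradient is (numerically) zero; FD is noise
                assert abs(fd - g) / max(abs(fd), abs(g)) < 1e-4, (key, idx)
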