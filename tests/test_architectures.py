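import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from methylfusion.architectures import (
    ModelConfig,
    build_model,
    build_smlp,
    build_ssmfn,
    count_parameters,
    forward,
    fuse,
    load_checkpoint,
    save_checkpoint,
)
from methylfusion.nn import softmax


def random_batch(rng, n, config=None):
    cfg = config or ModelConfig()
    return rng.integers(0, cfg.vocab_size, (n, cfg.window_length))


class TestConfig:
    def test_defaults_match_published_settings(self):
        cfg = ModelConfig()
        assert cfg.vocab_size == 21
        assert cfg.embedding_dim == 21
        assert cfg.window_length == 19
        assert cfg.embedding_dim * cfg.window_length == 399
        assert cfg.lstm_hidden == 64 and cfg.lstm_layers == 2
        assert cfg.cnn_channels == 64 and cfg.cnn_blocks == 4
        assert cfg.dropout_rate == 0.5
        assert cfg.latent_dim == 32 and cfg.output_dim == 2
        assert cfg.learning_rate == 0.001 and cfg.epochs == 500
        assert cfg.optimizer_name == "Adam"

    @pytest.mark.parametrize(
        "field, value",
        [("latent_dim", 0), ("dropout_rate", 1.0), ("learning_rate", -1), ("cnn_blocks", -2)],
    )
    def test_rejects_invalid_values(self, field, value):
        cfg = dataclasses.replace(ModelConfig(), **{field: value})
        with pytest.raises(ValueError):
            cfg.validate()

    def test_round_trips_through_dict(self):
        cfg = ModelConfig(latent_dim=16)
        assert ModelConfig.from_dict(cfg.to_dict()) == cfg


class TestShapes:
    @pytest.mark.parametrize("kind", ["ssmfn_merged", "ssmfn_cnn_only", "ssmfn_lstm_only", "smlp"])
    @pytest.mark.parametrize("n", [1, 7])
    def test_every_kind_emits_two_scores_per_window(self, rng, kind, n):
        model = build_model(kind, rng=0)
        scores = forward(model, random_batch(rng, n))
        assert scores.shape == (n, 2)
        assert np.isfinite(scores).all()

    def test_branch_latents_have_width_32_under_defaults(self):
        model = build_ssmfn(rng=0)
        assert model.lstm_latent.params["W"].shape == (64, 32)
        assert model.cnn_latent.params["W"].shape[1] == 32
        assert model.head.params["W"].shape == (32, 2)

    def test_smlp_first_hidden_width_is_399(self):
        model = build_smlp(rng=0)
        assert model.hidden.params["W"].shape == (399, 399)

    def test_probabilities_row_sum_to_one(self, rng):
        model = build_ssmfn(rng=0)
        p = softmax(forward(model, random_batch(rng, 5)))
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert (p >= 0).all()


class TestParameterCounts:
    def test_smlp_hand_tally(self):
        # embedding 21*21 + hidden 399*399+399 + head 399*2+2
        assert count_parameters(build_smlp(rng=0)) == 441 + 159_600 + 800 == 160_841

    def test_merged_equals_branches_minus_shared(self):
        cfg = ModelConfig()
        merged = count_parameters(build_ssmfn(cfg, "merged", rng=0))
        cnn = count_parameters(build_ssmfn(cfg, "cnn_only", rng=0))
        lstm = count_parameters(build_ssmfn(cfg, "lstm_only", rng=0))
        shared = cfg.vocab_size * cfg.embedding_dim  # embedding
        shared += cfg.latent_dim * cfg.output_dim + cfg.output_dim  # head
        assert merged == cnn + lstm - shared

    def test_count_is_stable_across_rebuilds_and_grows_with_latent(self, tiny_config):
        a = count_parameters(build_ssmfn(tiny_config, rng=0))
        b = count_parameters(build_ssmfn(tiny_config, rng=99))
        assert a == b
        wider = dataclasses.replace(tiny_config, latent_dim=tiny_config.latent_dim * 2)
        assert count_parameters(build_ssmfn(wider, rng=0)) > a

    def test_single_branch_has_fewer_parameters_than_merged(self, tiny_config):
        merged = count_parameters(build_ssmfn(tiny_config, "merged", rng=0))
        assert count_parameters(build_ssmfn(tiny_config, "cnn_only", rng=0)) < merged
        assert count_parameters(build_ssmfn(tiny_config, "lstm_only", rng=0)) < merged


class TestFuse:
    def test_additive_identity_and_sum(self):
        v = np.array([1.0, 2.0, 3.0])
        assert np.array_equal(fuse(v, np.zeros(3)), v)
        assert np.array_equal(fuse(np.array([1.0, 2.0]), np.array([3.0, 4.0])), [4.0, 6.0])

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            fuse(np.zeros(3), np.zeros(4))

    @given(
        hnp.arrays(np.float64, 8, elements=st.floats(-1e6, 1e6)),
        hnp.arrays(np.float64, 8, elements=st.floats(-1e6, 1e6)),
    )
    @settings(max_examples=30, deadline=None)
    def test_commutativity(self, a, b):
        assert np.array_equal(fuse(a, b), fuse(b, a))


class TestFusionWiring:
    def _copy_shared(self, src, dst, names):
        state = {k: v for k, v in src.state_dict().items()
                 if any(k.split(".", 1)[1].startswith(n) for n in names)}
        params = dst.parameters()
        for k, v in state.items():
            scope, name = k.split(".", 1)
            if scope == "param":
                np.copyto(params[name], v)

    def test_zeroed_cnn_branch_reduces_merged_to_lstm_only(self, rng, tiny_config):
        merged = build_ssmfn(tiny_config, "merged", rng=3)
        merged.cnn_latent.params["W"][:] = 0.0
        merged.cnn_latent.params["b"][:] = 0.0
        lstm_only = build_ssmfn(tiny_config, "lstm_only", rng=4)
        self._copy_shared(merged, lstm_only, ("embedding", "lstm", "head"))
        batch = random_batch(rng, 5, tiny_config)
        assert np.allclose(
            forward(merged, batch), forward(lstm_only, batch), atol=1e-6
        )

    def test_zeroed_lstm_branch_reduces_merged_to_cnn_only(self, rng, tiny_config):
        merged = build_ssmfn(tiny_config, "merged", rng=3)
        merged.lstm_latent.params["W"][:] = 0.0
        merged.lstm_latent.params["b"][:] = 0.0
        cnn_only = build_ssmfn(tiny_config, "cnn_only", rng=4)
        self._copy_shared(merged, cnn_only, ("embedding", "conv", "bn", "cnn", "head"))
        batch = random_batch(rng, 5, tiny_config)
        assert np.allclose(
            forward(merged, batch), forward(cnn_only, batch), atol=1e-6
        )

    def test_embedding_is_shared_by_both_branches(self, rng, tiny_config):
        model = build_ssmfn(tiny_config, "merged", rng=0)
        batch = random_batch(rng, 3, tiny_config)
        emb = model.embedding.forward(batch)
        lat_l = model._lstm_forward(emb, False, None).copy()
        lat_c = model._cnn_forward(emb, False, None).copy()
        model.embedding.params["W"] += 0.5
        emb2 = model.embedding.forward(batch)
        assert not np.allclose(model._lstm_forward(emb2, False, None), lat_l)
        assert not np.allclose(model._cnn_forward(emb2, False, None), lat_c)


class TestDeterminismAndErrors:
    def test_eval_forward_is_bit_identical(self, rng, tiny_config):
        model = build_ssmfn(tiny_config, rng=0)
        batch = random_batch(rng, 4, tiny_config)
        assert np.array_equal(forward(model, batch), forward(model, batch))

    def test_out_of_range_index_is_rejected(self, tiny_config):
        model = build_ssmfn(tiny_config, rng=0)
        bad = np.zeros((1, tiny_config.window_length), dtype=np.int64)
        bad[0, 3] = tiny_config.vocab_size
        with pytest.raises(ValueError, match="outside"):
            forward(model, bad)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            build_ssmfn(ModelConfig(), "both_branches")


class TestCheckpoint:
    def test_save_load_round_trip_is_bit_stable(self, rng, tiny_config, tmp_path):
        model = build_ssmfn(tiny_config, "merged", rng=7)
        batch = random_batch(rng, 6, tiny_config)
        before = forward(model, batch)
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        loaded, alphabet = load_checkpoint(path)
        assert loaded.kind == "ssmfn_merged"
        assert alphabet.symbols.endswith("X")
        assert np.array_equal(forward(loaded, batch), before)
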