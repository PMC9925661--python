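"""Hierarchical encoder: backends, attention, heads, gradients."""

import numpy as np
import pytest

from symptomnet.model import (
    HEAD_ARITY,
    BackendUnavailableError,
    HashingEmbedder,
    HierModel,
    ModelConfig,
    PretrainedSentenceEncoder,
    attention_forward,
    encode_turn,
    head_forward,
    make_backend,
)
from symptomnet.transcripts import Speaker, Turn, ValidationError


def tiny_config(**overrides):
    base = dict(d_turn=5, hidden=4, attn_dim=3, head_hidden=6, seed=3)
    base.update(overrides)
    return ModelConfig(**base)


class TestHashingEmbedder:
    def test_turn_embedding_is_mean_of_token_vectors(self):
        emb = HashingEmbedder(dim=16, seed=0)
        expected = (emb.token_vector("a") + emb.token_vector("b")) / 2
        np.testing.assert_allclose(emb.encode("a b"), expected, atol=1e-12)

    def test_independent_recomputation_from_hashing_rule(self):
        """Token vectors match a from-scratch recomputation of the seeded
        blake2b -> RNG -> unit-scaled normal rule."""
        import hashlib

        emb = HashingEmbedder(dim=8, seed=42)
        digest = hashlib.blake2b(b"hello", digest_size=8, key=b"42").digest()
        rng = np.random.default_rng(int.from_bytes(digest, "little"))
        expected = rng.standard_normal(8) / np.sqrt(8)
        np.testing.assert_allclose(emb.token_vector("hello"), expected, atol=0)

    def test_single_token_turn_equals_token_vector(self):
        emb = HashingEmbedder(dim=8, seed=1)
        np.testing.assert_allclose(
            encode_turn(Turn(Speaker.PARTICIPANT, "word", 0), emb),
            emb.token_vector("word"),
        )

    def test_identical_turns_identical_embeddings(self):
        emb = HashingEmbedder(dim=8, seed=1)
        a = encode_turn("some repeated sentence", emb)
        b = encode_turn("some repeated sentence", emb)
        np.testing.assert_array_equal(a, b)

    def test_empty_turn_maps_to_null_embedding(self):
        emb = HashingEmbedder(dim=8, seed=1)
        np.testing.assert_array_equal(emb.encode(""), np.zeros(8))

    def test_case_and_truncation(self):
        emb = HashingEmbedder(dim=8, seed=1, max_tokens=2)
        np.testing.assert_allclose(emb.encode("A b EXTRA tokens"), emb.encode("a b"))


def test_pretrained_backend_unavailable_is_explicit():
    pytest.importorskip  # not used: absence must raise, never skip silently
    try:
        import sentence_transformers  # noqa: F401

        pytest.skip("sentence_transformers installed; unavailability not testable")
    except ImportError:
        pass
    with pytest.raises(BackendUnavailableError):
        PretrainedSentenceEncoder()
    with pytest.raises(BackendUnavailableError):
        make_backend(ModelConfig(turn_backend="pretrained_sentence_encoder"))


class TestEncodeInterview:
    def test_attention_weights_are_a_distribution(self, rng):
        model = HierModel(tiny_config())
        _, attn = model.encode_interview(rng.standard_normal((7, 5)))
        assert (attn >= 0).all()
        assert abs(attn.sum() - 1.0) < 1e-6

    def test_single_turn_embedding_equals_its_state(self, rng):
        model = HierModel(tiny_config())
        X = rng.standard_normal((1, 5))
        h_int, attn = model.encode_interview(X)
        np.testing.assert_allclose(attn, [1.0])
        # recompute the lone concatenated BiLSTM state
        from symptomnet.model import _lstm_forward

        p = model.params
        hf, _ = _lstm_forward(X, p["Wx_fw"], p["Wh_fw"], p["b_fw"])
        hb, _ = _lstm_forward(X[::-1], p["Wx_bw"], p["Wh_bw"], p["b_bw"])
        np.testing.assert_allclose(h_int, np.concatenate([hf[0], hb[0]]), atol=1e-12)

    def test_order_sensitivity_of_recurrent_pass(self, rng):
        model = HierModel(tiny_config())
        X = rng.standard_normal((5, 5))
        h1, _ = model.encode_interview(X)
        h2, _ = model.encode_interview(X[::-1])
        assert np.abs(h1 - h2).max() > 1e-6

    def test_identical_states_get_uniform_attention(self, rng):
        model = HierModel(tiny_config())
        state = rng.standard_normal(8)  # 2 * hidden
        U = np.tile(state, (6, 1))
        _, attn, _ = attention_forward(U, model.params)
        np.testing.assert_allclose(attn, np.full(6, 1 / 6), atol=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        model = HierModel(tiny_config())
        with pytest.raises(ValidationError):
            model.encode_interview(rng.standard_normal((4, 9)))


class TestHeads:
    @pytest.mark.parametrize("head_type,arity", sorted(HEAD_ARITY.items()))
    def test_output_arity_by_head(self, head_type, arity, rng):
        model = HierModel(tiny_config(head_type=head_type))
        out, _ = model.forward(rng.standard_normal((3, 5)))
        assert out.shape == (arity,)

    def test_clamp_boundary(self, rng):
        model = HierModel(tiny_config(head_type="symptoms8"))
        model.params["W2"][:] = 0.0
        model.params["b2"][:] = 5.0
        pred = model.predict(rng.standard_normal((3, 5)))
        np.testing.assert_array_equal(pred, np.full(8, 3.0))

    def test_hand_computed_forward_pass(self):
        """Head arithmetic checked against an explicit 2-d recomputation."""
        params = {
            "W1": np.array([[1.0, 0.0], [0.0, -1.0], [0.5, 0.5]]),
            "b1": np.array([0.1, 0.2, -0.3]),
            "ln_gamma": np.array([1.0, 2.0, 1.0]),
            "ln_beta": np.array([0.0, 0.1, 0.0]),
            "W2": np.array([[1.0, 1.0, 1.0]]),
            "b2": np.array([0.5]),
        }
        h = np.array([0.4, -0.2])
        z1 = params["W1"] @ h + params["b1"]  # [0.5, 0.4, -0.2]
        zl = np.where(z1 > 0, z1, 0.01 * z1)  # [0.5, 0.4, -0.002]
        mu, var = zl.mean(), zl.var()
        xhat = (zl - mu) / np.sqrt(var + 1e-5)
        expected = params["W2"] @ (params["ln_gamma"] * xhat + params["ln_beta"]) + params["b2"]
        out, _ = head_forward(h, params)
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_symptom_predictions_always_in_range(self, rng):
        model = HierModel(tiny_config(head_type="symptoms8"))
        for _ in range(10):
            pred = model.predict(rng.standard_normal((4, 5)) * 10)
            assert (pred >= 0).all() and (pred <= 3).all()
            assert 0 <= pred.sum() <= 24


class TestGradients:
    def test_backward_matches_finite_differences(self, rng):
        """Exact backprop through head, attention and BiLSTM, including the
        gradient with respect to the turn embeddings."""
        model = HierModel(tiny_config())
        X = rng.standard_normal((6, 5))
        direction = rng.standard_normal(8)

        def objective():
            out, _ = model.forward(X)
            return float(out @ direction)

        out, cache = model.forward(X)
        grads, dX = model.backward(cache, direction)
        eps = 1e-6
        for key, P in model.params.items():
            flat = P.ravel()
            for i in rng.choice(P.size, size=min(P.size, 4), replace=False):
                old = flat[i]
                flat[i] = old + eps
                up = objective()
                flat[i] = old - eps
                down = objective()
                flat[i] = old
                numeric = (up - down) / (2 * eps)
                assert abs(numeric - grads[key].ravel()[i]) < 1e-5 * max(1, abs(numeric))
        for i in rng.choice(X.size, size=8, replace=False):
            old = X.ravel()[i]
            X.ravel()[i] = old + eps
            up = objective()
            X.ravel()[i] = old - eps
            down = objective()
            X.ravel()[i] = old
            numeric = (up - down) / (2 * eps)
            assert abs(numeric - dX.ravel()[i]) < 1e-5 * max(1, abs(numeric))

    def test_forward_deterministic_given_seed(self, rng):
        X = rng.standard_normal((4, 5))
        out1, _ = HierModel(tiny_config(seed=9)).forward(X)
        out2, _ = HierModel(tiny_config(seed=9)).forward(X)
        np.testing.assert_array_equal(out1, out2)


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, rng):
        model = HierModel(tiny_config(head_type="severity5"))
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = HierModel.load(path)
        assert loaded.config == model.config
        X = rng.standard_normal((3, 5))
        np.testing.assert_array_equal(model.forward(X)[0], loaded.forward(X)[0])
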