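"""Hierarchical interview encoder and prediction heads.

Architecture (two-level):

1. a turn encoder maps each dialogue turn to a fixed vector by mean-pooling
   token representations (pluggable backend: a pretrained sentence encoder,
   or a fast deterministic hashing embedder used for testing);
2. a single-layer BiLSTM runs over the turn embeddings and a Bahdanau-style
   additive attention layer (score_i = v^T tanh(W u_i + b)) pools the
   concatenated directional states u_i into the interview embedding
   h_int = sum_i a_i u_i;
3. a feed-forward head -- two linear layers with LeakyReLU and LayerNorm
   in between -- maps h_int to the output: eight symptom scores, binary or
   five-class logits, or a single total-score regression value.

Everything is implemented in NumPy with hand-written backpropagation; the
backward pass returns gradients with respect to the turn embeddings as well,
which is what the gradient-saliency analysis differentiates.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path

import numpy as np
import yaml

from .transcripts import Interview, Speaker, Turn, ValidationError

HEAD_ARITY = {"symptoms8": 8, "binary": 2, "severity5": 5, "total_regression": 1}

_LEAKY_SLOPE = 0.01
_LN_EPS = 1e-5


class BackendUnavailableError(RuntimeError):
    """The requested turn-encoder backend cannot be constructed."""


class NumericError(RuntimeError):
    """Non-finite values appeared in a forward pass."""


# ---------------------------------------------------------------------------
# Turn encoder backends
# ---------------------------------------------------------------------------

class HashingEmbedder:
    """Deterministic dependency-free turn encoder.

    Tokens are lowercased and whitespace-split; each token is mapped to a
    fixed random vector whose RNG stream is seeded from a stable hash of
    the token mixed with the embedder seed.  A turn embedding is the mean
    of its token vectors (the null embedding -- all zeros -- for an empty
    turn).  Fast and reproducible across processes, which is what the test
    and synthetic-experiment configurations need.
    """

    name = "hashing_embedder"

    def __init__(self, dim: int = 64, seed: int = 0, max_tokens: int = 128):
        if dim < 1:
            raise ValidationError("embedding dim must be positive")
        self.dim = dim
        self.seed = seed
        self.max_tokens = max_tokens
        self._cache: dict[str, np.ndarray] = {}

    def token_vector(self, token: str) -> np.ndarray:
        vec = self._cache.get(token)
        if vec is None:
            digest = hashlib.blake2b(
                token.encode("utf-8"), digest_size=8, key=str(self.seed).encode()
            ).digest()
            rng = np.random.default_rng(int.from_bytes(digest, "little"))
            vec = rng.standard_normal(self.dim) / np.sqrt(self.dim)
            self._cache[token] = vec
        return vec

    def encode(self, text: str) -> np.ndarray:
        tokens = text.lower().split()[: self.max_tokens]
        if not tokens:
            return np.zeros(self.dim)
        return np.mean([self.token_vector(t) for t in tokens], axis=0)


class PretrainedSentenceEncoder:
    """Sentence-transformer backend (mean-pooled token representations).

    Requires the ``sentence_transformers`` package and downloaded weights;
    absence raises :class:`BackendUnavailableError` -- never a silent
    fallback to another backend.
    """

    name = "pretrained_sentence_encoder"

    def __init__(self, model_name: str = "all-distilroberta-v1"):
        try:
            from sentence_transformers import SentenceTransformer
        except ImportError as exc:
            raise BackendUnavailableError(
                "pretrained_sentence_encoder needs the 'sentence_transformers' "
                "package and its model weights; install them or use the "
                "hashing_embedder backend"
            ) from exc
        self._model = SentenceTransformer(model_name)
        self.dim = self._model.get_sentence_embedding_dimension()

    def encode(self, text: str) -> np.ndarray:
        if not text.strip():
            return np.zeros(self.dim)
        return np.asarray(self._model.encode([text])[0], dtype=float)


def make_backend(config: "ModelConfig"):
    if config.turn_backend == "hashing_embedder":
        return HashingEmbedder(config.d_turn, config.seed, config.max_tokens_per_turn)
    if config.turn_backend == "pretrained_sentence_encoder":
        return PretrainedSentenceEncoder(config.pretrained_model_name)
    raise ValidationError(f"unknown turn backend {config.turn_backend!r}")


def encode_turn(turn: Turn | str, backend) -> np.ndarray:
    """Mean-pooled embedding of one turn under the given backend."""
    text = turn.text if isinstance(turn, Turn) else turn
    vec = backend.encode(text)
    if not np.all(np.isfinite(vec)):
        raise NumericError("turn embedding contains non-finite values")
    return vec


# ---------------------------------------------------------------------------
# Configuration and parameters
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ModelConfig:
    """Hierarchical encoder configuration.

    ``hidden`` is the per-direction recurrent width (the concatenated
    bidirectional state is twice that).
    """

    turn_backend: str = "hashing_embedder"
    d_turn: int = 64
    hidden: int = 300
    attn_dim: int = 128
    head_hidden: int = 256
    head_type: str = "symptoms8"
    include_interviewer_turns: bool = True
    max_tokens_per_turn: int = 128
    clamp_predictions: bool = True
    pretrained_model_name: str = "all-distilroberta-v1"
    seed: int = 0

    def __post_init__(self) -> None:
        for field in ("d_turn", "hidden", "attn_dim", "head_hidden"):
            if getattr(self, field) < 1:
                raise ValidationError(f"{field} must be positive")
        if self.head_type not in HEAD_ARITY:
            raise ValidationError(f"unknown head type {self.head_type!r}")

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelConfig":
        return cls(**yaml.safe_load(text))


def init_params(config: ModelConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    d, h = config.d_turn, config.hidden
    a, m = config.attn_dim, config.head_hidden
    out = HEAD_ARITY[config.head_type]

    def uniform(shape, fan_in):
        k = 1.0 / np.sqrt(fan_in)
        return rng.uniform(-k, k, size=shape)

    params: dict[str, np.ndarray] = {}
    for direction in ("fw", "bw"):
        params[f"Wx_{direction}"] = uniform((4 * h, d), h)
        params[f"Wh_{direction}"] = uniform((4 * h, h), h)
        params[f"b_{direction}"] = np.zeros(4 * h)
        # forget-gate bias 1: standard trick for stable early training
        params[f"b_{direction}"][h : 2 * h] = 1.0
    params["Wa"] = uniform((a, 2 * h), 2 * h)
    params["ba"] = np.zeros(a)
    params["va"] = uniform((a,), a)
    params["W1"] = uniform((m, 2 * h), 2 * h)
    params["b1"] = np.zeros(m)
    params["ln_gamma"] = np.ones(m)
    params["ln_beta"] = np.zeros(m)
    params["W2"] = uniform((out, m), m)
    params["b2"] = np.zeros(out)
    return params


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


# ---------------------------------------------------------------------------
# Forward / backward primitives
# ---------------------------------------------------------------------------

def _lstm_forward(X: np.ndarray, Wx, Wh, b):
    T = X.shape[0]
    h = Wh.shape[1]
    H = np.zeros((T, h))
    cache = []
    h_prev = np.zeros(h)
    c_prev = np.zeros(h)
    for t in range(T):
        pre = Wx @ X[t] + Wh @ h_prev + b
        i = _sigmoid(pre[:h])
        f = _sigmoid(pre[h : 2 * h])
        g = np.tanh(pre[2 * h : 3 * h])
        o = _sigmoid(pre[3 * h :])
        c = f * c_prev + i * g
        hc = np.tanh(c)
        ht = o * hc
        cache.append((X[t], h_prev, c_prev, i, f, g, o, hc))
        H[t] = ht
        h_prev, c_prev = ht, c
    return H, cache


def _lstm_backward(dH: np.ndarray, cache, Wx, Wh):
    T = dH.shape[0]
    h = Wh.shape[1]
    dX = np.zeros((T, Wx.shape[1]))
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * h)
    dh_next = np.zeros(h)
    dc_next = np.zeros(h)
    for t in range(T - 1, -1, -1):
        x, h_prev, c_prev, i, f, g, o, hc = cache[t]
        dh = dH[t] + dh_next
        do = dh * hc
        dc = dc_next + dh * o * (1.0 - hc * hc)
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dc_next = dc * f
        dpre = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ]
        )
        dWx += np.outer(dpre, x)
        dWh += np.outer(dpre, h_prev)
        db += dpre
        dX[t] = Wx.T @ dpre
        dh_next = Wh.T @ dpre
    return dX, dWx, dWh, db


def attention_forward(U: np.ndarray, params: dict):
    """Additive attention over states U (T x 2h) -> (h_int, weights, cache)."""
    pre = U @ params["Wa"].T + params["ba"]
    tq = np.tanh(pre)
    s = tq @ params["va"]
    s = s - s.max()
    e = np.exp(s)
    a = e / e.sum()
    h_int = a @ U
    return h_int, a, (U, tq, a)


def attention_backward(dh_int: np.ndarray, cache, params: dict):
    U, tq, a = cache
    dU = np.outer(a, dh_int)
    da = U @ dh_int
    ds = a * (da - np.dot(a, da))
    dva = tq.T @ ds
    dtq = np.outer(ds, params["va"])
    dpre = dtq * (1.0 - tq * tq)
    dWa = dpre.T @ U
    dba = dpre.sum(axis=0)
    dU += dpre @ params["Wa"]
    return dU, {"Wa": dWa, "ba": dba, "va": dva}


def head_forward(h_int: np.ndarray, params: dict):
    z1 = params["W1"] @ h_int + params["b1"]
    zl = np.where(z1 > 0, z1, _LEAKY_SLOPE * z1)
    mu = zl.mean()
    var = zl.var()
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (zl - mu) * inv
    z = params["ln_gamma"] * xhat + params["ln_beta"]
    out = params["W2"] @ z + params["b2"]
    return out, (h_int, z1, xhat, inv, z)


def head_backward(dout: np.ndarray, cache, params: dict):
    h_int, z1, xhat, inv, z = cache
    m = z1.shape[0]
    dW2 = np.outer(dout, z)
    db2 = dout.copy()
    dz = params["W2"].T @ dout
    dgamma = dz * xhat
    dbeta = dz.copy()
    dxhat = dz * params["ln_gamma"]
    dzl = (inv / m) * (m * dxhat - dxhat.sum() - xhat * np.dot(dxhat, xhat))
    dz1 = dzl * np.where(z1 > 0, 1.0, _LEAKY_SLOPE)
    dW1 = np.outer(dz1, h_int)
    db1 = dz1.copy()
    dh_int = params["W1"].T @ dz1
    grads = {
        "W1": dW1, "b1": db1, "ln_gamma": dgamma, "ln_beta": dbeta,
        "W2": dW2, "b2": db2,
    }
    return dh_int, grads


# ---------------------------------------------------------------------------
# Full model
# ---------------------------------------------------------------------------

class HierModel:
    """Turn-embedding sequence -> prediction, with exact backprop."""

    def __init__(self, config: ModelConfig, params: dict[str, np.ndarray] | None = None):
        self.config = config
        if params is None:
            params = init_params(config, np.random.default_rng(config.seed))
        self.params = params

    # -- encoding ----------------------------------------------------------

    def interview_embeddings(self, interview: Interview, backend) -> np.ndarray:
        """Stack turn embeddings (optionally participant turns only)."""
        turns = interview.turns
        if not self.config.include_interviewer_turns:
            kept = [t for t in turns if t.speaker is Speaker.PARTICIPANT]
            turns = kept if kept else turns
        return np.stack([encode_turn(t, backend) for t in turns])

    def encode_interview(self, embeddings: np.ndarray):
        """BiLSTM + additive attention: embeddings (T x d) -> (h_int, weights)."""
        h_int, attn, _ = self._encode_with_cache(np.asarray(embeddings, dtype=float))
        return h_int, attn

    def _encode_with_cache(self, X: np.ndarray):
        if X.ndim != 2 or X.shape[0] < 1:
            raise ValidationError("need a (T, d) array with at least one turn")
        if X.shape[1] != self.config.d_turn:
            raise ValidationError(
                f"embedding dim {X.shape[1]} != configured d_turn {self.config.d_turn}"
            )
        p = self.params
        Hf, cache_f = _lstm_forward(X, p["Wx_fw"], p["Wh_fw"], p["b_fw"])
        Hb_rev, cache_b = _lstm_forward(X[::-1], p["Wx_bw"], p["Wh_bw"], p["b_bw"])
        U = np.concatenate([Hf, Hb_rev[::-1]], axis=1)
        h_int, attn, attn_cache = attention_forward(U, p)
        return h_int, attn, (X, cache_f, cache_b, attn_cache)

    # -- forward / backward ------------------------------------------------

    def forward(self, X: np.ndarray):
        """Raw head output (no clamping/decoding) plus the backward cache."""
        h_int, attn, enc_cache = self._encode_with_cache(X)
        out, head_cache = head_forward(h_int, self.params)
        if not np.all(np.isfinite(out)):
            raise NumericError(
                f"non-finite head output {out!r} (|h_int| max "
                f"{np.abs(h_int).max():.3g})"
            )
        return out, (enc_cache, head_cache, attn)

    def backward(self, cache, dout: np.ndarray):
        """Gradients of a scalar objective with head-output gradient ``dout``.

        Returns (parameter-gradient dict, gradient w.r.t. turn embeddings).
        """
        (X, cache_f, cache_b, attn_cache), head_cache, _ = cache
        p = self.params
        dh_int, grads = head_backward(np.asarray(dout, dtype=float), head_cache, p)
        dU, attn_grads = attention_backward(dh_int, attn_cache, p)
        grads.update(attn_grads)
        h = self.config.hidden
        dX_f, dWx_f, dWh_f, db_f = _lstm_backward(dU[:, :h], cache_f, p["Wx_fw"], p["Wh_fw"])
        dX_b_rev, dWx_b, dWh_b, db_b = _lstm_backward(
            dU[:, h:][::-1], cache_b, p["Wx_bw"], p["Wh_bw"]
        )
        grads.update(
            {
                "Wx_fw": dWx_f, "Wh_fw": dWh_f, "b_fw": db_f,
                "Wx_bw": dWx_b, "Wh_bw": dWh_b, "b_bw": db_b,
            }
        )
        dX = dX_f + dX_b_rev[::-1]
        return grads, dX

    # -- prediction --------------------------------------------------------

    def predict(self, X: np.ndarray):
        """Decoded prediction for one interview's turn-embedding matrix.

        symptoms8 -> 8 scores (clamped to [0,3] when configured);
        binary / severity5 -> (class index, logits); total_regression ->
        scalar total.
        """
        out, _ = self.forward(X)
        return self.decode(out)

    def decode(self, out: np.ndarray):
        head = self.config.head_type
        if head == "symptoms8":
            return np.clip(out, 0.0, 3.0) if self.config.clamp_predictions else out
        if head in ("binary", "severity5"):
            return int(np.argmax(out)), out
        return float(out[0])

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-archive checkpoint: parameters + YAML config."""
        arrays = dict(self.params)
        arrays["__config__"] = np.frombuffer(
            self.config.to_yaml().encode("utf-8"), dtype=np.uint8
        )
        np.savez(Path(path), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "HierModel":
        with np.load(Path(path)) as archive:
            config = ModelConfig.from_yaml(bytes(archive["__config__"]).decode("utf-8"))
            params = {k: archive[k].copy() for k in archive.files if k != "__config__"}
        return cls(config, params)

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}


def encode_interview(embeddings: np.ndarray, model: HierModel):
    """Functional form of :meth:`HierModel.encode_interview`."""
    return model.encode_interview(embeddings)


def predict(h_int: np.ndarray, model: HierModel):
    """Head-only prediction from a precomputed interview embedding."""
    out, _ = head_forward(np.asarray(h_int, dtype=float), model.params)
    if not np.all(np.isfinite(out)):
        raise NumericError("non-finite head output")
    return model.decode(out)
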