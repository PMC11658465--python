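"""A small trainable transformer encoder.

The relation-extraction machinery only requires the encoder contract
``V = encode(x_1 … x_z)`` — a contextual vector per input token — so the
encoder is pluggable.  This module provides a compact pre-layer-norm
transformer (learned token + position embeddings, multi-head self-attention,
ReLU feed-forward blocks) sized for desk-scale experiments (default: two
layers, two heads, hidden size 64).

Everything runs on the package's own autodiff engine; the token-embedding
table is exposed as ``tok_emb`` because adversarial training perturbs it
directly.
"""

from __future__ import annotations

import numpy as np

from ._autograd import Tensor, no_grad, softmax
from .samples import EncoderConfig

__all__ = ["TinyTransformerEncoder"]

_NEG_INF = -1e9


def _layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = centered.pow(2).mean(axis=-1, keepdims=True)
    return centered / (var + eps).sqrt() * gamma + beta


class TinyTransformerEncoder:
    """Pre-LN transformer encoder over padded integer token batches."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        self.config = config
        h, ffn = config.hidden_size, config.ffn_size
        vocab_size = len(config.vocab)
        scale = 0.02

        def p(*shape):
            return Tensor.param(rng.normal(0.0, scale, size=shape))

        self.tok_emb = p(vocab_size, h)
        self.pos_emb = p(config.max_length, h)
        self.rel_window = 8  # relative attention bias clipped to ±window
        self.layers: list[dict[str, Tensor]] = []
        for _ in range(config.n_layers):
            self.layers.append(
                {
                    "ln1_g": Tensor.param(np.ones(h)),
                    "ln1_b": Tensor.param(np.zeros(h)),
                    "wq": p(h, h),
                    "wk": p(h, h),
                    "wv": p(h, h),
                    "wo": p(h, h),
                    "rel_bias": Tensor.param(
                        np.zeros((config.n_heads, 2 * self.rel_window + 1))
                    ),
                    "ln2_g": Tensor.param(np.ones(h)),
                    "ln2_b": Tensor.param(np.zeros(h)),
                    "w1": p(h, ffn),
                    "b1": Tensor.param(np.zeros(ffn)),
                    "w2": p(ffn, h),
                    "b2": Tensor.param(np.zeros(h)),
                }
            )
        self.ln_f_g = Tensor.param(np.ones(h))
        self.ln_f_b = Tensor.param(np.zeros(h))

    # -- parameter plumbing ---------------------------------------------------

    def parameters(self) -> list[Tensor]:
        params = [self.tok_emb, self.pos_emb, self.ln_f_g, self.ln_f_b]
        for layer in self.layers:
            params.extend(layer.values())
        return params

    def named_parameters(self) -> dict[str, Tensor]:
        named = {
            "tok_emb": self.tok_emb,
            "pos_emb": self.pos_emb,
            "ln_f_g": self.ln_f_g,
            "ln_f_b": self.ln_f_b,
        }
        for i, layer in enumerate(self.layers):
            for k, v in layer.items():
                named[f"layer{i}.{k}"] = v
        return named

    # -- forward --------------------------------------------------------------

    def encode(self, token_ids: np.ndarray, attn_mask: np.ndarray | None = None) -> Tensor:
        """Contextual representations for a padded batch.

        token_ids: int array (B, L); attn_mask: bool array (B, L) with True
        on real tokens (defaults to everything-real).  Returns V of shape
        (B, L, h); row ``V[b, i]`` is the contextual vector of token i.
        """
        token_ids = np.asarray(token_ids)
        squeeze = token_ids.ndim == 1
        if squeeze:
            token_ids = token_ids[None, :]
        B, L = token_ids.shape
        if L > self.config.max_length:
            raise ValueError(f"sequence length {L} exceeds max_length {self.config.max_length}")
        if token_ids.max() >= len(self.config.vocab) or token_ids.min() < 0:
            raise ValueError("token id out of vocabulary range")
        if attn_mask is None:
            attn_mask = np.ones((B, L), dtype=bool)

        nh = self.config.n_heads
        h = self.config.hidden_size
        d = h // nh
        # additive mask over keys: (B, 1, 1, L)
        add_mask = np.where(attn_mask, 0.0, _NEG_INF)[:, None, None, :]

        # relative-distance bucket index matrix, shared across layers
        rel = np.arange(L)[None, :] - np.arange(L)[:, None]
        rel_idx = np.clip(rel, -self.rel_window, self.rel_window) + self.rel_window

        x = self.tok_emb[token_ids] + self.pos_emb[np.arange(L)]
        for layer in self.layers:
            a_in = _layer_norm(x, layer["ln1_g"], layer["ln1_b"])
            q = (a_in @ layer["wq"]).reshape(B, L, nh, d).swapaxes(1, 2)
            k = (a_in @ layer["wk"]).reshape(B, L, nh, d).swapaxes(1, 2)
            v = (a_in @ layer["wv"]).reshape(B, L, nh, d).swapaxes(1, 2)
            head_idx = np.repeat(np.arange(nh), L * L)
            bias = layer["rel_bias"][(head_idx, np.tile(rel_idx.ravel(), nh))].reshape(
                1, nh, L, L
            )
            scores = (
                (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(d)) + bias + Tensor(add_mask)
            )
            attn = softmax(scores, axis=-1)
            ctx = (attn @ v).swapaxes(1, 2).reshape(B, L, h)
            x = x + ctx @ layer["wo"]
            f_in = _layer_norm(x, layer["ln2_g"], layer["ln2_b"])
            x = x + (f_in @ layer["w1"] + layer["b1"]).relu() @ layer["w2"] + layer["b2"]
        out = _layer_norm(x, self.ln_f_g, self.ln_f_b)
        return out[0] if squeeze else out

    # -- (de)serialization ----------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.named_parameters().items():
            v.data[...] = state[k]
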