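"""A deterministic toy causal transformer, in pure NumPy.

Stands in for a pretrained causal language model (e.g. GPT-2) wherever the
pipeline needs per-layer, per-token activations: small fixed random weights,
pre-norm blocks, and strict causal attention.  Two contracts matter and are
enforced by construction:

* **causality** — the hidden state at position ``t`` never depends on
  tokens at positions ``> t``;
* **determinism** — identical ``(seed, tokens, mask)`` give bit-identical
  activations.

The attention mask can additionally be *banded* per layer, which is how the
attention-span ablation restricts how far back each layer may look.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ToyCausalLM"]

_LN_EPS = 1e-5


def _layer_norm(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    return (x - mu) / np.sqrt(var + _LN_EPS)


@dataclass
class ToyCausalLM:
    """Fixed-weight causal transformer exposing per-layer activations.

    Parameters
    ----------
    n_layers, dim, n_heads, vocab_size
        Architecture sizes; ``dim`` must be divisible by ``n_heads``.
    seed
        Seeds the weight initialization; the forward pass itself has no
        randomness.
    max_positions
        Length of the learned positional table, an upper bound on any
        input window.
    """

    n_layers: int = 4
    dim: int = 16
    n_heads: int = 2
    vocab_size: int = 50
    seed: int = 0
    max_positions: int = 2048

    _weights: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.dim % self.n_heads != 0:
            raise ValueError(
                f"dim ({self.dim}) must be divisible by n_heads ({self.n_heads})"
            )
        if min(self.n_layers, self.dim, self.n_heads, self.vocab_size) < 1:
            raise ValueError("all architecture sizes must be >= 1")
        rng = np.random.default_rng(self.seed)
        s = 1.0 / np.sqrt(self.dim)
        w: dict = {
            "emb": rng.normal(0.0, 1.0, (self.vocab_size, self.dim)),
            "pos": rng.normal(0.0, 0.1, (self.max_positions, self.dim)),
            "blocks": [],
        }
        for _ in range(self.n_layers):
            w["blocks"].append(
                {
                    "wq": rng.normal(0.0, s, (self.dim, self.dim)),
                    "wk": rng.normal(0.0, s, (self.dim, self.dim)),
                    "wv": rng.normal(0.0, s, (self.dim, self.dim)),
                    "wo": rng.normal(0.0, s, (self.dim, self.dim)),
                    "w1": rng.normal(0.0, s, (self.dim, 4 * self.dim)),
                    "b1": np.zeros(4 * self.dim),
                    "w2": rng.normal(0.0, 0.5 * s, (4 * self.dim, self.dim)),
                    "b2": np.zeros(self.dim),
                }
            )
        self._weights = w

    # ------------------------------------------------------------------

    def embed(self, tokens: np.ndarray) -> np.ndarray:
        """Non-contextual token embedding (the pipeline's "layer 0")."""
        tokens = np.asarray(tokens, dtype=np.int64)
        if tokens.ndim != 1:
            raise ValueError("tokens must be a 1-D sequence of ids")
        if len(tokens) and (tokens.min() < 0 or tokens.max() >= self.vocab_size):
            raise ValueError("token id out of vocabulary range")
        return self._weights["emb"][tokens].copy()

    def _attention(self, x: np.ndarray, blk: dict, mask: np.ndarray) -> np.ndarray:
        t, d = x.shape
        hd = d // self.n_heads
        q = (x @ blk["wq"]).reshape(t, self.n_heads, hd)
        k = (x @ blk["wk"]).reshape(t, self.n_heads, hd)
        v = (x @ blk["wv"]).reshape(t, self.n_heads, hd)
        # scores: (heads, query, key)
        scores = np.einsum("qhd,khd->hqk", q, k) / np.sqrt(hd)
        scores = np.where(mask[None, :, :], scores, -np.inf)
        scores -= scores.max(axis=-1, keepdims=True)
        att = np.exp(scores)
        att /= att.sum(axis=-1, keepdims=True)
        out = np.einsum("hqk,khd->qhd", att, v).reshape(t, d)
        return out @ blk["wo"]

    def hidden_states(
        self, tokens: np.ndarray, layer_masks: list[np.ndarray] | None = None
    ) -> np.ndarray:
        """Run the model; return activations of shape (n_layers+1, T, dim).

        Index 0 is the non-contextual embedding; index ``l`` (1-based) is
        the residual stream after block ``l``.  ``layer_masks`` optionally
        gives one boolean (T, T) attention mask per block (True = key
        visible); each mask is intersected with the causal mask.
        """
        tokens = np.asarray(tokens, dtype=np.int64)
        t = len(tokens)
        if t == 0:
            raise ValueError("empty token sequence")
        if t > self.max_positions:
            raise ValueError(f"sequence length {t} exceeds max_positions")
        emb = self.embed(tokens)
        causal = np.tril(np.ones((t, t), dtype=bool))
        if layer_masks is None:
            layer_masks = [causal] * self.n_layers
        else:
            if len(layer_masks) != self.n_layers:
                raise ValueError("one mask per block required")
            layer_masks = [np.asarray(m, dtype=bool) & causal for m in layer_masks]
            for m in layer_masks:
                # every query must see at least itself, else softmax degenerates
                if not np.all(np.diagonal(m)):
                    raise ValueError("attention mask must keep the diagonal visible")

        h = emb + self._weights["pos"][:t]
        states = np.empty((self.n_layers + 1, t, self.dim))
        states[0] = emb
        for li, blk in enumerate(self._weights["blocks"]):
            h = h + self._attention(_layer_norm(h), blk, layer_masks[li])
            h = h + (np.maximum(_layer_norm(h) @ blk["w1"] + blk["b1"], 0.0) @ blk["w2"] + blk["b2"])
            states[li + 1] = h
        return states

    def last_hidden_batched(self, windows: np.ndarray, layer: int) -> np.ndarray:
        """Final-position activation of ``layer`` for a batch of windows.

        ``windows`` is (B, L) token ids; attention is plain causal, positions
        are window-relative (0..L-1), matching per-window extraction.  Only
        the residual stream at the last position is returned, shape (B, dim).
        """
        windows = np.asarray(windows, dtype=np.int64)
        if windows.ndim != 2:
            raise ValueError("windows must be (batch, length)")
        b, t = windows.shape
        if layer == 0:
            return self._weights["emb"][windows[:, -1]].copy()
        if not 1 <= layer <= self.n_layers:
            raise ValueError(f"layer {layer} out of range 0..{self.n_layers}")
        causal = np.tril(np.ones((t, t), dtype=bool))
        h = self._weights["emb"][windows] + self._weights["pos"][:t][None, :, :]
        hd = self.dim // self.n_heads
        for blk in self._weights["blocks"][:layer]:
            x = _layer_norm(h)
            q = (x @ blk["wq"]).reshape(b, t, self.n_heads, hd)
            k = (x @ blk["wk"]).reshape(b, t, self.n_heads, hd)
            v = (x @ blk["wv"]).reshape(b, t, self.n_heads, hd)
            scores = np.einsum("bqhd,bkhd->bhqk", q, k) / np.sqrt(hd)
            scores = np.where(causal[None, None, :, :], scores, -np.inf)
            scores -= scores.max(axis=-1, keepdims=True)
            att = np.exp(scores)
            att /= att.sum(axis=-1, keepdims=True)
            out = np.einsum("bhqk,bkhd->bqhd", att, v).reshape(b, t, self.dim)
            h = h + out @ blk["wo"]
            h = h + (np.maximum(_layer_norm(h) @ blk["w1"] + blk["b1"], 0.0) @ blk["w2"] + blk["b2"])
        return h[:, -1, :]

    def banded_masks(
        self, t: int, span: int, span_layer_cap: int, anchor: int | None = None
    ) -> list[np.ndarray]:
        """Per-block masks restricting layers ``<= span_layer_cap`` to a band.

        With ``anchor=None`` the band is per-query (query ``i`` sees keys
        ``>= i - span``).  With an ``anchor`` position the band is fixed at
        ``>= anchor - span`` for every query, which is what guarantees that
        the *anchor* position's activation at every capped layer depends on
        no token before ``anchor - span`` even after stacking blocks
        (diagonal entries stay visible so off-band queries remain defined).
        """
        causal = np.tril(np.ones((t, t), dtype=bool))
        if anchor is None:
            idx = np.arange(t)
            band = idx[None, :] >= (idx[:, None] - span)
        else:
            band = np.broadcast_to(np.arange(t)[None, :] >= anchor - span, (t, t)).copy()
        band = (band & causal) | np.eye(t, dtype=bool)
        masks = []
        for li in range(self.n_layers):
            masks.append(band if (li + 1) <= span_layer_cap else causal)
        return masks
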