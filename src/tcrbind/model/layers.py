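"""Transformer encoder with disentangled (relative-position) self-attention.

Attention scores combine three terms over clipped relative distances
delta(i, j) = clip(i - j, -k, k):

    score(i, j) = Qc_i . Kc_j              (content -> content)
                + Qc_i . Kr[delta(i, j)]   (content -> position)
                + Qr[delta(j, i)] . Kc_j   (position -> content)

scaled by sqrt(3 * d_head) and row-softmaxed.  Kr/Qr are the key/query
projections (weights only, no bias) of a learned relative-position embedding
table of size 2k+1; with that table zeroed the layer reduces exactly to
standard scaled dot-product attention at the sqrt(3 d_head) scale.  Position
information enters only through delta, so scores are invariant to shifting
the whole sequence.  Layers are pre-norm; a final layer norm closes the
stack.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

NEG_INF = -1e9


class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params


def _init(rng: np.random.Generator, shape, dtype, std: float = 1.0) -> Tensor:
    return Tensor(rng.normal(0.0, std, size=shape).astype(dtype), requires_grad=True)


class Linear(Module):
    """Affine map with fan-in scaled (Xavier-style) weight initialization —
    keeps activation scale steady through the pre-norm stack."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, dtype,
                 std: float | None = None):
        self.w = _init(rng, (d_in, d_out), dtype,
                       std=d_in ** -0.5 if std is None else std)
        self.b = Tensor(np.zeros(d_out, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.matmul(self.w) + self.b


class LayerNorm(Module):
    def __init__(self, dim: int, dtype):
        self.gamma = Tensor(np.ones(dim, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.layer_norm(self.gamma, self.beta)


class Dropout:
    """Inverted dropout driven by an explicit generator (deterministic under
    a fixed seed); identity when inactive or p == 0."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p

    def __call__(self, x: Tensor, rng: np.random.Generator | None) -> Tensor:
        if rng is None or self.p == 0.0:
            return x
        u = rng.random(x.shape, dtype=np.float32)
        keep = (u >= self.p).astype(x.data.dtype) * float(1.0 / (1.0 - self.p))
        return x * keep


class DisentangledSelfAttention(Module):
    def __init__(self, d_model: int, n_heads: int, rel_window: int,
                 dropout: float, rng: np.random.Generator, dtype):
        if rel_window <= 0:
            raise ValueError("relative-position window must be positive")
        if d_model % n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.k = rel_window
        self.wq = Linear(d_model, d_model, rng, dtype)
        self.wk = Linear(d_model, d_model, rng, dtype)
        self.wv = Linear(d_model, d_model, rng, dtype)
        self.wo = Linear(d_model, d_model, rng, dtype)
        # learned relative-position embeddings for delta in [-k, k]
        self.rel_emb = _init(rng, (2 * rel_window + 1, d_model), dtype)
        self.drop = Dropout(dropout)

    def _delta_index(self, n_query: int, n_key: int) -> np.ndarray:
        """idx[i, j] = clip(i - j, -k, k) + k (index into the 2k+1 table)."""
        i = np.arange(n_query)[:, None]
        j = np.arange(n_key)[None, :]
        return np.clip(i - j, -self.k, self.k) + self.k

    def _split(self, x: Tensor, batch: int, length: int) -> Tensor:
        return x.reshape(batch, length, self.n_heads, self.d_head).swapaxes(1, 2)

    def attention_scores(self, x: Tensor, valid: np.ndarray | None = None) -> Tensor:
        """Row-softmaxed attention weights, shape (B, H, L, L)."""
        batch, length, _ = x.shape
        qc = self._split(self.wq(x), batch, length)
        kc = self._split(self.wk(x), batch, length)
        # project the relative-position table with the same (bias-free)
        # content projections: (H, 2k+1, d_head)
        r = 2 * self.k + 1
        kr = self.rel_emb.matmul(self.wk.w).reshape(r, self.n_heads, self.d_head).swapaxes(0, 1)
        qr = self.rel_emb.matmul(self.wq.w).reshape(r, self.n_heads, self.d_head).swapaxes(0, 1)

        idx = self._delta_index(length, length)
        c2c = qc.matmul(kc.swapaxes(-1, -2))                       # (B,H,L,L)
        c2p = qc.matmul(kr.swapaxes(-1, -2)).gather_last(idx)      # (B,H,L,L)
        p2c = kc.matmul(qr.swapaxes(-1, -2)).gather_last(idx).swapaxes(-1, -2)

        scale = float(1.0 / np.sqrt(3.0 * self.d_head))  # python float: keeps f32
        scores = (c2c + c2p + p2c) * scale
        if valid is not None:
            mask = np.where(valid[:, None, None, :], 0.0, NEG_INF).astype(x.data.dtype)
            scores = scores + mask
        return scores.softmax(axis=-1)

    def __call__(self, x: Tensor, valid: np.ndarray | None = None,
                 rng: np.random.Generator | None = None) -> Tensor:
        batch, length, d_model = x.shape
        attn = self.attention_scores(x, valid)
        attn = self.drop(attn, rng)
        vc = self._split(self.wv(x), batch, length)
        ctx = attn.matmul(vc).swapaxes(1, 2).reshape(batch, length, d_model)
        return self.wo(ctx)


class FeedForward(Module):
    def __init__(self, d_model: int, dropout: float, rng, dtype):
        self.lin1 = Linear(d_model, 4 * d_model, rng, dtype)
        self.lin2 = Linear(4 * d_model, d_model, rng, dtype)
        self.drop = Dropout(dropout)

    def __call__(self, x: Tensor, rng=None) -> Tensor:
        return self.lin2(self.drop(self.lin1(x).relu(), rng))


class EncoderLayer(Module):
    def __init__(self, d_model: int, n_heads: int, rel_window: int,
                 dropout: float, rng, dtype):
        self.ln1 = LayerNorm(d_model, dtype)
        self.attn = DisentangledSelfAttention(d_model, n_heads, rel_window,
                                              dropout, rng, dtype)
        self.ln2 = LayerNorm(d_model, dtype)
        self.ffn = FeedForward(d_model, dropout, rng, dtype)

    def __call__(self, x: Tensor, valid, rng=None) -> Tensor:
        x = x + self.attn(self.ln1(x), valid, rng)
        x = x + self.ffn(self.ln2(x), rng)
        return x


class Encoder(Module):
    """Token + segment embedding, stacked pre-norm disentangled-attention
    layers.

    Tokens carry no absolute positions (position enters attention only via
    relative distances), so each token additionally receives a learned
    segment embedding identifying the input component it belongs to (alpha
    chain, beta chain, peptide, MHC pseudosequence) — derived on the fly
    from the delimiting prefix tokens.
    """

    #: prefix-token ids that open a new segment (vocabulary layout order:
    #: [pad] [cls] [mask] [tra] [trb] [peptide] [mhc])
    SEGMENT_MARKERS = (3, 4, 5, 6)
    N_SEGMENTS = 5  # leading [cls] + four components

    def __init__(self, vocab_size: int, d_model: int, n_layers: int,
                 n_heads: int, rel_window: int, dropout: float,
                 rng: np.random.Generator, dtype=np.float32):
        self.embed = _init(rng, (vocab_size, d_model), dtype)
        self.segment_embed = _init(rng, (self.N_SEGMENTS, d_model), dtype)
        self.layers = [EncoderLayer(d_model, n_heads, rel_window, dropout, rng, dtype)
                       for _ in range(n_layers)]
        self.ln_final = LayerNorm(d_model, dtype)
        self.drop = Dropout(dropout)

    def segment_ids(self, token_ids: np.ndarray) -> np.ndarray:
        seg = np.zeros(token_ids.shape, dtype=np.int64)
        for marker in self.SEGMENT_MARKERS:
            seg += np.cumsum(token_ids == marker, axis=-1)
        return np.minimum(seg, self.N_SEGMENTS - 1)

    def __call__(self, token_ids: np.ndarray, valid: np.ndarray | None = None,
                 rng: np.random.Generator | None = None) -> Tensor:
        x = self.embed.embedding(token_ids) + self.segment_embed.embedding(
            self.segment_ids(token_ids))
        x = self.drop(x, rng)
        for layer in self.layers:
            x = layer(x, valid, rng)
        return self.ln_final(x)


class MlmHead(Module):
    """Predicts the masked residue class (20-way; specials are never targets)."""

    def __init__(self, d_model: int, n_residues: int, rng, dtype):
        self.dense = Linear(d_model, d_model, rng, dtype)
        self.ln = LayerNorm(d_model, dtype)
        # near-zero output projection: a fresh model starts (almost) uniform
        # over the 20 residues, i.e. at ln(20) loss per masked position
        self.out = Linear(d_model, n_residues, rng, dtype, std=0.01)

    def __call__(self, states: Tensor) -> Tensor:
        return self.out(self.ln(self.dense(states).relu()))


class ClassifierHead(Module):
    """Single-logit head on the pooled sequence state, optionally through
    one hidden relu layer."""

    def __init__(self, d_in: int, rng, dtype, hidden: int = 0):
        self.dense = Linear(d_in, hidden, rng, dtype) if hidden else None
        self.out = Linear(hidden or d_in, 1, rng, dtype)

    def __call__(self, pooled: Tensor) -> Tensor:
        if self.dense is not None:
            pooled = self.dense(pooled).relu()
        return self.out(pooled).reshape(pooled.shape[0])
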