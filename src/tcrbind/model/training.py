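"""Masked-LM pretraining, binary finetuning and prediction.

Pretraining masks a fraction of residue tokens per sequence (special and
prefix tokens are never masked) with the usual 80/10/10 replacement split —
80% become [mask], 10% a random residue, 10% stay — and minimises
cross-entropy at the selected positions only.  At a fresh initialization the
expected loss is ln(20) per masked position (uniform over amino acids).

Finetuning pools the per-token states (by default the concatenation of the
mean and the feature-wise maximum over valid tokens) into a single-logit
head and minimises binary cross-entropy over binder/nonbinder labels; the
encoder can start from pretrained weights or from random initialization
(recorded in metadata).
All randomness flows from the config seed, so a fixed seed and config give
identical loss traces.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autograd import Adam, Tensor, bce_with_logits, softmax_cross_entropy
from .layers import ClassifierHead, Encoder, MlmHead
from .vocab import Vocabulary


@dataclass
class ModelConfig:
    """Tiny-by-default encoder definition; every field lands in run metadata."""

    n_layers: int = 2
    n_heads: int = 2
    d_model: int = 32
    rel_window: int = 8
    max_len: int = 192
    dropout: float = 0.1
    mask_rate: float = 0.15
    lr: float = 3e-3
    batch_size: int = 32
    epochs: int = 5
    seed: int = 0
    pooling: str = "meanmax"  # "mean", "max", "meanmax" (concat) or "cls"
    head_hidden: int = 64     # hidden width of the classifier head (0 = linear)
    lr_decay: float = 0.3     # lr multiplier applied at 70% of the epochs (1.0 = constant)
    dtype: str = "float32"

    def __post_init__(self):
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


def pad_batch(seqs: list[list[int]], pad_id: int):
    """Pad to the longest sequence in the batch; returns (ids, valid mask)."""
    length = max(len(s) for s in seqs)
    ids = np.full((len(seqs), length), pad_id, dtype=np.int64)
    valid = np.zeros((len(seqs), length), dtype=bool)
    for i, s in enumerate(seqs):
        ids[i, : len(s)] = s
        valid[i, : len(s)] = True
    return ids, valid


from .autograd import Tensor as _Tensor


def pool_states(states, valid: np.ndarray, mode: str):
    """Sequence-level state from per-token states.

    ``mean``: average over valid tokens; ``max``: feature-wise maximum over
    valid tokens (existence evidence survives undiluted); ``meanmax``: the
    two concatenated; ``cls``: the [cls] token state.
    """
    if mode == "cls":
        return states[:, 0, :]
    dtype = states.data.dtype
    if mode in ("mean", "meanmax"):
        weights = (valid / valid.sum(axis=1, keepdims=True)).astype(dtype)
        mean = (states * weights[:, :, None]).sum(axis=1)
        if mode == "mean":
            return mean
    if mode in ("max", "meanmax"):
        neg = np.where(valid, 0.0, -1e9).astype(dtype)
        mx = (states + neg[:, :, None]).amax(axis=1)
        if mode == "max":
            return mx
    if mode == "meanmax":
        return _Tensor.concat([mean, mx], axis=-1)
    raise ValueError(f"unknown pooling mode {mode!r}")


def build_encoder(cfg: ModelConfig, vocab: Vocabulary,
                  rng: np.random.Generator | None = None) -> Encoder:
    rng = rng or np.random.default_rng(cfg.seed)
    return Encoder(vocab_size=len(vocab), d_model=cfg.d_model,
                   n_layers=cfg.n_layers, n_heads=cfg.n_heads,
                   rel_window=cfg.rel_window, dropout=cfg.dropout,
                   rng=rng, dtype=cfg.np_dtype)


def build_head(cfg: ModelConfig, rng: np.random.Generator) -> ClassifierHead:
    d_in = cfg.d_model * (2 if cfg.pooling == "meanmax" else 1)
    return ClassifierHead(d_in, rng, cfg.np_dtype, hidden=cfg.head_hidden)


def _mask_tokens(ids: np.ndarray, valid: np.ndarray, vocab: Vocabulary,
                 mask_rate: float, rng: np.random.Generator):
    """BERT-style masking of residue tokens.  Returns (masked ids, targets)
    where targets hold the 0..19 residue class at selected positions and -1
    elsewhere.  At least one position per sequence is always selected."""
    ids = ids.copy()
    maskable = valid & (ids >= vocab.residue_offset)
    selected = maskable & (rng.random(ids.shape) < mask_rate)
    for i in range(ids.shape[0]):
        if not selected[i].any() and maskable[i].any():
            pos = rng.choice(np.flatnonzero(maskable[i]))
            selected[i, pos] = True
    targets = np.where(selected, ids - vocab.residue_offset, -1)
    action = rng.random(ids.shape)
    to_mask = selected & (action < 0.8)
    to_random = selected & (action >= 0.8) & (action < 0.9)
    ids[to_mask] = vocab.mask_id
    n_rand = int(to_random.sum())
    if n_rand:
        ids[to_random] = vocab.residue_offset + rng.integers(vocab.n_residues, size=n_rand)
    return ids, targets


def mlm_batch_loss(encoder: Encoder, head: MlmHead, ids, valid, targets,
                   rng=None) -> Tensor:
    states = encoder(ids, valid, rng)
    logits = head(states)
    flat = logits.reshape(ids.shape[0] * ids.shape[1], logits.shape[-1])
    return softmax_cross_entropy(flat, targets.reshape(-1), ignore_index=-1)


def pretrain_mlm(corpus: list[list[int]], cfg: ModelConfig,
                 vocab: Vocabulary | None = None):
    """Train an encoder on masked-residue prediction.

    Returns ``(encoder, epoch_losses)``; ``epoch_losses[e]`` is the mean
    batch loss of epoch ``e``.
    """
    vocab = vocab or Vocabulary.default()
    if not corpus:
        raise ValueError("pretraining corpus is empty")
    if len(corpus) < cfg.batch_size:
        raise ValueError(f"corpus ({len(corpus)} sequences) shorter than one "
                         f"batch ({cfg.batch_size}); nothing to learn from")
    if not 0.0 < cfg.mask_rate < 1.0:
        raise ValueError("mask rate must be in (0, 1): nothing to learn otherwise")

    rng = np.random.default_rng(cfg.seed)
    encoder = build_encoder(cfg, vocab, rng)
    head = MlmHead(cfg.d_model, vocab.n_residues, rng, cfg.np_dtype)
    opt = Adam(encoder.parameters() + head.parameters(), lr=cfg.lr)

    losses = []
    order = np.arange(len(corpus))
    for epoch in range(cfg.epochs):
        if epoch == int(0.7 * cfg.epochs) and cfg.lr_decay != 1.0:
            opt.lr *= cfg.lr_decay
        rng.shuffle(order)
        batch_losses = []
        for start in range(0, len(order) - cfg.batch_size + 1, cfg.batch_size):
            batch = [corpus[i] for i in order[start:start + cfg.batch_size]]
            ids, valid = pad_batch(batch, vocab.pad_id)
            ids, targets = _mask_tokens(ids, valid, vocab, cfg.mask_rate, rng)
            loss = mlm_batch_loss(encoder, head, ids, valid, targets,
                                  rng if cfg.dropout > 0 else None)
            opt.zero_grad()
            loss.backward()
            opt.step()
            batch_losses.append(float(loss.data))
        losses.append(float(np.mean(batch_losses)))
    return encoder, losses


@dataclass
class Classifier:
    """Finetuned binding classifier: encoder + pooled-state logistic head."""

    encoder: Encoder
    head: ClassifierHead
    config: ModelConfig
    vocab: Vocabulary
    metadata: dict = field(default_factory=dict)

    def predict(self, token_lists: list[list[int]],
                batch_size: int | None = None) -> np.ndarray:
        """Scores in [0, 1], order-aligned with the input records."""
        batch_size = batch_size or self.config.batch_size
        out = np.empty(len(token_lists))
        for start in range(0, len(token_lists), batch_size):
            batch = token_lists[start:start + batch_size]
            ids, valid = pad_batch(batch, self.vocab.pad_id)
            states = self.encoder(ids, valid, rng=None)
            logits = self.head(pool_states(states, valid, self.config.pooling)).data
            # float64 sigmoid: confident logits keep distinct ranks instead
            # of all saturating to exactly 0.0/1.0
            out[start:start + len(batch)] = 1.0 / (1.0 + np.exp(-logits.astype(np.float64)))
        return out

    def save(self, directory) -> None:
        save_classifier(self, directory)

    @classmethod
    def load(cls, directory) -> "Classifier":
        return load_classifier(directory)


def finetune(token_lists: list[list[int]], labels, cfg: ModelConfig,
             encoder: Encoder | None = None,
             vocab: Vocabulary | None = None):
    """Train a binary binding classifier.

    Returns ``(classifier, epoch_losses)``.  ``encoder=None`` trains from
    random initialization; the choice is recorded in classifier metadata.
    """
    vocab = vocab or Vocabulary.default()
    labels = np.asarray(labels, dtype=np.float64)
    if len(set(labels.tolist())) < 2:
        raise ValueError("finetuning requires both classes in the training set")
    rng = np.random.default_rng(cfg.seed)
    pretrained = encoder is not None
    if encoder is None:
        encoder = build_encoder(cfg, vocab, rng)
    head = build_head(cfg, rng)
    opt = Adam(encoder.parameters() + head.parameters(), lr=cfg.lr)

    losses = []
    order = np.arange(len(token_lists))
    for epoch in range(cfg.epochs):
        if epoch == int(0.7 * cfg.epochs) and cfg.lr_decay != 1.0:
            opt.lr *= cfg.lr_decay
        rng.shuffle(order)
        batch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            if len(idx) < 2:
                continue
            ids, valid = pad_batch([token_lists[i] for i in idx], vocab.pad_id)
            states = encoder(ids, valid, rng if cfg.dropout > 0 else None)
            logits = head(pool_states(states, valid, cfg.pooling))
            loss = bce_with_logits(logits, labels[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            batch_losses.append(float(loss.data))
        losses.append(float(np.mean(batch_losses)))
    clf = Classifier(encoder=encoder, head=head, config=cfg, vocab=vocab,
                     metadata={"pretrained": pretrained})
    return clf, losses


# -- persistence: directory with JSON manifest + npz weights ----------------

def _param_list(clf: Classifier):
    return clf.encoder.parameters() + clf.head.parameters()


def save_classifier(clf: Classifier, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    clf.vocab.save(directory / "vocab.json")
    manifest = {"config": clf.config.to_dict(), "metadata": clf.metadata,
                "format": "tcrbind-classifier-v1"}
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    arrays = {f"p{i}": p.data for i, p in enumerate(_param_list(clf))}
    np.savez(directory / "weights.npz", **arrays)


def load_classifier(directory) -> Classifier:
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    cfg = ModelConfig.from_dict(manifest["config"])
    vocab = Vocabulary.load(directory / "vocab.json")
    rng = np.random.default_rng(cfg.seed)
    encoder = build_encoder(cfg, vocab, rng)
    head = build_head(cfg, rng)
    clf = Classifier(encoder=encoder, head=head, config=cfg, vocab=vocab,
                     metadata=manifest["metadata"])
    weights = np.load(directory / "weights.npz")
    params = _param_list(clf)
    if len(weights.files) != len(params):
        raise ValueError("weight file does not match model architecture")
    for i, p in enumerate(params):
        p.data = weights[f"p{i}"].astype(cfg.np_dtype)
    return clf


def grid_search(train_fn, param_grid: dict[str, list]):
    """Plumbing hook for hyperparameter sweeps: calls ``train_fn(**combo)``
    for every combination in the cartesian grid and returns
    ``(best_combo, best_score, all_results)`` where ``train_fn`` returns a
    score to maximise."""
    import itertools

    keys = list(param_grid)
    results = []
    for values in itertools.product(*(param_grid[k] for k in keys)):
        combo = dict(zip(keys, values))
        results.append((combo, train_fn(**combo)))
    best_combo, best_score = max(results, key=lambda t: t[1])
    return best_combo, best_score, results
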