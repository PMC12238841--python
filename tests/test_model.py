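"""Tokenization, disentangled attention, masked-LM pretraining and the
binding classifier."""

import dataclasses

import numpy as np
import pytest

from tcrbind.model import (
    ModelConfig,
    Vocabulary,
    build_encoder,
    finetune,
    pretrain_mlm,
    tokenize,
    tokenize_pair,
)
from tcrbind.model.autograd import Tensor
from tcrbind.model.layers import DisentangledSelfAttention
from tcrbind.model.training import (
    _mask_tokens,
    load_classifier,
    mlm_batch_loss,
    pad_batch,
    save_classifier,
)
from tcrbind.model.layers import MlmHead

VOCAB = Vocabulary.default()


def tiny_cfg(**kw):
    base = dict(n_layers=2, n_heads=2, d_model=16, rel_window=4, max_len=64,
                dropout=0.0, batch_size=8, epochs=2, seed=0)
    base.update(kw)
    return ModelConfig(**base)


def random_corpus(rng, n, length=(20, 30)):
    aa = "ACDEFGHIKLMNPQRSTVWY"
    out = []
    for _ in range(n):
        alpha = "".join(rng.choice(list(aa), rng.integers(*length)))
        beta = "".join(rng.choice(list(aa), rng.integers(*length)))
        out.append(tokenize_pair(alpha, beta, VOCAB))
    return out


class TestTokenize:
    def test_toy_layout(self):
        ids = tokenize("CAV", "CAS", "AAA", "WW", VOCAB)
        expect = [VOCAB.id("[cls]"), VOCAB.id("[tra]")]
        expect += [VOCAB.residue_id(c) for c in "CAV"]
        expect += [VOCAB.id("[trb]")] + [VOCAB.residue_id(c) for c in "CAS"]
        expect += [VOCAB.id("[peptide]")] + [VOCAB.residue_id(c) for c in "AAA"]
        expect += [VOCAB.id("[mhc]")] + [VOCAB.residue_id(c) for c in "WW"]
        assert ids == expect
        # 5 delimiter/special tokens + 3 + 3 + 3 + 2 residues
        assert len(ids) == 16

    def test_token_count_identity(self, rng):
        aa = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(10):
            parts = ["".join(rng.choice(list(aa), rng.integers(3, 20)))
                     for _ in range(4)]
            ids = tokenize(*parts, VOCAB)
            assert len(ids) == 5 + sum(len(p) for p in parts)

    def test_missing_component_errors(self):
        with pytest.raises(ValueError, match="missing alpha"):
            tokenize("", "CAS", "AAA", "WW", VOCAB)

    def test_unknown_residue_errors(self):
        with pytest.raises(ValueError, match="outside"):
            tokenize("CAX", "CAS", "AAA", "WW", VOCAB)

    def test_truncation_protects_peptide_and_pseudo(self):
        ids = tokenize("A" * 50, "C" * 50, "DDDDDDDD", "E" * 34, VOCAB, max_len=60)
        assert len(ids) == 60
        residues = [VOCAB.tokens[i] for i in ids]
        assert residues.count("D") == 8       # full peptide retained
        assert residues.count("E") == 34      # full pseudosequence retained

    def test_truncation_trims_chain_starts(self):
        # chains are trimmed from the start, keeping the CDR3-bearing end
        alpha = "M" * 30 + "CAVRF"
        beta = "K" * 30 + "CASSF"
        ids = tokenize(alpha, beta, "DDDDDDDD", "E" * 34, VOCAB, max_len=80)
        residues = "".join(VOCAB.tokens[i] if len(VOCAB.tokens[i]) == 1 else "|"
                           for i in ids)
        assert "CAVRF" in residues and "CASSF" in residues


class TestDisentangledAttention:
    def _inputs(self, rng, batch=2, length=6, d=8):
        return Tensor(rng.normal(size=(batch, length, d)))

    def test_zeroed_positions_match_standard_attention(self, rng):
        """With the relative-position table zeroed, scores must equal plain
        scaled dot-product attention (independent implementation)."""
        d, heads = 8, 2
        attn = DisentangledSelfAttention(d, heads, rel_window=3, dropout=0.0,
                                         rng=rng, dtype=np.float64)
        attn.rel_emb.data[:] = 0.0
        x = self._inputs(rng, length=4, d=d)
        got = attn.attention_scores(x).data

        # independent standard attention oracle
        q = (x.data @ attn.wq.w.data + attn.wq.b.data)
        k = (x.data @ attn.wk.w.data + attn.wk.b.data)
        dh = d // heads
        q = q.reshape(2, 4, heads, dh).swapaxes(1, 2)
        k = k.reshape(2, 4, heads, dh).swapaxes(1, 2)
        scores = q @ k.swapaxes(-1, -2) / np.sqrt(3 * dh)
        e = np.exp(scores - scores.max(axis=-1, keepdims=True))
        expect = e / e.sum(axis=-1, keepdims=True)
        assert np.abs(got - expect).max() < 1e-6

    def test_softmax_rows_sum_to_one(self, rng):
        attn = DisentangledSelfAttention(8, 2, rel_window=3, dropout=0.0,
                                         rng=rng, dtype=np.float64)
        rows = attn.attention_scores(self._inputs(rng)).data.sum(axis=-1)
        assert np.allclose(rows, 1.0, atol=1e-9)

    def test_delta_table_matches_brute_force(self, rng):
        k = 3
        attn = DisentangledSelfAttention(8, 2, rel_window=k, dropout=0.0,
                                         rng=rng, dtype=np.float64)
        idx = attn._delta_index(7, 7)
        for i in range(7):
            for j in range(7):
                assert idx[i, j] == min(max(i - j, -k), k) + k
        # delta depends only on i-j, so a global shift leaves it unchanged
        assert np.array_equal(idx[1:, 1:], idx[:-1, :-1])

    def test_invalid_window_errors(self, rng):
        with pytest.raises(ValueError, match="window"):
            DisentangledSelfAttention(8, 2, rel_window=0, dropout=0.0,
                                      rng=rng, dtype=np.float64)

    def test_padding_does_not_change_valid_scores(self, rng):
        cfg = tiny_cfg()
        enc = build_encoder(cfg, VOCAB)
        seq = random_corpus(np.random.default_rng(0), 1)[0]
        ids1, valid1 = pad_batch([seq], VOCAB.pad_id)
        ids2, valid2 = pad_batch([seq, seq + seq[:10]], VOCAB.pad_id)
        out1 = enc(ids1, valid1).data[0]
        out2 = enc(ids2, valid2).data[0][: len(seq)]
        assert np.abs(out1 - out2[: len(seq)]).max() < 1e-5


class TestMasking:
    def test_specials_never_masked(self, rng):
        corpus = random_corpus(rng, 16)
        ids, valid = pad_batch(corpus, VOCAB.pad_id)
        for _ in range(10):
            masked, targets = _mask_tokens(ids, valid, VOCAB, 0.3, rng)
            special_positions = ids < VOCAB.residue_offset
            assert (targets[special_positions] == -1).all()
            # prefix/special tokens are left intact
            assert (masked[special_positions] == ids[special_positions]).all()

    def test_at_least_one_position_selected(self, rng):
        corpus = random_corpus(rng, 8)
        ids, valid = pad_batch(corpus, VOCAB.pad_id)
        masked, targets = _mask_tokens(ids, valid, VOCAB, 0.01, rng)
        assert ((targets != -1).sum(axis=1) >= 1).all()


class TestPretraining:
    def test_initial_loss_near_log20(self, rng):
        """A fresh model is uniform over the 20 residues, so the masked-LM
        loss starts at ln(20) per masked position (within 10%)."""
        cfg = tiny_cfg()
        enc = build_encoder(cfg, VOCAB)
        head = MlmHead(cfg.d_model, VOCAB.n_residues, np.random.default_rng(1),
                       cfg.np_dtype)
        corpus = random_corpus(rng, 32)
        ids, valid = pad_batch(corpus, VOCAB.pad_id)
        ids_m, targets = _mask_tokens(ids, valid, VOCAB, cfg.mask_rate, rng)
        loss = float(mlm_batch_loss(enc, head, ids_m, valid, targets).data)
        assert abs(loss - np.log(20)) / np.log(20) < 0.10

    def test_loss_decreases_over_training(self, rng):
        cfg = tiny_cfg(epochs=4, lr=3e-3)
        corpus = random_corpus(rng, 48)
        _, losses = pretrain_mlm(corpus, cfg, VOCAB)
        assert losses[-1] < losses[0]

    def test_zero_mask_rate_errors(self, rng):
        with pytest.raises(ValueError, match="mask rate"):
            pretrain_mlm(random_corpus(rng, 16), tiny_cfg(mask_rate=0.0), VOCAB)

    def test_corpus_shorter_than_batch_errors(self, rng):
        with pytest.raises(ValueError, match="batch"):
            pretrain_mlm(random_corpus(rng, 4), tiny_cfg(batch_size=8), VOCAB)

    def test_seeded_loss_trace_reproducible(self, rng):
        corpus = random_corpus(rng, 24)
        _, a = pretrain_mlm(corpus, tiny_cfg(epochs=2), VOCAB)
        _, b = pretrain_mlm(corpus, tiny_cfg(epochs=2), VOCAB)
        assert a == b


def labelled_toy(rng, n=40):
    """Binders carry a planted 4-mer in the beta segment; nonbinders don't."""
    aa = "ACDEFGHIKLMNPQRSTVWY"
    tokens, labels = [], []
    for i in range(n):
        label = i % 2
        beta = "".join(rng.choice(list(aa), 12))
        if label:
            beta = beta[:4] + "WWWW" + beta[8:]
        alpha = "".join(rng.choice(list(aa), 12))
        tokens.append(tokenize(alpha, beta, "ACDEFGHIK", "Y" * 10, VOCAB))
        labels.append(label)
    return tokens, labels


class TestFinetune:
    def test_single_class_errors(self, rng):
        tokens, _ = labelled_toy(rng)
        with pytest.raises(ValueError, match="both classes"):
            finetune(tokens, [1] * len(tokens), tiny_cfg(), encoder=None)

    def test_learns_separable_toy_signal(self, rng):
        from tcrbind.evalstats import auc

        tokens, labels = labelled_toy(rng, n=60)
        cfg = tiny_cfg(epochs=30, lr=3e-3)
        clf, losses = finetune(tokens[:40], labels[:40], cfg)
        scores = clf.predict(tokens[40:])
        assert losses[-1] < losses[0]
        assert auc(scores, labels[40:]) > 0.8

    def test_metadata_records_pretraining_flag(self, rng):
        tokens, labels = labelled_toy(rng)
        clf, _ = finetune(tokens, labels, tiny_cfg(epochs=1))
        assert clf.metadata["pretrained"] is False


class TestPredict:
    @pytest.fixture(scope="class")
    def trained(self):
        rng = np.random.default_rng(7)
        tokens, labels = labelled_toy(rng)
        clf, _ = finetune(tokens, labels, tiny_cfg(epochs=2))
        return clf, tokens

    def test_scores_in_unit_interval(self, trained):
        clf, tokens = trained
        scores = clf.predict(tokens)
        assert ((scores >= 0) & (scores <= 1)).all()

    def test_batched_equals_single(self, trained):
        clf, tokens = trained
        batched = clf.predict(tokens[:16], batch_size=16)
        single = np.array([clf.predict([t], batch_size=1)[0] for t in tokens[:16]])
        assert np.abs(batched - single).max() < 1e-6

    def test_duplicate_records_get_identical_scores(self, trained):
        clf, tokens = trained
        scores = clf.predict([tokens[0], tokens[1], tokens[0]])
        assert scores[0] == scores[2]

    def test_save_load_round_trip(self, trained, tmp_path):
        clf, tokens = trained
        save_classifier(clf, tmp_path / "clf")
        back = load_classifier(tmp_path / "clf")
        assert np.allclose(clf.predict(tokens[:8]), back.predict(tokens[:8]),
                           atol=1e-7)


class TestDeterminism:
    def test_same_seed_same_losses(self, rng):
        tokens, labels = labelled_toy(rng)
        _, a = finetune(tokens, labels, tiny_cfg(epochs=2))
        _, b = finetune(tokens, labels, tiny_cfg(epochs=2))
        assert a == b
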