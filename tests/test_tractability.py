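"""Train/test relationship features and their correlation with AUC."""

import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from tcrbind.tractability import (
    cdr3_distance,
    correlate,
    fold_features,
    peptide_blosum_score,
)

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def dp_align_oracle(a: str, b: str, gap: float = -4.0) -> float:
    """Brute-force global-alignment DP with a linear gap penalty."""
    n, k = len(a), len(b)
    d = np.full((n + 1, k + 1), -np.inf)
    d[0, 0] = 0.0
    for i in range(n + 1):
        for j in range(k + 1):
            if i > 0:
                d[i, j] = max(d[i, j], d[i - 1, j] + gap)
            if j > 0:
                d[i, j] = max(d[i, j], d[i, j - 1] + gap)
            if i > 0 and j > 0:
                d[i, j] = max(d[i, j], d[i - 1, j - 1] + BLOSUM62[a[i - 1], b[j - 1]])
    return float(d[n, k])


class TestCdr3Distance:
    def test_identity_is_zero(self, rng):
        aa = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(20):
            cdr3 = "C" + "".join(rng.choice(list(aa), rng.integers(4, 12))) + "F"
            assert cdr3_distance(cdr3, cdr3) == 0.0

    def test_single_substitution_hand_computed(self):
        # cores SLGQ / SLGE differ at Q vs E; blosum62(Q,E)=2 so the
        # per-position cost is min(4, 4-2)=2, weighted by 3 -> 6
        assert cdr3_distance("CASSLGQYF", "CASSLGEYF") == pytest.approx(6.0)

    def test_gap_against_residue_costs_twelve(self):
        # cores SLGQ vs SLWGQ: centre-padding aligns SL-GQ against SLWGQ,
        # leaving a single gap-vs-residue column: 3 * 4 = 12
        assert cdr3_distance("CASSLGQYF", "CASSLWGQYF") == pytest.approx(12.0)

    def test_symmetry_and_nonnegativity(self, rng):
        aa = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(100):
            x = "C" + "".join(rng.choice(list(aa), rng.integers(4, 12))) + "F"
            y = "C" + "".join(rng.choice(list(aa), rng.integers(4, 12))) + "F"
            d1, d2 = cdr3_distance(x, y), cdr3_distance(y, x)
            assert d1 == d2 >= 0.0

    def test_too_short_cdr3_errors(self):
        with pytest.raises(ValueError, match="too short"):
            cdr3_distance("CASSF", "CASSLGQYF")


class TestPeptideBlosumScore:
    def test_self_score_is_diagonal_sum(self):
        assert peptide_blosum_score("AAA", "AAA") == pytest.approx(12.0)  # 3 x 4

    def test_one_gap_hand_computed(self):
        assert peptide_blosum_score("AAAA", "AAA") == pytest.approx(8.0)  # 12 - 4

    def test_self_is_optimal(self, rng):
        aa = "ACDEFGHIKLMNPQRSTVWY"
        p = "".join(rng.choice(list(aa), 9))
        for _ in range(20):
            q = "".join(rng.choice(list(aa), rng.integers(8, 13)))
            assert peptide_blosum_score(p, p) >= peptide_blosum_score(p, q)

    def test_matches_dp_oracle_on_short_pairs(self, rng):
        alphabet = list("ACDE")
        for _ in range(150):
            a = "".join(rng.choice(alphabet, rng.integers(1, 7)))
            b = "".join(rng.choice(alphabet, rng.integers(1, 7)))
            assert peptide_blosum_score(a, b) == pytest.approx(dp_align_oracle(a, b))

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            peptide_blosum_score("", "AAA")


class TestFoldFeatures:
    def _fold_inputs(self, record_factory):
        train = [record_factory(beta_cdr3="CASSLGQYF", peptide="AAAAAAAAA",
                                hla="HLA-A*02:01"),
                 record_factory(beta_cdr3="CASSLGEYF", peptide="CCCCCCCCC",
                                hla="HLA-A*02:01")]
        test = [record_factory(beta_cdr3="CASSLGQYF", peptide="DDDDDDDDD",
                               hla="HLA-A*02:01")]
        return train, test

    def test_single_test_record_median_is_its_min(self, record_factory):
        train, test = self._fold_inputs(record_factory)
        feats = fold_features(None, train, test)
        assert feats.cdr3b_similarity == 0.0  # exact CDR3beta match in train

    def test_hla_log_count(self, record_factory):
        train, test = self._fold_inputs(record_factory)
        feats = fold_features(None, train, test)
        assert feats.hla_log_count == pytest.approx(math.log(1 + 2))

    def test_absent_allele_gives_zero(self, record_factory):
        train, test = self._fold_inputs(record_factory)
        test = [record_factory(beta_cdr3="CASSLGQYF", peptide="DDDDDDDDD",
                               hla="HLA-B*07:02")]
        assert fold_features(None, train, test).hla_log_count == 0.0

    def test_peptide_distance_below_self_score(self, record_factory):
        # by holdout construction the held-out peptide is absent from training
        train, test = self._fold_inputs(record_factory)
        feats = fold_features(None, train, test)
        held_out = test[0].phla.peptide_aa
        assert feats.peptide_distance < peptide_blosum_score(held_out, held_out)


class TestCorrelate:
    def _table(self, values):
        import pandas as pd
        return pd.DataFrame({"peptide": [f"P{i}" for i in range(len(values))],
                             "feat": values})

    def test_identical_feature_is_perfectly_correlated(self):
        aucs = [0.5, 0.6, 0.7, 0.9]
        per_feature, matrix = correlate(self._table(aucs), aucs)
        assert per_feature["feat"]["r"] == pytest.approx(1.0)
        assert matrix.loc["auc", "feat"] == pytest.approx(1.0)

    def test_negated_feature(self):
        aucs = [0.5, 0.6, 0.7, 0.9]
        per_feature, _ = correlate(self._table([-a for a in aucs]), aucs)
        assert per_feature["feat"]["r"] == pytest.approx(-1.0)

    def test_four_point_closed_form(self):
        aucs = [0.4, 0.5, 0.6, 0.7]
        feat = [1.0, 3.0, 2.0, 4.0]
        x, y = np.asarray(aucs), np.asarray(feat)
        r_manual = (((x - x.mean()) * (y - y.mean())).sum()
                    / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        per_feature, _ = correlate(self._table(feat), aucs)
        assert per_feature["feat"]["r"] == pytest.approx(r_manual)

    def test_zero_variance_reported_missing(self):
        per_feature, _ = correlate(self._table([1.0, 1.0, 1.0, 1.0]),
                                   [0.4, 0.5, 0.6, 0.7])
        assert math.isnan(per_feature["feat"]["r"])

    def test_too_few_peptides_errors(self):
        with pytest.raises(ValueError):
            correlate(self._table([1.0, 2.0]), [0.4, 0.5])


class TestSimilarityTracksMotifSharing:
    def test_cross_epitope_distance_decreases_with_sharing(self):
        """As epitopes share more CDR3beta motifs, nearest cross-epitope
        CDR3beta distances shrink (in expectation over seeds)."""
        from tcrbind import synth

        from scipy.stats import spearmanr

        settings = (0.0, 0.25, 0.5, 0.75, 1.0)
        means = []
        for sharing in settings:
            vals = []
            for seed in range(10):
                cfg = synth.SynthConfig(n_epitopes=4, tcrs_per_epitope=8,
                                        cross_epitope_sharing=sharing, seed=seed)
                records, _ = synth.gen_binding_dataset(cfg)
                by_pep = {}
                for r in records:
                    by_pep.setdefault(r.phla.peptide_aa, []).append(r.beta.cdr3_aa)
                peps = list(by_pep)
                held = by_pep[peps[0]]
                rest = [c for p in peps[1:] for c in by_pep[p]]
                nn = [min(cdr3_distance(t, s) for s in rest) for t in held]
                vals.append(np.median(nn))
            means.append(np.mean(vals))
        rho, p = spearmanr(settings, means)
        assert rho < 0 and p < 0.05
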