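"""Curation rules: column mapping, inclusion/exclusion filters, HLA
imputation, merging and duplicate removal."""

import pytest

from tcrbind import standardize
from tcrbind.standardize import (
    FilterRules,
    apply_filters,
    complete_v_allele,
    impute_hla_allele,
    merge_and_dedup,
    read_binding_tsv,
    standardize_table,
)

AIRR_TSV = (
    "locus\tv_call\tj_call\tjunction_aa\tpeptide\tmhc\n"
    "TRB\tTRBV19*01\tTRBJ2-1*01\tCASSIRSSYEQYF\tNLVPMVATV\tHLA-A*02:01\n"
    "TRB\tTRBV9*01\tTRBJ1-2*01\tCASSVGQGYTF\tGILGFVFTL\tHLA-A*02:01\n"
    "TRA\tTRAV12-1*01\tTRAJ23*01\tCVVNDYKLSF\tGILGFVFTL\tHLA-A*02:01\n"
)


def _raw(peptide="NLVPMVATV", mhc="HLA-A*02:01", beta_cdr3="CASSIRSSYEQYF",
         **extra):
    raw = {"beta_v": "TRBV19*01", "beta_j": "TRBJ2-1*01", "beta_cdr3": beta_cdr3,
           "peptide": peptide, "hla_allele": mhc, "label": "binder", "source": "x"}
    raw.update(extra)
    return raw


class TestReadBindingTsv:
    def test_column_mapping_passthrough(self, tmp_path):
        path = tmp_path / "airr.tsv"
        path.write_text(AIRR_TSV)
        raws = read_binding_tsv(path, {"junction_aa": "cdr3_aa", "mhc": "hla_allele"})
        assert len(raws) == 3
        assert raws[0]["cdr3_aa"] == "CASSIRSSYEQYF"
        assert raws[0]["v_call"] == "TRBV19*01"  # unmapped column preserved

    def test_header_only_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("locus\tv_call\tj_call\tjunction_aa\n")
        assert read_binding_tsv(path, {"junction_aa": "cdr3_aa"}) == []

    def test_missing_mapped_column_is_hard_error(self, tmp_path):
        path = tmp_path / "airr.tsv"
        path.write_text(AIRR_TSV)
        with pytest.raises(ValueError, match="missing column.*epitope"):
            read_binding_tsv(path, {"epitope": "peptide"})


class TestApplyFilters:
    @pytest.mark.parametrize("raw, reason", [
        (_raw(peptide="NLVPMVA"), "peptide_length"),            # 7-mer: too short
        (_raw(peptide="NLVPMVATVNLVP"), "peptide_length"),      # 13-mer: too long
        (_raw(mhc="H-2Kb"), "non_human_mhc"),                   # mouse MHC
        (_raw(mhc="HLA-DRB1*01:01"), "class_ii_mhc"),           # class II code
        (_raw(mhc="HLA-DQB1*06:02"), "class_ii_mhc"),
        (_raw(beta_cdr3="CASSXEQYF"), "ambiguous_residue"),     # X in CDR3
        (_raw(peptide="NLVPMVaTV"), "ambiguous_residue"),       # lowercase residue
        (_raw(beta_cdr3=""), "missing_chain_fields"),
        (_raw(mhc="B*07:02"), "non_hla_class_i"),               # missing HLA- prefix
        ({"locus": "IGH", "v_call": "IGHV1", "j_call": "IGHJ1",
          "cdr3_aa": "CARDF", "peptide": "NLVPMVATV",
          "hla_allele": "HLA-A*02:01"}, "bad_locus"),
    ])
    def test_rejection_reasons(self, raw, reason):
        status, got = apply_filters(raw)
        assert (status, got) == ("reject", reason)

    def test_accept_and_idempotence(self):
        status, rec = apply_filters(_raw())
        assert status == "accept"
        # a record that passes, passes again unchanged
        again = {"beta_v": rec.beta.v_call, "beta_j": rec.beta.j_call,
                 "beta_cdr3": rec.beta.cdr3_aa, "peptide": rec.phla.peptide_aa,
                 "hla_allele": rec.phla.hla_allele, "label": rec.label,
                 "source": rec.source}
        status2, rec2 = apply_filters(again)
        assert status2 == "accept"
        assert rec2.dedup_key() == rec.dedup_key()

    def test_boundary_lengths_8_and_12_pass(self):
        for pep in ("NLVPMVAT", "NLVPMVATVNLV"):
            assert apply_filters(_raw(peptide=pep))[0] == "accept"

    def test_group_level_allele_is_imputed(self):
        rules = FilterRules(hla_freq_table={"HLA-A*02:01": 0.27, "HLA-A*02:06": 0.03})
        status, rec = apply_filters(_raw(mhc="HLA-A*02"), rules)
        assert status == "accept"
        assert rec.phla.hla_allele == "HLA-A*02:01"

    def test_report_conservation(self, rng):
        raws = [_raw() for _ in range(5)]
        raws += [_raw(peptide="SHORT"), _raw(mhc="H-2Kb"), _raw(beta_cdr3="CAXF")]
        records, report = standardize_table(raws)
        assert report.retained == len(records) == 5
        assert report.total == len(raws)


class TestVAlleleCompletion:
    def test_gene_only_gets_01(self):
        assert complete_v_allele("TRBV19") == "TRBV19*01"

    def test_allele_passthrough(self):
        assert complete_v_allele("TRBV19*02") == "TRBV19*02"


class TestImputeHla:
    TABLE = {"HLA-A*02:01": 0.27, "HLA-A*02:06": 0.03, "HLA-B*07:02": 0.09}

    def test_group_maps_to_most_frequent(self):
        assert impute_hla_allele("HLA-A*02", self.TABLE) == "HLA-A*02:01"

    def test_full_resolution_identity(self):
        assert impute_hla_allele("HLA-B*07:02", self.TABLE) == "HLA-B*07:02"

    def test_unresolvable_group_errors(self):
        with pytest.raises(ValueError, match="unresolvable"):
            impute_hla_allele("HLA-C*99", {})

    def test_frequency_tie_breaks_lexicographically(self):
        table = {"HLA-A*02:05": 0.1, "HLA-A*02:01": 0.1}
        assert impute_hla_allele("HLA-A*02", table) == "HLA-A*02:01"


class TestMergeAndDedup:
    def test_shared_record_counted_once(self, record_factory):
        a = [record_factory(), record_factory(beta_cdr3="CASSLGEYF")]
        b = [record_factory()]
        merged, report = merge_and_dedup([a, b])
        assert len(merged) == 2
        assert report.rejections["duplicate"] == 1

    def test_conflicting_labels_both_survive(self, record_factory):
        # dedup key includes the label: a binder and a nonbinder for the same
        # complex are different records (4-record fixture, keys by hand)
        recs = [record_factory(label="binder"),
                record_factory(label="nonbinder"),
                record_factory(label="binder"),           # duplicate of first
                record_factory(beta_cdr3="CASSLGEYF")]
        merged, _ = merge_and_dedup([recs])
        assert len(merged) == 3
        labels = {r.label for r in merged if r.beta.cdr3_aa == "CASSLGQYF"}
        assert labels == {"binder", "nonbinder"}

    def test_empty_input(self):
        merged, report = merge_and_dedup([[]])
        assert merged == [] and report.total == 0

    def test_idempotent(self, positives):
        once, _ = merge_and_dedup([positives])
        twice, _ = merge_and_dedup([once])
        assert [r.dedup_key() for r in once] == [r.dedup_key() for r in twice]

    def test_first_occurrence_wins_order_stable(self, record_factory):
        a = record_factory(source="first")
        b = record_factory(source="second")  # same dedup key, later source
        merged, _ = merge_and_dedup([[a], [b]])
        assert len(merged) == 1 and merged[0].source == "first"


class TestCoalesce:
    def test_single_chain_adopts_partner(self, record_factory):
        from tcrbind.records import BindingRecord, PeptideHla, TcrChain
        paired = record_factory()
        solo = BindingRecord(
            beta=paired.beta, phla=paired.phla, label="binder", source="other")
        merged, _ = merge_and_dedup([[paired, solo]], coalesce=True)
        assert len(merged) == 1
        assert merged[0].alpha is not None


class TestRoundTrip:
    def test_standard_tsv_round_trip(self, tmp_path, positives):
        path = tmp_path / "std.tsv"
        standardize.write_standard_tsv(positives, path)
        back = standardize.read_standard_tsv(path)
        assert [r.dedup_key() for r in back] == [r.dedup_key() for r in positives]

    def test_retained_records_satisfy_constraints(self, positives):
        records, _ = standardize_table(
            [{"beta_v": r.beta.v_call, "beta_j": r.beta.j_call,
              "beta_cdr3": r.beta.cdr3_aa, "peptide": r.phla.peptide_aa,
              "hla_allele": r.phla.hla_allele, "label": r.label}
             for r in positives])
        for r in records:
            assert 8 <= len(r.phla.peptide_aa) <= 12
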