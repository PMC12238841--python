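"""Standardization of heterogeneous binding-data tables.

Public binding databases describe TCR-peptide-HLA records in incompatible
dialects.  This module maps each source into a single standard record set and
applies the inclusion/exclusion rules used for curation:

* the TCR must have an alpha and/or beta chain with specified CDR3, V and J;
* the peptide must be 8-12 residues of standard amino acids;
* the MHC must be a human class I (HLA-A/B/C) label, imputed to two-field
  allele resolution when given only at group level;
* no ambiguous residues anywhere in peptide or CDR3.

Duplicates (same chains + peptide + allele + label) are removed after merging
all sources; contradictory binder/nonbinder pairs are both kept.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .records import (
    BindingRecord,
    FilterReport,
    PeptideHla,
    TcrChain,
    hla_resolution,
    is_standard_aa,
)

#: fixed column order of the standardized TSV
STANDARD_COLUMNS = [
    "alpha_v", "alpha_j", "alpha_cdr3",
    "beta_v", "beta_j", "beta_cdr3",
    "peptide", "hla_allele", "label", "source",
]

_CLASS_II_CODES = ("DRB", "DQ", "DP")
_NON_HUMAN_CODES = ("H-2", "H2-")

_LABEL_MAP = {
    "binder": "binder", "nonbinder": "nonbinder",
    "1": "binder", "0": "nonbinder",
    "true": "binder", "false": "nonbinder",
    "positive": "binder", "negative": "nonbinder",
}


@dataclass
class FilterRules:
    """Tunable bounds for :func:`apply_filters`."""

    min_peptide_len: int = 8
    max_peptide_len: int = 12
    hla_freq_table: Optional[dict] = None  # allele -> frequency, for group imputation
    default_v_allele: str = "*01"


def read_binding_tsv(path, column_map: dict) -> list[dict]:
    """Read a tab-separated source table and rename columns per ``column_map``
    (source name -> standard name).  Unmapped columns are preserved as
    provenance.  A mapped column absent from the header is a hard error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in column_map if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s) in {path}: {', '.join(missing)}")
    df = df.rename(columns=column_map)
    return df.to_dict(orient="records")


def complete_v_allele(call: str, default: str = "*01") -> str:
    """Complete a gene-level call lacking an allele suffix to the canonical
    first allele, e.g. ``TRBV19`` -> ``TRBV19*01``."""
    if call and "*" not in call:
        return call + default
    return call


def impute_hla_allele(label: str, freq_table: dict) -> str:
    """Resolve an HLA label to two-field allele resolution.

    Two-field labels pass through unchanged.  Group-level labels (e.g.
    ``HLA-A*02``) map to the most frequent allele of that group in
    ``freq_table`` (ties broken lexicographically).
    """
    res = hla_resolution(label)
    if res == "full":
        return label
    if res != "group":
        raise ValueError(f"label {label!r} is not an HLA-I allele or allele group")
    prefix = label + ":"
    candidates = [(freq, name) for name, freq in freq_table.items() if name.startswith(prefix)]
    if not candidates:
        raise ValueError(f"unresolvable allele group {label!r}")
    best_freq = max(f for f, _ in candidates)
    return min(name for freq, name in candidates if freq == best_freq)


def normalize_single_chain_raw(raw: dict) -> dict:
    """Fold a one-chain-per-row dialect (locus/v_call/j_call/cdr3_aa) into the
    paired ``alpha_*``/``beta_*`` key convention."""
    if "locus" not in raw:
        return raw
    out = dict(raw)
    locus = (raw.get("locus") or "").strip()
    pfx = {"TRA": "alpha_", "TRB": "beta_"}.get(locus)
    if pfx is None:
        # leave the invalid locus visible so apply_filters can reject it
        out["_bad_locus"] = locus
        return out
    out[pfx + "v"] = raw.get("v_call", "")
    out[pfx + "j"] = raw.get("j_call", "")
    out[pfx + "cdr3"] = raw.get("cdr3_aa", raw.get("junction_aa", ""))
    return out


def apply_filters(raw: dict, rules: FilterRules | None = None):
    """Validate one column-mapped raw record.

    Returns ``("accept", BindingRecord)`` or ``("reject", reason)``.  Rules
    fire in a fixed order and the first firing rule is the recorded reason.
    """
    rules = rules or FilterRules()
    raw = normalize_single_chain_raw(raw)

    if "_bad_locus" in raw:
        return ("reject", "bad_locus")

    # chains: at least one complete (cdr3 + v + j) chain must be present;
    # residue validity is a separate rule, so collect raw fields first
    chains = {}
    for locus, pfx in (("TRA", "alpha_"), ("TRB", "beta_")):
        v = (raw.get(pfx + "v") or "").strip()
        j = (raw.get(pfx + "j") or "").strip()
        cdr3 = (raw.get(pfx + "cdr3") or "").strip()
        if not (v or j or cdr3):
            continue
        if not (v and j and cdr3):
            return ("reject", "missing_chain_fields")
        chains[locus] = (complete_v_allele(v), complete_v_allele(j), cdr3)
    if not chains:
        return ("reject", "missing_chain_fields")

    peptide = (raw.get("peptide") or "").strip()
    if not (rules.min_peptide_len <= len(peptide) <= rules.max_peptide_len):
        return ("reject", "peptide_length")

    for seq in [peptide] + [c[2] for c in chains.values()]:
        if not is_standard_aa(seq):
            return ("reject", "ambiguous_residue")

    mhc = (raw.get("hla_allele") or raw.get("mhc") or "").strip()
    if any(code in mhc for code in _NON_HUMAN_CODES):
        return ("reject", "non_human_mhc")
    if any(code in mhc for code in _CLASS_II_CODES):
        return ("reject", "class_ii_mhc")
    if not mhc.startswith(("HLA-A", "HLA-B", "HLA-C")):
        return ("reject", "non_hla_class_i")
    if rules.hla_freq_table is not None and hla_resolution(mhc) != "full":
        try:
            mhc = impute_hla_allele(mhc, rules.hla_freq_table)
        except ValueError:
            return ("reject", "unresolvable_allele")
    elif hla_resolution(mhc) == "other":
        return ("reject", "unresolvable_allele")

    label = _LABEL_MAP.get((raw.get("label") or "binder").strip().lower())
    if label is None:
        return ("reject", "bad_label")

    try:
        alpha = TcrChain("TRA", *chains["TRA"]) if "TRA" in chains else None
        beta = TcrChain("TRB", *chains["TRB"]) if "TRB" in chains else None
    except ValueError:
        return ("reject", "bad_locus")  # v/j call inconsistent with locus
    rec = BindingRecord(
        alpha=alpha, beta=beta,
        phla=PeptideHla(peptide_aa=peptide, hla_allele=mhc),
        label=label, source=(raw.get("source") or "").strip(),
    )
    return ("accept", rec)


def standardize_table(raws: Iterable[dict], rules: FilterRules | None = None):
    """Apply :func:`apply_filters` to every raw record; returns
    ``(records, FilterReport)`` with conservation checked."""
    raws = list(raws)
    report = FilterReport()
    records = []
    for raw in raws:
        status, payload = apply_filters(raw, rules)
        if status == "accept":
            report.accept()
            records.append(payload)
        else:
            report.reject(payload)
    report.check(len(raws))
    return records, report


def coalesce_complementary(records: list[BindingRecord]) -> list[BindingRecord]:
    """Fill a record's missing chain from another source describing the same
    complex.  A single-chain record whose present chain, peptide, allele and
    label all match exactly one paired record adopts the partner chain; the
    subsequent dedup then collapses the two."""
    paired = [r for r in records if r.alpha is not None and r.beta is not None]
    by_beta: dict[tuple, list[BindingRecord]] = {}
    by_alpha: dict[tuple, list[BindingRecord]] = {}
    for r in paired:
        b = (r.beta.v_call, r.beta.j_call, r.beta.cdr3_aa) + r.phla_key() + (r.label,)
        a = (r.alpha.v_call, r.alpha.j_call, r.alpha.cdr3_aa) + r.phla_key() + (r.label,)
        by_beta.setdefault(b, []).append(r)
        by_alpha.setdefault(a, []).append(r)
    out = []
    for r in records:
        if r.alpha is None and r.beta is not None:
            key = (r.beta.v_call, r.beta.j_call, r.beta.cdr3_aa) + r.phla_key() + (r.label,)
            hits = by_beta.get(key, [])
            if len(hits) == 1:
                r = BindingRecord(alpha=hits[0].alpha, beta=r.beta, phla=r.phla,
                                  label=r.label, source=r.source)
        elif r.beta is None and r.alpha is not None:
            key = (r.alpha.v_call, r.alpha.j_call, r.alpha.cdr3_aa) + r.phla_key() + (r.label,)
            hits = by_alpha.get(key, [])
            if len(hits) == 1:
                r = BindingRecord(alpha=r.alpha, beta=hits[0].beta, phla=r.phla,
                                  label=r.label, source=r.source)
        out.append(r)
    return out


def merge_and_dedup(datasets: list[list[BindingRecord]], coalesce: bool = False):
    """Combine record lists into one set with exactly one record per dedup key
    (first occurrence wins, order stable).  Returns ``(records, FilterReport)``
    where rejections count the removed duplicates."""
    merged: list[BindingRecord] = [r for ds in datasets for r in ds]
    if coalesce:
        merged = coalesce_complementary(merged)
    seen = set()
    out = []
    report = FilterReport()
    for r in merged:
        key = r.dedup_key()
        if key in seen:
            report.reject("duplicate")
        else:
            seen.add(key)
            out.append(r)
            report.accept()
    report.check(len(merged))
    return out, report


def records_to_frame(records: list[BindingRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "alpha_v": r.alpha.v_call if r.alpha else "",
            "alpha_j": r.alpha.j_call if r.alpha else "",
            "alpha_cdr3": r.alpha.cdr3_aa if r.alpha else "",
            "beta_v": r.beta.v_call if r.beta else "",
            "beta_j": r.beta.j_call if r.beta else "",
            "beta_cdr3": r.beta.cdr3_aa if r.beta else "",
            "peptide": r.phla.peptide_aa,
            "hla_allele": r.phla.hla_allele,
            "label": r.label,
            "source": r.source,
        })
    return pd.DataFrame(rows, columns=STANDARD_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[BindingRecord]:
    records = []
    for row in df.itertuples(index=False):
        alpha = beta = None
        if row.alpha_cdr3:
            alpha = TcrChain("TRA", row.alpha_v, row.alpha_j, row.alpha_cdr3)
        if row.beta_cdr3:
            beta = TcrChain("TRB", row.beta_v, row.beta_j, row.beta_cdr3)
        records.append(BindingRecord(
            alpha=alpha, beta=beta,
            phla=PeptideHla(row.peptide, row.hla_allele),
            label=row.label, source=getattr(row, "source", "") or "",
        ))
    return records


def write_standard_tsv(records: list[BindingRecord], path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False,
                                     quoting=csv.QUOTE_NONE)


def read_standard_tsv(path) -> list[BindingRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return frame_to_records(df)
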