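"""Single-cell (10x-style) chain pairing and UMI-based binder calling.

Each cell barcode should carry exactly one productive alpha and one
productive beta chain; anything else (multiplets, double-alpha cells, empty
GEMs) is dropped.  Binding is called per (cell, peptide) from a UMI count
matrix with a designated negative-control column: a complex is a binder iff
its UMI count exceeds the same cell's negative-control count by more than
three standard deviations of the negative-control counts pooled across all
cells.  Only positive calls enter the labelled dataset — the nonbinder side
is simulated separately by mispairing.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import BindingRecord, PeptideHla, TcrChain


@dataclass
class PairingReport:
    kept: int = 0
    dropped: Counter = None

    def __post_init__(self):
        if self.dropped is None:
            self.dropped = Counter()


def read_cell_chain_tsv(path) -> pd.DataFrame:
    """AIRR-style TSV with a ``cell_id`` column plus locus/v_call/j_call/
    cdr3_aa and boolean ``productive`` / ``high_confidence`` flags."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("productive", "high_confidence"):
        if col in df.columns:
            df[col] = df[col].str.lower().isin(("true", "t", "1", "yes"))
    return df


def filter_productive(table: pd.DataFrame) -> pd.DataFrame:
    """Keep only productive, high-confidence rows (both flags required when
    the columns are present)."""
    mask = np.ones(len(table), dtype=bool)
    for col in ("productive", "high_confidence"):
        if col in table.columns:
            mask &= table[col].to_numpy(dtype=bool)
    return table[mask]


def select_paired_cells(table: pd.DataFrame):
    """Keep barcodes with exactly two distinct chain sequences, one TRA and
    one TRB.  Duplicate rows collapse to one distinct chain first.  Returns
    ``(pairs, PairingReport)`` with pairs mapping barcode -> (alpha, beta).
    """
    report = PairingReport()
    pairs: dict[str, tuple[TcrChain, TcrChain]] = {}
    for barcode, group in table.groupby("cell_id", sort=True):
        distinct = {(row.locus, row.v_call, row.j_call, row.cdr3_aa)
                    for row in group.itertuples(index=False)}
        if len(distinct) < 2:
            report.dropped["fewer_than_two_chains"] += 1
            continue
        if len(distinct) > 2:
            report.dropped["multiplet"] += 1
            continue
        loci = sorted(chain[0] for chain in distinct)
        if loci != ["TRA", "TRB"]:
            report.dropped["same_locus_pair"] += 1
            continue
        chains = {c[0]: TcrChain(locus=c[0], v_call=c[1], j_call=c[2], cdr3_aa=c[3])
                  for c in distinct}
        pairs[barcode] = (chains["TRA"], chains["TRB"])
        report.kept += 1
    return pairs, report


def read_umi_tsv(path, negctrl_col: str) -> pd.DataFrame:
    """UMI count matrix: rows = cell barcodes (first column), columns =
    peptide identities including the designated negative-control column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if negctrl_col not in df.columns:
        raise ValueError(f"negative-control column {negctrl_col!r} not in UMI table")
    return df


def call_binders(umi: pd.DataFrame, negctrl_col: str,
                 sd_mode: str = "sample") -> pd.DataFrame:
    """Binary binder flags per (cell, peptide).

    flag(cell, peptide) = count(cell, peptide) > count(cell, negctrl) + 3*s
    where ``s`` is the standard deviation of the negative-control column over
    all cells (sample, n-1 denominator, by default; ``sd_mode='population'``
    selects the n denominator).  Ties fall to nonbinder (strict inequality).
    The negative-control column itself is never flagged.
    """
    if negctrl_col not in umi.columns:
        raise ValueError(f"negative-control column {negctrl_col!r} not in UMI table")
    if (umi.to_numpy() < 0).any():
        raise ValueError("UMI counts must be non-negative")
    neg = umi[negctrl_col].to_numpy(dtype=float)
    if len(neg) < 2:
        raise ValueError("SD undefined: need at least two cells")
    ddof = 1 if sd_mode == "sample" else 0
    s = float(np.std(neg, ddof=ddof))
    peptide_cols = [c for c in umi.columns if c != negctrl_col]
    threshold = neg + 3.0 * s
    flags = umi[peptide_cols].to_numpy(dtype=float) > threshold[:, None]
    return pd.DataFrame(flags, index=umi.index, columns=peptide_cols)


def positives_only(flags: pd.DataFrame,
                   pairs: dict[str, tuple[TcrChain, TcrChain]],
                   peptide_map: dict[str, PeptideHla],
                   source: str = "10x") -> list[BindingRecord]:
    """One binder-labelled record per (kept cell, binder-flagged peptide);
    nonbinder flags are discarded, flags on dropped barcodes ignored."""
    records = []
    for barcode in flags.index:
        if barcode not in pairs:
            continue
        alpha, beta = pairs[barcode]
        for peptide_col in flags.columns:
            if flags.at[barcode, peptide_col]:
                records.append(BindingRecord(
                    alpha=alpha, beta=beta, phla=peptide_map[peptide_col],
                    label="binder", source=source,
                ))
    return records
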