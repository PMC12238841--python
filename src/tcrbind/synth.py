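"""Synthetic inputs for every pipeline stage.

Generates germline V/J references, unlabelled paired repertoires,
motif-planted labelled binding datasets, and 10x-style UMI tables, with
controllable signal strength, so the whole pipeline is testable without any
download.

The labelled generator emulates the statistical structure of curated binding
data: per-epitope clusters of TCRs (a binder's CDR3beta carries a short
motif linked to its epitope with a configurable probability), skewed HLA
usage, a realistic peptide length distribution over 8-12, and optionally a
single dominant epitope holding half of all positives (the situation that
motivates top-epitope downsampling).  By default each epitope's motif is the
peptide's own N-terminal k-mer, so similar peptides attract similar CDR3beta
motifs — the structure that makes some unseen peptides tractable.  A truth
sidecar records every assignment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .germline import GermlineDb, GermlineSegment
from .records import BindingRecord, PeptideHla, TcrChain

_AA = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_PEPTIDE_LEN_PROBS = {8: 0.05, 9: 0.50, 10: 0.25, 11: 0.15, 12: 0.05}
# skewed allele usage mirroring the dominance of a couple of common alleles
DEFAULT_HLA_FREQS = (0.40, 0.30, 0.18, 0.12)


@dataclass
class SynthConfig:
    n_v: int = 8                 # V genes per locus
    n_j: int = 4                 # J genes per locus
    n_epitopes: int = 8
    tcrs_per_epitope: int = 75
    motif_len: int = 4
    motif_strength: float = 1.0  # P(binder CDR3beta carries its epitope motif)
    n_hla: int = 4
    hla_freqs: tuple = DEFAULT_HLA_FREQS
    peptide_len_probs: dict = field(default_factory=lambda: dict(DEFAULT_PEPTIDE_LEN_PROBS))
    motif_mode: str = "peptide"  # "peptide": motif derived from peptide; "random"
    cross_epitope_sharing: float = 0.0  # P(epitope adopts the shared family motif)
    dominant_epitope: bool = False      # give epitope 0 half of all positives
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.motif_strength <= 1.0:
            raise ValueError("motif_strength must be in [0, 1]")
        if not 0.0 <= self.cross_epitope_sharing <= 1.0:
            raise ValueError("cross_epitope_sharing must be in [0, 1]")
        if abs(sum(self.hla_freqs[: self.n_hla]) - 1.0) > 1e-6:
            freqs = np.asarray(self.hla_freqs[: self.n_hla], dtype=float)
            self.hla_freqs = tuple(freqs / freqs.sum())
        if abs(sum(self.peptide_len_probs.values()) - 1.0) > 1e-6:
            raise ValueError("peptide length probabilities must sum to 1")


def _random_aa(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(_AA))[rng.integers(20, size=n)])


# -- germline ---------------------------------------------------------------

def gen_germline_db(cfg: SynthConfig, seed: int | None = None) -> GermlineDb:
    """Random V segments (80-100 aa, conserved Cys anchor at the end, CDR1/2
    spans annotated) and J segments (12-18 aa containing F-G-X-G with the
    anchor on the F), IMGT-style names with a *01 allele suffix."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    segments = []
    for locus in ("TRA", "TRB"):
        for i in range(cfg.n_v):
            length = int(rng.integers(80, 101))
            aa = _random_aa(rng, length - 1) + "C"
            segments.append(GermlineSegment(
                name=f"{locus}V{i + 1}*01", segment_type="V", aa=aa,
                anchor=length - 1, cdr1_span=(26, 33), cdr2_span=(49, 56),
            ))
        for i in range(cfg.n_j):
            length = int(rng.integers(12, 19))
            # conserved Phe sits 9-12 residues from the segment end, as in
            # real TRAJ/TRBJ genes (F-G-X-G + a short run to the end)
            tail = int(rng.integers(8, 12))
            anchor = length - 1 - tail
            aa = list(_random_aa(rng, length))
            aa[anchor] = "F"
            aa[anchor + 1] = "G"
            aa[anchor + 3] = "G"
            segments.append(GermlineSegment(
                name=f"{locus}J{i + 1}*01", segment_type="J", aa="".join(aa),
                anchor=anchor,
            ))
    return GermlineDb(segments)


# -- labelled binding data --------------------------------------------------

def _peptide_motif(peptide: str, k: int) -> str:
    # the epitope's CDR3beta motif is the peptide's N-terminal k-mer: a
    # simple, analyzable peptide-motif link (similar peptides, similar motifs)
    return peptide[:k]


def _random_cdr3(rng: np.random.Generator, motif: str | None) -> str:
    """Junction-inclusive CDR3 (C...F) with an optional planted motif in the
    core."""
    core_len = int(rng.integers(6, 13))
    core = list(_random_aa(rng, core_len))
    if motif is not None:
        if len(motif) > core_len:
            raise ValueError(f"motif {motif!r} longer than CDR3 core ({core_len})")
        start = int(rng.integers(0, core_len - len(motif) + 1))
        core[start: start + len(motif)] = list(motif)
    return "C" + "".join(core) + "F"


def _random_chain(rng: np.random.Generator, locus: str, cfg: SynthConfig,
                  motif: str | None = None) -> TcrChain:
    v = f"{locus}V{int(rng.integers(cfg.n_v)) + 1}*01"
    j = f"{locus}J{int(rng.integers(cfg.n_j)) + 1}*01"
    return TcrChain(locus=locus, v_call=v, j_call=j,
                    cdr3_aa=_random_cdr3(rng, motif))


def gen_binding_dataset(cfg: SynthConfig):
    """Positive binding records plus a truth sidecar.

    Per epitope: one peptide (length drawn from the configured distribution),
    one HLA allele drawn from the skewed frequency vector, and
    ``tcrs_per_epitope`` TCRs whose CDR3beta carries the epitope's motif with
    probability ``motif_strength``.  ``dominant_epitope`` gives epitope 0 as
    many records as all others combined (~50% of positives).
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.motif_len > 6:
        raise ValueError("motif longer than the minimum CDR3 core (6)")
    alleles = [f"HLA-A*{i + 1:02d}:01" for i in range(cfg.n_hla)]
    freqs = np.asarray(cfg.hla_freqs[: cfg.n_hla], dtype=float)

    lens = sorted(cfg.peptide_len_probs)
    len_probs = np.array([cfg.peptide_len_probs[l] for l in lens])
    peptides: list[str] = []
    while len(peptides) < cfg.n_epitopes:
        pep = _random_aa(rng, int(rng.choice(lens, p=len_probs)))
        if pep not in peptides:
            peptides.append(pep)

    shared_motif = _random_aa(rng, cfg.motif_len)
    epitopes = []
    for e, pep in enumerate(peptides):
        if rng.random() < cfg.cross_epitope_sharing:
            motif = shared_motif
        elif cfg.motif_mode == "peptide":
            motif = _peptide_motif(pep, cfg.motif_len)
        else:
            motif = _random_aa(rng, cfg.motif_len)
        hla = alleles[int(rng.choice(cfg.n_hla, p=freqs))]
        n_tcrs = cfg.tcrs_per_epitope
        if cfg.dominant_epitope and e == 0:
            n_tcrs = cfg.tcrs_per_epitope * (cfg.n_epitopes - 1)
        epitopes.append({"peptide": pep, "hla": hla, "motif": motif,
                         "n_tcrs": n_tcrs})

    records: list[BindingRecord] = []
    truth_records = []
    for epi in epitopes:
        phla = PeptideHla(peptide_aa=epi["peptide"], hla_allele=epi["hla"])
        for _ in range(epi["n_tcrs"]):
            planted = bool(rng.random() < cfg.motif_strength)
            beta = _random_chain(rng, "TRB", cfg, motif=epi["motif"] if planted else None)
            alpha = _random_chain(rng, "TRA", cfg)
            records.append(BindingRecord(alpha=alpha, beta=beta, phla=phla,
                                         label="binder", source="synth"))
            truth_records.append({"peptide": epi["peptide"],
                                  "beta_cdr3": beta.cdr3_aa,
                                  "motif_planted": planted})
    truth = {"seed": cfg.seed, "config": {**asdict(cfg)},
             "epitopes": epitopes, "records": truth_records}
    return records, truth


def gen_hla_sequences(cfg: SynthConfig, length: int = 275,
                      seed: int | None = None) -> dict[str, str]:
    """Synthetic mature HLA heavy chains for the generated alleles: a shared
    scaffold with allele-specific polymorphisms (long enough for the
    packaged 34-position pseudosequence list)."""
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 7)
    scaffold = list(_random_aa(rng, length))
    out = {}
    for i in range(cfg.n_hla):
        seq = scaffold.copy()
        for pos in rng.choice(length, size=25, replace=False):
            seq[pos] = _AA[int(rng.integers(20))]
        out[f"HLA-A*{i + 1:02d}:01"] = "".join(seq)
    return out


def gen_repertoire(cfg: SynthConfig, n_pairs: int, seed: int | None = None):
    """Unlabelled paired alpha/beta chains for masked-LM pretraining."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    return [(_random_chain(rng, "TRA", cfg), _random_chain(rng, "TRB", cfg))
            for _ in range(n_pairs)]


# -- 10x-style UMI tables ---------------------------------------------------

def gen_umi_table(n_cells: int, n_peptides: int, effect: float, seed: int = 0,
                  lam_bg: float = 20.0, binder_frac: float = 0.5,
                  negctrl_col: str = "negctrl"):
    """UMI count matrix with truth flags.

    Background counts (including the negative control) are Poisson(lam_bg);
    a true binder cell's cognate-peptide count is Poisson(lam_bg +
    effect * sqrt(lam_bg)), i.e. the binder excess is ``effect`` background
    standard deviations.  Returns ``(umi DataFrame, truth DataFrame)`` with
    matching shapes.
    """
    if effect < 0:
        raise ValueError("effect must be non-negative")
    rng = np.random.default_rng(seed)
    s_bg = np.sqrt(lam_bg)
    counts = rng.poisson(lam_bg, size=(n_cells, n_peptides + 1))
    truth = np.zeros((n_cells, n_peptides), dtype=bool)
    for i in range(n_cells):
        if rng.random() < binder_frac:
            cognate = int(rng.integers(n_peptides))
            truth[i, cognate] = True
            counts[i, cognate] = rng.poisson(lam_bg + effect * s_bg)
    barcodes = [f"cell{i:05d}" for i in range(n_cells)]
    peptide_cols = [f"pep{j}" for j in range(n_peptides)]
    umi = pd.DataFrame(counts, index=barcodes, columns=peptide_cols + [negctrl_col])
    truth_df = pd.DataFrame(truth, index=barcodes, columns=peptide_cols)
    return umi, truth_df


# -- file emission (the formats the pipeline reads) -------------------------

#: column names of the raw source dialect written by write_source_tsv,
#: mapping to the standard names expected downstream
SOURCE_COLUMN_MAP = {
    "alpha_v_gene": "alpha_v", "alpha_j_gene": "alpha_j",
    "alpha_junction_aa": "alpha_cdr3",
    "beta_v_gene": "beta_v", "beta_j_gene": "beta_j",
    "beta_junction_aa": "beta_cdr3",
    "epitope": "peptide", "mhc_allele": "hla_allele",
    "binder_label": "label", "dataset": "source",
}


def write_source_tsv(records: list[BindingRecord], path) -> None:
    """Emit records in a raw source dialect (renamed columns) so the
    standardization column-mapping path is exercised end to end."""
    rows = []
    for r in records:
        rows.append({
            "alpha_v_gene": r.alpha.v_call if r.alpha else "",
            "alpha_j_gene": r.alpha.j_call if r.alpha else "",
            "alpha_junction_aa": r.alpha.cdr3_aa if r.alpha else "",
            "beta_v_gene": r.beta.v_call if r.beta else "",
            "beta_j_gene": r.beta.j_call if r.beta else "",
            "beta_junction_aa": r.beta.cdr3_aa if r.beta else "",
            "epitope": r.phla.peptide_aa,
            "mhc_allele": r.phla.hla_allele,
            "binder_label": r.label,
            "dataset": r.source,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_cell_chain_tsv(pairs, path) -> None:
    """AIRR-style per-chain rows with a cell_id column for the 10x path."""
    rows = []
    for barcode, (alpha, beta) in pairs.items():
        for chain in (alpha, beta):
            rows.append({"cell_id": barcode, "locus": chain.locus,
                         "v_call": chain.v_call, "j_call": chain.j_call,
                         "cdr3_aa": chain.cdr3_aa,
                         "productive": "True", "high_confidence": "True"})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_truth_json(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1)
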