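import numpy as np
import pytest

from tcrbind import synth
from tcrbind.records import BindingRecord, PeptideHla, TcrChain


@pytest.fixture(scope="session")
def small_cfg():
    """Small but structured synthetic study: a handful of epitopes with a
    strong planted motif."""
    return synth.SynthConfig(n_epitopes=4, tcrs_per_epitope=20, seed=11)


@pytest.fixture(scope="session")
def germline_db(small_cfg):
    return synth.gen_germline_db(small_cfg)


@pytest.fixture(scope="session")
def positives(small_cfg):
    records, _ = synth.gen_binding_dataset(small_cfg)
    return records


def make_record(beta_cdr3="CASSLGQYF", peptide="NLVPMVATV", hla="HLA-A*02:01",
                label="binder", alpha_cdr3="CAVRDNYGF", source="t"):
    return BindingRecord(
        alpha=TcrChain("TRA", "TRAV1*01", "TRAJ1*01", alpha_cdr3),
        beta=TcrChain("TRB", "TRBV1*01", "TRBJ1*01", beta_cdr3),
        phla=PeptideHla(peptide, hla),
        label=label, source=source,
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
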