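import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from bcrtrace.io import ChainTable
from bcrtrace.simulate import SimConfig, simulate_repertoire


def familywise_z(n_comparisons: int, single_z: float = 3.0) -> float:
    """Bonferroni-adjusted z bound for checking many proportions at once.

    Keeps the familywise false-alarm rate of ``n_comparisons`` simultaneous
    checks equal to that of a single ``single_z``-sigma check, so
    multi-cell recovery tests carry the same statistical guarantee as a
    single 3-SE comparison.
    """
    from scipy.stats import norm

    alpha = 2 * norm.sf(single_z)
    return float(norm.isf(alpha / (2 * n_comparisons)))


def make_chain_table(rows: list[dict]) -> ChainTable:
    """Build a ChainTable from plain dicts, filling schema defaults."""
    defaults = {
        "cell_id": "cellX",
        "locus": "IGH",
        "v_call": "IGHV3-23*01",
        "j_call": "IGHJ4*01",
        "productive": True,
        "junction": pd.NA,
        "junction_aa": pd.NA,
        "cdr3": pd.NA,
        "cdr3_aa": pd.NA,
        "c_call": pd.NA,
        "visit": pd.NA,
        "read_count": 100,
    }
    filled = [{**defaults, **row} for row in rows]
    return ChainTable(pd.DataFrame(filled))


@pytest.fixture(scope="session")
def default_sim():
    """One moderate simulated repertoire shared across tests (seed 11)."""
    return simulate_repertoire(SimConfig(n_clones=120, seed=11))


@pytest.fixture()
def airr_tsv(tmp_path):
    path = tmp_path / "chains.tsv"
    path.write_text(
        "sequence_id\tcell_id\tlocus\tv_call\tj_call\tc_call\tproductive\tjunction\tjunction_aa\tcdr3\tread_count\n"
        "c1\tcellA\tIGH\tIGHV3-23*01\tIGHJ4*02\tIGHG1\tT\tTGTGCTAGATGG\tCARW\tGCTAGA\t100\n"
        "c2\tcellA\tIGK\tIGKV1-39*01\tIGKJ1*01\tIGKC\ttrue\tTGTCAGTTC\tCQF\tCAG\t80\n"
        "c3\tcellB\tIGH\tIGHV1-2*01\tIGHJ6*01\tIGHM\tF\tTGTGCTTGG\tCAW\tGCT\t5\n"
    )
    return path


@pytest.fixture()
def tenx_csv(tmp_path):
    path = tmp_path / "filtered_contig_annotations.csv"
    path.write_text(
        "barcode,contig_id,chain,v_gene,d_gene,j_gene,c_gene,productive,cdr3,cdr3_nt,reads,umis\n"
        "AAAC-1,AAAC-1_contig_1,IGH,IGHV3-23,IGHD3-10,IGHJ4,IGHG1,True,CARW,TGTGCTAGATGG,500,4\n"
        "AAAC-1,AAAC-1_contig_2,IGK,IGKV1-39,None,IGKJ1,IGKC,True,CQF,TGTCAGTTC,300,2\n"
        "TTTG-1,TTTG-1_contig_1,IGH,IGHV1-2,None,IGHJ6,None,False,CAW,TGTGCTTGG,20,1\n"
    )
    return path
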