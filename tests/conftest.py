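import numpy as np
import pandas as pd
import pytest

from concordpgs.clump import ClumpParams, ReferencePanel, WeightSet
from concordpgs.gwas_io import RECORD_COLUMNS, SummaryStatsSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240521)


def make_records(rows):
    """Rows of (snv_id, chrom, pos, ea, oa, z, p, n_cases, n_controls)."""
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def make_study(label, rows, trait_kind="binary"):
    return SummaryStatsSet(label, make_records(rows), trait_kind)


def random_panel(rng, n_ind, snv_ids, chrom, pos, maf=0.3):
    g = rng.binomial(2, maf, size=(n_ind, len(snv_ids))).astype(np.float32)
    return ReferencePanel(np.array(snv_ids, dtype=object),
                          np.array(chrom, dtype=object),
                          np.array(pos, dtype=np.int64), g)


def make_weightset(members_rows, params=ClumpParams(1.0, 0.5, 250)):
    """Rows of (snv_id, chrom, pos, effect_allele, other_allele, weight, p)."""
    cols = ["snv_id", "chrom", "pos", "effect_allele", "other_allele", "weight", "p"]
    return WeightSet(params, pd.DataFrame(members_rows, columns=cols))


@pytest.fixture
def sumstats_file(tmp_path):
    """Well-formed 5-row TSV with default column names."""
    path = tmp_path / "study.tsv"
    path.write_text(
        "SNP\tCHR\tBP\tA1\tA2\tZ\tP\tN_CASES\tN_CONTROLS\n"
        "rs1\t1\t1000\tA\tG\t1.5\t0.13\t500\t500\n"
        "rs2\t1\t2000\tC\tT\t-2.1\t0.036\t500\t500\n"
        "rs3\t2\t3000\tG\tA\t0.3\t0.76\t500\t500\n"
        "rs4\t2\t4000\tT\tC\t3.2\t0.0014\t500\t500\n"
        "rs5\t3\t5000\tA\tC\t-0.9\t0.37\t500\t500\n"
    )
    return path
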