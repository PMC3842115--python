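import numpy as np
import pandas as pd
import pytest

from hepaprot.quantio import ExpressionMatrix, RunTable


def make_run_table(records, run_id="run1", channels=("113", "114", "115"), pool="113"):
    """Build a RunTable from (accession, n_peptides, conf, fdr, quantities) tuples."""
    rows = {}
    for acc, n_pep, conf, fdr, quants in records:
        rows[acc] = {"n_peptides": n_pep, "best_single_conf": conf, "fdr_pass": fdr,
                     **dict(zip(channels, quants))}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "accession"
    return RunTable(run_id, tuple(channels), pool, table)


@pytest.fixture
def small_matrix():
    """Complete 4-protein x 3-sample ratio matrix."""
    values = pd.DataFrame(
        {
            "s1": [1.0, 2.0, 0.5, 1.0],
            "s2": [2.0, 1.0, 1.0, 0.5],
            "s3": [1.0, 1.0, 2.0, 2.0],
        },
        index=pd.Index(["P1", "P2", "P3", "P4"], name="accession"),
    )
    return ExpressionMatrix(values)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
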