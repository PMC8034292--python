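"""Shared fixtures: small quant tables and the published-count TMA cohort."""

import numpy as np
import pandas as pd
import pytest

from memscreen import QuantTable, reconstruct_cohort

NAN = np.nan

#: Printed positive/negative counts per covariate level for the clinical
#: cohort the association stage reproduces (benign: 0/17, cancer: 20/21).
TABLE3_COVARIATE_COUNTS = {
    "age_group": {">40": (14, 10), "<=40": (6, 11)},
    "pt_status": {"T2": (15, 9), "T3": (3, 7)},
    "grade": {"II": (10, 0), "II~III": (4, 4), "III": (4, 8)},
    "ln_metastasis": {"negative": (7, 13), "positive": (13, 7)},
    "stage": {"IIA": (5, 5), "IIB": (9, 11), "IIIA": (4, 1)},
    "her2_status": {"negative": (7, 11), "positive": (7, 10)},
}

TABLE3_PVALUES = {
    "tissue_class": 0.0004,
    "age_group": 0.1459,
    "pt_status": 0.0836,
    "grade": 0.0051,
    "ln_metastasis": 0.0578,
    "stage": 0.3729,
    "her2_status": 0.8902,
}


def make_quant_table(values, cell_line="toy", accessions=None, normalized=False):
    """QuantTable from a nested list (rows = proteins, cols = replicates)."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    acc = accessions or [f"P{i + 1:03d}" for i in range(n)]
    idx = pd.Index(acc, name="accession")
    proteins = pd.DataFrame(
        {"gene": [f"GENE{i + 1}" for i in range(n)],
         "description": [f"protein {i + 1}" for i in range(n)]},
        index=idx,
    )
    areas = pd.DataFrame(
        values, index=idx, columns=[f"rep{j + 1}" for j in range(values.shape[1])]
    )
    return QuantTable(cell_line=cell_line, proteins=proteins, areas=areas,
                      normalized=normalized)


@pytest.fixture(scope="session")
def table3_cohort():
    return reconstruct_cohort(
        benign=(0, 17),
        cancer=(20, 21),
        covariate_counts=TABLE3_COVARIATE_COUNTS,
        n_unevaluable=(1, 1),
    )


def random_raw_table(rng, n_proteins=50, n_replicates=4, missing_rate=0.1):
    """Random positive table with missing cells (every row keeps one value)."""
    values = rng.lognormal(8.0, 1.0, size=(n_proteins, n_replicates))
    miss = rng.random(values.shape) < missing_rate
    keep = rng.integers(0, n_replicates, size=n_proteins)
    miss[np.arange(n_proteins), keep] = False
    values[miss] = np.nan
    return make_quant_table(values, cell_line="random")
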