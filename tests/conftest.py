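import numpy as np
import pandas as pd
import pytest

from neanderscore import GenotypeMatrix, SnpCatalog, SnpRecord


@pytest.fixture
def tiny_catalog() -> SnpCatalog:
    return SnpCatalog(
        [
            SnpRecord("1", 1000, "A", "G", "rs1"),
            SnpRecord("1", 2000, "C", "T", "rs2"),
            SnpRecord("2", 500, "G", "A", "rs3"),
            SnpRecord("2", 900, "T", "C", "rs4"),
            SnpRecord("3", 42, "A", "C", "rs5"),
        ]
    )


def make_meta(sample_ids, groups, stratum="WNH", **phenos) -> pd.DataFrame:
    n = len(sample_ids)
    df = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": groups,
            "ethnicity": stratum,
            "sex": ["female"] * n,
            "epilepsy": phenos.get("epilepsy", [0] * n),
            "intellectual_disability": 0,
            "language_delay": 0,
            "language_regression": 0,
            "family_type": "simplex",
            "diagnosis": "autism",
            "excluded": False,
            "exclusion_reason": "",
        }
    )
    return df


@pytest.fixture
def small_cohort(tiny_catalog):
    """4 samples (2 cases, 2 controls) x 5 SNPs, complete."""
    dosage = np.array(
        [
            [2, 1, 0, 0, 1],
            [1, 1, 0, 2, 0],
            [0, 0, 0, 1, 0],
            [0, 1, 0, 0, 0],
        ],
        dtype=np.int8,
    )
    ids = ["c1", "c2", "k1", "k2"]
    matrix = GenotypeMatrix(ids, tiny_catalog, dosage)
    meta = make_meta(ids, ["case", "case", "control", "control"])
    return matrix, meta
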