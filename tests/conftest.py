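import numpy as np
import pandas as pd
import pytest

from glioclass.io import ClinicalTable, OmicsMatrix
from glioclass.synthetic import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted cohort shared by read-only tests (default conditions
    scaled down for speed: 3 subtypes x 30, 200 genes, 400 CpGs, 20 pairs)."""
    config = SimConfig(
        n_per_subtype=(30, 30, 30),
        n_genes=200,
        n_cpgs=400,
        n_informative_pairs=20,
        seed=7,
    )
    return config, generate_dataset(config)


@pytest.fixture(scope="session")
def default_cohort():
    """The full default study conditions (n = 150, 60 planted pairs)."""
    config = SimConfig(seed=1)
    return config, generate_dataset(config)


@pytest.fixture
def tiny_expr():
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0], [0.0, 0.0, 0.0, 9.0]],
        index=["G1", "G2", "G3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return OmicsMatrix(layer="expression", values=values)


@pytest.fixture
def tiny_clinical():
    table = pd.DataFrame(
        {
            "subtype": ["A", "A", "B", "B"],
            "os_time": [10.0, 20.0, 30.0, 40.0],
            "os_event": [1, 1, 0, 1],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )
    return ClinicalTable(table=table, label_set=("A", "B"))
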