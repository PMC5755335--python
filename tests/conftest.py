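import numpy as np
import pandas as pd
import pytest

from crcmet import pipeline, synthetic
from crcmet.io_tables import ConcentrationTable


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic cohort: 163 metabolites, 48 injected effects."""
    return synthetic.generate(seed=1)


@pytest.fixture(scope="session")
def fitted_pipeline(default_dataset):
    table, ann, _ = default_dataset
    return pipeline.discover(table, ann, ("control", "CRC"))


@pytest.fixture()
def small_table():
    """Tiny hand-made table with a missing cell and a QC pair."""
    values = pd.DataFrame(
        {
            "AA_01": [5.0, np.nan, 7.0, 10.0, 10.0],
            "AC_01": [1.0, 2.0, 3.0, 2.0, 2.2],
            "SM_01": [0.5, 0.6, 0.7, 0.6, 0.6],
        },
        index=["S1", "S2", "S3", "QC1", "QC2"],
    )
    classes = pd.Series(
        ["amino_acid", "acylcarnitine", "SM"], index=["AA_01", "AC_01", "SM_01"]
    )
    table = ConcentrationTable(values, classes)
    ann = pd.DataFrame(
        {
            "sample_id": ["S1", "S2", "S3", "QC1", "QC2"],
            "group": ["control", "CRC", "CRC", "none", "none"],
            "stage": ["none", "I", "II", "none", "none"],
            "set": ["train", "train", "train", "none", "none"],
            "is_qc": [False, False, False, True, True],
        }
    )
    return table, ann
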