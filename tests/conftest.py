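import numpy as np
import pandas as pd
import pytest

import maitsig as m


@pytest.fixture(scope="session")
def small_sc_dataset():
    """A small multi-cancer synthetic dataset shared across test modules."""
    cfg = m.SyntheticScConfig(
        seed=11,
        cancers=("HCC", "CRC"),
        patients_per_cancer=2,
        cells_per_subset=40,
        n_background_genes=120,
    )
    return m.generate_sc_dataset(cfg)


@pytest.fixture()
def tiny_matrix():
    """3 genes x 4 cells counts matrix with simple values."""
    counts = np.array(
        [
            [0, 1, 2, 3],
            [4, 0, 0, 1],
            [1, 1, 1, 1],
        ],
        dtype=float,
    )
    return m.GeneExpressionMatrix(
        gene_ids=["G1", "G2", "G3"], cell_ids=["c1", "c2", "c3", "c4"], counts=counts
    )


def make_annotations(cell_ids, tissue="tumor", subset="CD8", patient="P1",
                     treatment="not_applicable"):
    return pd.DataFrame(
        {
            "cell_id": list(cell_ids),
            "patient_id": patient,
            "tissue": tissue,
            "subset": subset,
            "treatment": treatment,
        }
    )
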