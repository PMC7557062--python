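import numpy as np
import pandas as pd
import pytest

from savbind import data_model as dm
from savbind import synthetic_data as sd


@pytest.fixture(scope="session")
def bundle():
    """One mid-sized synthetic dataset shared across read-only tests."""
    return sd.generate_dataset(sd.GeneratorConfig(n_savs=20_000, seed=7))


@pytest.fixture(scope="session")
def joined(bundle):
    table, _ = dm.join_annotations(
        bundle["variants"], bundle["effect_scores"], bundle["residue_annotations"]
    )
    return dm.filter_extremes(table)


@pytest.fixture()
def tiny_table():
    """Four SAVs covering the full (common/rare) x (binding/other) grid."""
    return pd.DataFrame(
        {
            "protein_id": ["P1"] * 4,
            "position": [1, 2, 3, 4],
            "ref_aa": ["A"] * 4,
            "alt_aa": ["V"] * 4,
            "ldaf": [0.2, 0.3, 1e-4, 2e-4],
            "freq_class": ["common", "common", "rare", "rare"],
            "snap2_score": [60, -20, 40, -50],
            "protein_status": ["binding", "other", "binding", "other"],
            "dna_status": ["other"] * 4,
            "rna_status": ["other"] * 4,
        }
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
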