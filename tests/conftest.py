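import numpy as np
import pandas as pd
import pytest

from rhizonet import generate_dataset
from rhizonet.otu import OtuTable


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic survey (24 samples, both compartments)."""
    return generate_dataset()


@pytest.fixture(scope="session")
def compartment_tables(dataset):
    """Per-compartment sub-tables of the default dataset."""
    table = dataset.table
    return {
        comp: table.subset_samples(
            table.metadata.index[table.metadata["compartment"] == comp]
        )
        for comp in ("G", "T")
    }


def make_table(counts, compartments=None, species=None, taxonomy=None):
    """Small OtuTable builder for hand-constructed examples."""
    counts = pd.DataFrame(
        np.asarray(counts),
        index=[f"S{i+1}" for i in range(len(counts))],
        columns=[f"OTU{j+1}" for j in range(np.asarray(counts).shape[1])],
    )
    n = counts.shape[0]
    metadata = pd.DataFrame(
        {
            "compartment": compartments or ["G"] * n,
            "species": species or ["PZ"] * n,
            "replicate": list(range(1, n + 1)),
        },
        index=counts.index,
    )
    return OtuTable(counts, metadata, taxonomy)
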