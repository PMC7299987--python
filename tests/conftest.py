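import numpy as np
import pandas as pd
import pytest

from aldernet.io_tables import AbundanceProfile, OtuTable, SampleInfo


def make_profile(values, otu_ids=None, sample_ids=None, lineages=None, rank="otu"):
    """Build an AbundanceProfile from a plain nested list/array."""
    values = np.asarray(values, dtype=float)
    otu_ids = otu_ids or [f"OTU_{i + 1:02d}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"S{j + 1}" for j in range(values.shape[1])]
    lin = None
    if lineages is not None:
        lin = pd.Series(lineages, index=otu_ids)
    return AbundanceProfile(
        values=pd.DataFrame(values, index=otu_ids, columns=sample_ids),
        rank=rank,
        lineages=lin,
    )


def make_table(counts, otu_ids=None, sample_ids=None, lineages=None, samples=None):
    counts = np.asarray(counts, dtype=np.int64)
    otu_ids = otu_ids or [f"OTU_{i + 1:02d}" for i in range(counts.shape[0])]
    sample_ids = sample_ids or [f"S{j + 1}" for j in range(counts.shape[1])]
    taxonomy = pd.Series(
        lineages if lineages is not None else ["k__Bacteria"] * len(otu_ids),
        index=otu_ids,
        name="taxonomy",
    )
    if samples is None:
        samples = [SampleInfo(sample_id=s) for s in sample_ids]
    return OtuTable(
        counts=pd.DataFrame(counts, index=otu_ids, columns=sample_ids),
        taxonomy=taxonomy,
        samples=samples,
    )


@pytest.fixture
def three_otu_table():
    return make_table(
        [[5, 1], [3, 0], [2, 9]],
        lineages=[
            "k__Bacteria;p__Actinobacteria",
            "k__Bacteria;p__Actinobacteria",
            "k__Bacteria;p__Proteobacteria",
        ],
    )
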