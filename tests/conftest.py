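import numpy as np
import pandas as pd
import pytest

from dustair.io_tables import CountTable, SampleMetadata, TaxonomyTable


def make_counts(matrix, otu_ids=None, sample_ids=None) -> CountTable:
    matrix = np.asarray(matrix, dtype=np.int64)
    otu_ids = otu_ids or [f"Otu{i+1:04d}" for i in range(matrix.shape[0])]
    sample_ids = sample_ids or [f"S{j+1}" for j in range(matrix.shape[1])]
    return CountTable(pd.DataFrame(matrix, index=pd.Index(otu_ids, name="otu_id"),
                                   columns=sample_ids))


def make_metadata(rows) -> SampleMetadata:
    defaults = {"environment": "", "season": "", "farm_id": "",
                "replicate_of": "", "is_control": False, "collection_days": np.nan}
    return SampleMetadata(pd.DataFrame([{**defaults, **r} for r in rows]))


@pytest.fixture
def tiny_counts():
    return make_counts([[5, 0, 2], [1, 9, 3]], sample_ids=["S1", "S2", "S3"])


@pytest.fixture
def paired_metadata():
    """Two farms (stable + home) in winter, one suburban home, one control."""
    return make_metadata([
        {"sample_id": "PSW01", "environment": "pig_stable", "season": "winter",
         "farm_id": "F01", "collection_days": 14},
        {"sample_id": "PSW02", "environment": "pig_stable", "season": "winter",
         "farm_id": "F02", "collection_days": 14},
        {"sample_id": "FHW01", "environment": "farm_home", "season": "winter",
         "farm_id": "F01", "collection_days": 14},
        {"sample_id": "FHW02", "environment": "farm_home", "season": "winter",
         "farm_id": "F02", "collection_days": 14},
        {"sample_id": "SUW01", "environment": "suburban_home", "season": "winter",
         "collection_days": 14},
        {"sample_id": "NC01", "is_control": True},
    ])


@pytest.fixture
def flat_taxonomy():
    """One genus per OTU, all Bacteria/Firmicutes — for rank-collapse-free tests."""
    def build(otu_ids):
        return TaxonomyTable({
            o: ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales",
                "Lachnospiraceae", f"Genus_{i}")
            for i, o in enumerate(otu_ids)
        })
    return build
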