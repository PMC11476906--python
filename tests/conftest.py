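"""Shared fixtures: a tiny hand-built catalog and a small simulated study."""

import pandas as pd
import pytest

from sedncycle import syndata
from sedncycle.catalog import GeneCatalog, GeneRecord


@pytest.fixture
def tiny_catalog() -> GeneCatalog:
    """Five genes: two nitrification paralogs, one nosZ, two markers."""
    return GeneCatalog(
        [
            GeneRecord("amoA_1", 750, ko_id="K10944", gene_symbol="amoA"),
            GeneRecord("amoA_2", 800, ko_id="K10944", gene_symbol="amoA"),
            GeneRecord("nosZ_1", 1900, ko_id="K00376", gene_symbol="nosZ"),
            GeneRecord("MG01", 900, ko_id="K9901", is_marker=True),
            GeneRecord("MG02", 950, ko_id="K9902", is_marker=True),
        ]
    )


@pytest.fixture(scope="session")
def small_study() -> syndata.StudyData:
    """A down-scaled simulated study reused across module tests."""
    return syndata.simulate_study(seed=7, n_inserts=4000)


def alignment_frame(pairs, pct=99.0, aligned=100):
    """Build an alignment DataFrame from (insert, gene) pairs."""
    return pd.DataFrame(
        {
            "insert_id": [p[0] for p in pairs],
            "gene_id": [p[1] for p in pairs],
            "pct_id": pct,
            "aligned_bases": aligned,
        }
    )
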