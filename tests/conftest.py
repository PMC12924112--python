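import numpy as np
import pandas as pd
import pytest

from benthos16s.io_model import FilterConfig, Lineage, OtuTable, SimilarityHit


@pytest.fixture
def config():
    return FilterConfig()


def make_hit(
    query="q1",
    subject="s1",
    identity=99.0,
    alen=300,
    evalue=1e-20,
    bitscore=500.0,
    lineage=("d__B", "p__P", "c__C", "o__O", "f__F", "g__G", "s__S"),
):
    return SimilarityHit(
        query_id=query,
        subject_id=subject,
        pct_identity=identity,
        alignment_length=alen,
        evalue=evalue,
        bitscore=bitscore,
        lineage=Lineage(tuple(lineage)) if lineage is not None else None,
    )


@pytest.fixture
def toy_table():
    """4 OTUs x 6 samples: 3 true samples + one control of each role."""
    counts = pd.DataFrame(
        np.array(
            [
                [10, 20, 30, 5, 4, 6],   # contaminant-like: high in controls
                [100, 0, 50, 0, 0, 0],
                [0, 7, 0, 0, 0, 0],
                [3, 3, 3, 1, 0, 0],
            ]
        ),
        index=["otuA", "otuB", "otuC", "otuD"],
        columns=["s1", "s2", "s3", "fc", "ec", "pc"],
    )
    roles = {
        "s1": "true_sample",
        "s2": "true_sample",
        "s3": "true_sample",
        "fc": "field_control",
        "ec": "extraction_control",
        "pc": "pcr_control",
    }
    return OtuTable(counts, roles)
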