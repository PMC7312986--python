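import numpy as np
import pandas as pd
import pytest

from u12retain import SimConfig


@pytest.fixture
def toy_genome():
    # 30 nt single chromosome; exons [0,10) and [20,30) leave intron [10,20)
    return {"chrA": "ACGTACGTAC" + "GTAAGTTTAG" + "TTTTACGTAC"}


def _gtf(strand: str) -> str:
    attrs = 'gene_id "gX"; transcript_id "gX.t1";'
    lines = [
        f"chrA\ttoy\texon\t1\t10\t.\t{strand}\t.\t{attrs}",
        f"chrA\ttoy\texon\t21\t30\t.\t{strand}\t.\t{attrs}",
    ]
    return "\n".join(lines) + "\n"


@pytest.fixture
def toy_gtf_plus():
    return _gtf("+")


@pytest.fixture
def toy_gtf_minus():
    return _gtf("-")


@pytest.fixture
def small_config():
    return SimConfig(seed=11, n_genes=60, n_planted=8)


def make_counts(event_rows):
    """Long-format counts table from (event_id, class, gene, intron, sample, group, inc, exc) rows."""
    return pd.DataFrame(
        event_rows,
        columns=[
            "event_id",
            "event_class",
            "gene_id",
            "intron_id",
            "sample",
            "group",
            "inclusion_reads",
            "exclusion_reads",
        ],
    )


@pytest.fixture
def counts_builder():
    return make_counts
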