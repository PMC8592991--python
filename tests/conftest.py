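import numpy as np
import pandas as pd
import pytest

from fitcage.ctss import TagCluster


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_cluster(positions, counts, strand="+", chrom="chr1", peak=None, cid="p1"):
    positions = np.asarray(positions, dtype=np.int64)
    counts = np.asarray(counts, dtype=float)
    if peak is None:
        top = positions[counts == counts.max()]
        peak = int(top.min() if strand == "+" else top.max())
    return TagCluster(
        cluster_id=cid,
        chrom=chrom,
        start=int(positions.min()),
        end=int(positions.max()) + 1,
        strand=strand,
        peak=peak,
        positions=positions,
        counts=counts,
    )


@pytest.fixture
def small_genome():
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), size=5000))
    return {"chr1": seq}


@pytest.fixture
def gene_table():
    return pd.DataFrame(
        {
            "gene_id": ["geneA", "geneB"],
            "chrom": ["chr1", "chr1"],
            "start": [1000, 3000],
            "end": [2000, 4000],
            "strand": ["+", "-"],
            "tss": [1000, 3999],
        }
    )
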