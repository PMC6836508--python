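import numpy as np
import pytest

from cnvpost.model import (
    LEFT,
    RIGHT,
    Breakend,
    NovelAdjacency,
    canonicalize_adjacency,
)


def make_adj(chrom1, pos1, o1, chrom2, pos2, o2, tool="DELLY", pe=5, sr=5,
             ins=None, id=""):
    return canonicalize_adjacency(
        Breakend(chrom1, pos1, o1),
        Breakend(chrom2, pos2, o2),
        id=id,
        pe_support=pe,
        sr_support=sr,
        source_tool=tool,
        inserted_seq=ins,
    )


def del_adj(chrom, start, end, **kw):
    """Deletion-signature adjacency over [start, end)."""
    return make_adj(chrom, start, RIGHT, chrom, end, LEFT, **kw)


def tdup_adj(chrom, start, end, **kw):
    """Tandem-duplication-signature adjacency over [start, end)."""
    return make_adj(chrom, start, LEFT, chrom, end, RIGHT, **kw)


def random_adjacencies(rng, n, span=20_000, tools=("DELLY", "MANTA"),
                       chroms=("chr1", "chr2")):
    """Dense random adjacencies for clustering stress tests."""
    out = []
    orients = [RIGHT, LEFT]
    for i in range(n):
        c1, c2 = rng.choice(chroms), rng.choice(chroms)
        out.append(
            make_adj(
                str(c1), int(rng.integers(0, span)), orients[rng.integers(2)],
                str(c2), int(rng.integers(0, span)), orients[rng.integers(2)],
                tool=str(rng.choice(tools)), id=f"r{i}",
            )
        )
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
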