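import warnings

import numpy as np
import pytest

from ccfind.core_model import (
    Relation,
    SearchConfig,
    Segment,
    SegmentCollection,
    SpeciesTable,
)


def make_config(**kwargs) -> SearchConfig:
    """SearchConfig builder that silences the small-k feasibility warning."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return SearchConfig(**kwargs)


def make_collection(seqs, side="A", genes=None):
    """Collection from {species: {segment_id: sequence}}.

    ``genes`` optionally maps segment_id -> gene_id (default: one gene per
    segment id).
    """
    species = sorted(seqs)
    segments = []
    for sp in species:
        for seg_id, seq in sorted(seqs[sp].items()):
            gene = (genes or {}).get(seg_id, f"gene_{seg_id}")
            segments.append(Segment(sp, seg_id, gene, seq))
    return SegmentCollection(
        side, tuple(segments), SpeciesTable.uniform(species)
    )


def random_collection(rng, m=3, n=4, length=50, genes=None, side="A"):
    """Random uniform-nucleotide collection, m species x n segments."""
    nt = "ACGT"
    seqs = {
        f"sp{i}": {
            f"s{j:02d}": "".join(
                nt[c] for c in rng.integers(0, 4, size=length)
            )
            for j in range(n)
        }
        for i in range(m)
    }
    return make_collection(seqs, side=side, genes=genes)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def tiny_hit_fixture():
    """3 species; GGGC planted in s1 and GCCC in s2 for sp0/sp1 only."""
    seqs = {}
    for i, sp in enumerate(["sp0", "sp1", "sp2"]):
        seqs[sp] = {
            "s1": "AATTGGGCATAT" if i < 2 else "AATTAAACATAT",
            "s2": "CCAAGCCCTGGA" if i < 2 else "CCAATTTCTGGA",
        }
    return make_collection(seqs, genes={"s1": "g1", "s2": "g1"})
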