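import numpy as np
import pytest

from relaxsel.alignment import CodonAlignment
from relaxsel.trees import parse_newick


@pytest.fixture
def four_taxon_tree():
    return parse_newick("((A:0.1,B:0.2):0.05,C:0.3,D:0.12);")


@pytest.fixture
def four_taxon_alignment():
    seqs = {
        "A": "ATGGCTAAA",
        "B": "ATGGCCAAG",
        "C": "ATAGCTAAA",
        "D": "ATGGATAAA",
    }
    return CodonAlignment(list(seqs), list(seqs.values()))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
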