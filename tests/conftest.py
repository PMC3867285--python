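import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the naive oracles

from cube.msa_io import Alignment, GroupedAlignment

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def toy_alignment():
    """Four 6-column sequences with a gap and varied columns."""
    return Alignment(
        ids=("a", "b", "c", "d"),
        seqs=("ACDEFG", "ACDEFG", "ACDKYG", "AC-KYW"),
    )


@pytest.fixture
def three_taxon_alignment():
    """a and b near-identical, c distant; UPGMA merges (a, b) first.

    Column 1 differs in every sequence; columns 2-3 split along the first
    bifurcation (G,G | W); column 4 is jointly invariant.
    """
    return Alignment(ids=("a", "b", "c"), seqs=("AGGG", "CGGG", "DWWG"))


@pytest.fixture
def grouped_toy():
    aln = Alignment(
        ids=("g1a", "g1b", "g1c", "g2a", "g2b", "g2c"),
        seqs=("DAGR", "DCGR", "DDGR", "KAGA", "KCGG", "KDGS"),
    )
    return GroupedAlignment(aln, {"g1a": 0, "g1b": 0, "g1c": 0,
                                  "g2a": 1, "g2b": 1, "g2c": 1})


def random_alignment(rng, n_seqs=None, n_cols=None, gap_prob=0.08):
    """A small random alignment (may contain gaps), for oracle sweeps."""
    n_seqs = n_seqs or int(rng.integers(2, 7))
    n_cols = n_cols or int(rng.integers(2, 9))
    letters = np.array(list(AA20 + "-"))
    p = np.full(21, (1 - gap_prob) / 20)
    p[20] = gap_prob
    while True:
        seqs = ["".join(letters[rng.choice(21, size=n_cols, p=p)])
                for _ in range(n_seqs)]
        if all(any(c != "-" for c in s) for s in seqs):
            return Alignment(tuple(f"s{i}" for i in range(n_seqs)), tuple(seqs))


@pytest.fixture
def rng():
    return np.random.default_rng(20131120)
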