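import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from sulfur_census.profiles import TrainingSet, build_profile
from sulfur_census.synthetic_data import (
    bundled_reference_families,
    synthetic_taxonomy,
)


@pytest.fixture(scope="session")
def references():
    """Bundled synthetic reference families (ancestors + training sets)."""
    return bundled_reference_families()


@pytest.fixture(scope="session")
def fixture_tree():
    """Rank-complete taxonomy of ~200 nodes for LCA tests."""
    tree, genus_ids = synthetic_taxonomy(n_genera_bacteria=60, n_genera_eukaryota=30)
    return tree, genus_ids


def random_tiny_profile(rng, max_model=3):
    """A profile built from a random tiny alignment (for oracle comparisons)."""
    from sulfur_census.alphabet import AMINO_ACIDS

    width = int(rng.integers(1, max_model + 1))
    n_seq = int(rng.integers(1, 4))
    rows = []
    for _ in range(n_seq):
        row = "".join(
            AMINO_ACIDS[rng.integers(20)] if rng.random() > 0.2 else "-"
            for _ in range(width)
        )
        rows.append(row)
    # force column 0 ungapped so at least one match column exists
    rows = [("A" if r[0] == "-" else r[0]) + r[1:] for r in rows]
    return build_profile(TrainingSet("tiny", rows))


def random_query(rng, max_len=3, with_x=True):
    from sulfur_census.alphabet import AMINO_ACIDS

    alphabet = AMINO_ACIDS + ("X" if with_x else "")
    return "".join(
        alphabet[rng.integers(len(alphabet))] for _ in range(int(rng.integers(1, max_len + 1)))
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20200218)
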