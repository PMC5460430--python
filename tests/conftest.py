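from __future__ import annotations

import numpy as np
import pytest
from hypothesis import strategies as st

from seedmat import GroupAlignment
from seedmat.alphabet import CANONICAL

EXTENDED_PLUS_GAP = CANONICAL + "BJZX-"


def make_group(*rows: str, gid: str = "g") -> GroupAlignment:
    return GroupAlignment.from_strings(
        gid, [(f"s{i}", row) for i, row in enumerate(rows)]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240229)


def random_freq_table(rng: np.random.Generator):
    """Strictly positive canonical frequency table (unordered-mass
    convention) with ambiguity rows left empty."""
    from seedmat.counting import FrequencyTable, compute_marginals

    upper = rng.dirichlet(np.ones(210)) + 1e-6
    upper /= upper.sum()
    p = np.zeros((24, 24))
    k = 0
    for a in range(20):
        for b in range(a, 20):
            p[a, b] = upper[k]
            p[b, a] = upper[k]
            k += 1
    return FrequencyTable(p=p, marginals=compute_marginals(p))


def aligned_rows(
    min_seqs: int = 2,
    max_seqs: int = 5,
    min_cols: int = 1,
    max_cols: int = 10,
    alphabet: str = EXTENDED_PLUS_GAP,
):
    """Hypothesis strategy: equal-length rows with at least one residue per
    row (all-gap sequences have no defined identity)."""

    def has_residues(rows: list[str]) -> bool:
        return all(any(ch != "-" for ch in row) for row in rows)

    return st.integers(min_cols, max_cols).flatmap(
        lambda L: st.lists(
            st.text(alphabet=alphabet, min_size=L, max_size=L),
            min_size=min_seqs,
            max_size=max_seqs,
        )
    ).filter(has_residues)
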