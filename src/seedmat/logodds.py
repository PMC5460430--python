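"""Log-odds scoring, relative entropy, and the final integer matrix.

Scores are log2 odds of the observed joint pair frequency against
independence,

    S(a, b) = log2 p(a, b) - log2( p(a) p(b) )

evaluated in the ordered-pair representation (off-diagonal unordered mass is
split in half), which makes the printed formula coincide with the
conventional factor-2 off-diagonal denominator of BLOSUM-style scoring.
The relative entropy H = sum p_ord(a,b) S(a,b) is the Kullback-Leibler
divergence in bits between the observed pairing distribution and
independence; the expected score E = sum p(a) p(b) S(a,b) must be negative
for a usable local-alignment matrix.

Ambiguity codes get scores from their own frequency cells against set
marginals p(Theta) = sum of member marginals, falling back to pooled member
frequencies when a cell carries no mass.  Entropy and expected score are
computed over the canonical block only — ambiguity rows are score outputs,
not probability mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .alphabet import EXTENDED, MEMBERSHIP, N_CANONICAL
from .errors import ZeroCellError

if TYPE_CHECKING:
    from .counting import FrequencyTable


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to the nearest integer, ties away from zero (so -2.5 -> -3)."""
    x = np.asarray(x, dtype=float)
    return np.copysign(np.floor(np.abs(x) + 0.5), x)


@dataclass
class SubstitutionMatrix:
    """Integer score table with its diagnostics and provenance."""

    alphabet: tuple[str, ...]
    scores_int: np.ndarray
    scores_raw: np.ndarray | None = None
    H: float | None = None              # relative entropy, bits
    E: float | None = None              # expected score, bits
    t: float | None = None              # clustering threshold used upstream
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores_int = np.asarray(self.scores_int, dtype=int)
        k = len(self.alphabet)
        if self.scores_int.shape != (k, k):
            raise ValueError("score table shape does not match alphabet")

    def index(self, symbol: str) -> int:
        return self.alphabet.index(symbol)

    def score(self, a: str, b: str) -> int:
        return int(self.scores_int[self.index(a), self.index(b)])

    def header_comments(self) -> list[str]:
        lines = ["substitution matrix (log2 odds, rounded)"]
        if self.t is not None:
            lines.append(f"clustering threshold t: {self.t:g}")
        if self.H is not None:
            lines.append(f"relative entropy H (bits): {self.H:.4f}")
        if self.E is not None:
            lines.append(f"expected score E (bits): {self.E:.4f}")
        for key, value in self.meta.items():
            lines.append(f"{key}: {value}")
        return lines


def marginals(f: "FrequencyTable") -> np.ndarray:
    """Per-symbol frequencies: canonical residues from the ordered joint,
    ambiguity codes as sums over their member residues."""
    from .counting import compute_marginals

    return compute_marginals(f.p)


def score_matrix(
    f: "FrequencyTable",
    *,
    t: float | None = None,
    pseudocount: float = 0.0,
    rounding: str = "half-away",
    bits_per_unit: float = 1.0,
) -> SubstitutionMatrix:
    """Turn a frequency table into the rounded integer matrix.

    A zero canonical cell makes the log undefined; by default this is a hard
    error listing the offending pairs (the remedy is more data or a higher
    clustering threshold).  ``pseudocount`` adds a flat epsilon of unordered
    mass to every canonical cell (then renormalizes) for experimentation.
    ``bits_per_unit`` sets the output scale: 1.0 gives whole-bit scores (the
    default); 0.5 emits half-bit units for ecosystem compatibility.
    """
    from .counting import compute_marginals, ordered_joint, ordered_total

    p = np.array(f.p, dtype=float)
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if pseudocount > 0:
        p[:N_CANONICAL, :N_CANONICAL] += pseudocount
        p /= ordered_total(p[:N_CANONICAL, :N_CANONICAL])
    marg = compute_marginals(p)

    canon_ord = ordered_joint(p[:N_CANONICAL, :N_CANONICAL])
    zero_mask = canon_ord == 0.0
    if zero_mask.any():
        pairs = [
            (EXTENDED[a], EXTENDED[b])
            for a, b in zip(*np.nonzero(np.triu(zero_mask)))
        ]
        raise ZeroCellError(pairs)

    p_ord = ordered_joint(p)
    # pooled member frequencies: fallback for empty ambiguity cells
    pooled = MEMBERSHIP @ canon_ord @ MEMBERSHIP.T
    cell = np.where(p_ord > 0.0, p_ord, pooled)
    if np.any(cell <= 0.0):
        raise ZeroCellError(
            [(EXTENDED[a], EXTENDED[b]) for a, b in zip(*np.nonzero(cell <= 0.0))]
        )
    with np.errstate(divide="ignore"):
        raw = np.log2(cell) - np.log2(np.outer(marg, marg))

    if rounding == "half-away":
        ints = round_half_away(raw / bits_per_unit).astype(int)
    elif rounding == "half-even":
        ints = np.rint(raw / bits_per_unit).astype(int)
    else:
        raise ValueError(f"unknown rounding mode {rounding!r}")

    canon_raw = raw[:N_CANONICAL, :N_CANONICAL]
    H = float(np.sum(canon_ord * canon_raw))
    indep = np.outer(marg[:N_CANONICAL], marg[:N_CANONICAL])
    E = float(np.sum(indep * canon_raw))
    meta = dict(f.meta)
    meta.update(
        {
            "input digest": f.digest(),
            "rounding": rounding,
            "bits per unit": bits_per_unit,
            "pseudocount": pseudocount,
        }
    )
    return SubstitutionMatrix(
        alphabet=tuple(EXTENDED),
        scores_int=ints,
        scores_raw=raw,
        H=H,
        E=E,
        t=t,
        meta=meta,
    )


def relative_entropy(f: "FrequencyTable", s: SubstitutionMatrix | None = None) -> float:
    """H = sum over canonical ordered pairs of p_ord(a,b) * S_raw(a,b), bits."""
    from .counting import ordered_joint

    if s is None or s.scores_raw is None:
        s = score_matrix(f)
    canon_ord = ordered_joint(np.asarray(f.p)[:N_CANONICAL, :N_CANONICAL])
    canon_ord = canon_ord / canon_ord.sum()
    return float(np.sum(canon_ord * s.scores_raw[:N_CANONICAL, :N_CANONICAL]))


def expected_score(f: "FrequencyTable", s: SubstitutionMatrix | None = None) -> float:
    """E = sum p(a) p(b) S_raw(a,b) over canonical pairs, bits (negative for
    any non-degenerate matrix)."""
    if s is None or s.scores_raw is None:
        s = score_matrix(f)
    marg = np.asarray(f.marginals)[:N_CANONICAL]
    return float(
        np.sum(np.outer(marg, marg) * s.scores_raw[:N_CANONICAL, :N_CANONICAL])
    )
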