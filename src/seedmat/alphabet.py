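"""Extended amino-acid alphabet and input canonicalization.

The working alphabet has 24 residue symbols: the 20 canonical amino acids in
the classical matrix order ``A R N D C Q E G H I L K M F P S T W Y V``
followed by the ambiguity codes ``B`` (= N or D), ``J`` (= I or L),
``Z`` (= E or Q) and ``X`` (= any).  Gaps — whether spelled ``-`` or ``.`` in
the input — share one internal gap code.

Sequences are stored as small integer code vectors (``numpy.int8``); all
counting and scoring modules index their tables with these codes.
"""

from __future__ import annotations

import numpy as np

from .errors import AlphabetError

CANONICAL: str = "ARNDCQEGHILKMFPSTWYV"
AMBIGUITY_SETS: dict[str, str] = {
    "B": "ND",
    "J": "IL",
    "Z": "EQ",
    "X": CANONICAL,
}
EXTENDED: str = CANONICAL + "BJZX"
GAP: str = "-"
STOP: str = "*"

N_CANONICAL = len(CANONICAL)          # 20
N_EXTENDED = len(EXTENDED)            # 24
GAP_CODE = N_EXTENDED                 # 24, outside every scoring table

CODE_OF: dict[str, int] = {ch: i for i, ch in enumerate(EXTENDED)}
CODE_OF[GAP] = GAP_CODE

#: For each extended code, the canonical member codes of its ambiguity set
#: (a canonical symbol is a singleton set containing itself).
MEMBER_CODES: tuple[np.ndarray, ...] = tuple(
    np.array(
        [CODE_OF[m] for m in AMBIGUITY_SETS.get(sym, sym)],
        dtype=np.intp,
    )
    for sym in EXTENDED
)

#: |Theta_x| for every extended code.
SET_SIZES: np.ndarray = np.array([len(m) for m in MEMBER_CODES], dtype=float)

#: Membership matrix E (24 x 20): E[x, a] = 1 iff canonical a is in Theta_x.
MEMBERSHIP: np.ndarray = np.zeros((N_EXTENDED, N_CANONICAL))
for _x, _members in enumerate(MEMBER_CODES):
    MEMBERSHIP[_x, _members] = 1.0
del _x, _members


def is_ambiguous(code: int) -> bool:
    return N_CANONICAL <= code < N_EXTENDED


def canonicalize_char(
    ch: str,
    *,
    nonstandard: str = "x",
    stop: str = "error",
) -> int:
    """Map one input character to its alphabet code.

    Lowercase letters are uppercased and both gap spellings (``-``, ``.``)
    merge into the gap code.  ``nonstandard`` controls the rare residues
    selenocysteine (U) and pyrrolysine (O): ``"x"`` maps them to X,
    ``"error"`` rejects them.  ``stop`` controls ``*``: ``"error"`` rejects
    it, ``"gap"`` drops the residue by treating it as a gap.

    The mapping is total: every character either yields exactly one code or
    raises :class:`AlphabetError`.
    """
    if ch in (".", "-"):
        return GAP_CODE
    up = ch.upper()
    code = CODE_OF.get(up)
    if code is not None:
        return code
    if up in ("U", "O"):
        if nonstandard == "x":
            return CODE_OF["X"]
        raise AlphabetError(f"nonstandard residue {ch!r} rejected under strict policy")
    if up == STOP:
        if stop == "gap":
            return GAP_CODE
        raise AlphabetError("stop character '*' in sequence (set stop='gap' to drop it)")
    raise AlphabetError(f"unknown sequence character {ch!r}")


def encode(sequence: str, *, nonstandard: str = "x", stop: str = "error") -> np.ndarray:
    """Canonicalize a row of an alignment into an int8 code vector."""
    return np.array(
        [canonicalize_char(ch, nonstandard=nonstandard, stop=stop) for ch in sequence],
        dtype=np.int8,
    )


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode` on canonical output (gap prints as ``-``)."""
    return "".join(GAP if c == GAP_CODE else EXTENDED[c] for c in np.asarray(codes))
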