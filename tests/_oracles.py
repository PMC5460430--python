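"""Independent brute-force oracles used by the test suite.

Everything here operates on decoded strings / plain Python dictionaries and
is written from the definitions, deliberately sharing no code path with the
package implementation it checks.
"""

from __future__ import annotations

import itertools
from collections import defaultdict

CANONICAL = "ARNDCQEGHILKMFPSTWYV"
AMBIG = {"B": "ND", "J": "IL", "Z": "EQ", "X": CANONICAL}


def identity_fraction(a: str, b: str) -> float:
    """Phi from the definition: identical non-gap symbols over the shorter
    residue count."""
    phi = sum(
        1 for x, y in zip(a, b) if x == y and x != "-" and y != "-"
    )
    lam_a = sum(1 for x in a if x != "-")
    lam_b = sum(1 for x in b if x != "-")
    return phi / min(lam_a, lam_b)


def cluster_components(rows: list[str], t: float) -> list[int]:
    """Connected components over the 'at least t% identical' graph, grown by
    naive repeated merging (order-independent fixed point)."""
    s = len(rows)
    comp = list(range(s))
    changed = True
    while changed:
        changed = False
        for i, j in itertools.combinations(range(s), 2):
            if 100.0 * identity_fraction(rows[i], rows[j]) >= t:
                if comp[i] != comp[j]:
                    old, new = comp[j], comp[i]
                    comp = [new if c == old else c for c in comp]
                    changed = True
    return comp


def pair_counts(
    rows: list[str], labels: list[int]
) -> tuple[dict[tuple[str, str], float], float]:
    """Triple loop over (column, i, j): cluster-weighted counts keyed by the
    unordered symbol pair, with equal-share ambiguity redistribution."""
    sizes: dict[int, int] = defaultdict(int)
    for c in labels:
        sizes[c] += 1
    n: dict[tuple[str, str], float] = defaultdict(float)
    total = 0.0
    s = len(rows)
    L = len(rows[0])
    for l in range(L):
        for i in range(s):
            for j in range(i + 1, s):
                a, b = rows[i][l], rows[j][l]
                if a == "-" or b == "-":
                    continue
                if labels[i] == labels[j]:
                    continue
                w = 1.0 / (sizes[labels[i]] * sizes[labels[j]])
                total += w
                n[_key(a, b)] += w
                if a in AMBIG or b in AMBIG:
                    ea = AMBIG.get(a, a)
                    eb = AMBIG.get(b, b)
                    share = w / (len(ea) * len(eb))
                    for x in ea:
                        for y in eb:
                            n[_key(x, y)] += share
    return dict(n), total


def _key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def corrected_frequencies(
    n: dict[tuple[str, str], float], total: float
) -> dict[tuple[str, str], float]:
    """Mu-corrected frequencies from the counts, by explicit set sums."""
    symbols = CANONICAL + "BJZX"
    p: dict[tuple[str, str], float] = {}
    for x in symbols:
        for y in symbols:
            members_x = AMBIG.get(x, x)
            members_y = AMBIG.get(y, y)
            block = sum(
                n.get(_key(a, b), 0.0) for a in members_x for b in members_y
            )
            direct = n.get(_key(x, y), 0.0)
            mu = (block - direct) / (len(members_x) * len(members_y))
            p[_key(x, y)] = (mu + direct) / total
    return p


def longest_valid_prefix_coverage(
    records: list[tuple[str, str, float]],
    sf: dict[str, str],
    epq: float,
) -> float:
    """Coverage from the definition: enumerate every prefix of the stably
    E-value-sorted list, keep the longest whose false-positive count fits the
    budget, then average the quadratically normalized true-positive tallies."""
    order = sorted(range(len(records)), key=lambda k: records[k][2])
    ranked = [records[k] for k in order]
    budget = epq * len(sf)
    best = 0
    for p in range(len(ranked) + 1):
        fp = sum(1 for q, t, _ in ranked[:p] if sf[q] != sf[t])
        if fp <= budget:
            best = p
    sizes: dict[str, int] = defaultdict(int)
    for fam in sf.values():
        sizes[fam] += 1
    tp: dict[str, int] = defaultdict(int)
    for q, t, _ in ranked[:best]:
        if sf[q] == sf[t]:
            tp[sf[q]] += 1
    eligible = [fam for fam, s in sizes.items() if s >= 2]
    return sum(tp[fam] / (sizes[fam] ** 2 - sizes[fam]) for fam in eligible) / len(
        eligible
    )


def aligned_pairs(rows: dict[str, str]) -> set[tuple[str, int, str, int]]:
    """Every residue pair an MSA aligns, as (id1, ordinal1, id2, ordinal2)."""
    ordinals: dict[str, list[int | None]] = {}
    for sid, seq in rows.items():
        k = 0
        cols: list[int | None] = []
        for ch in seq:
            if ch == "-":
                cols.append(None)
            else:
                cols.append(k)
                k += 1
        ordinals[sid] = cols
    pairs: set[tuple[str, int, str, int]] = set()
    ids = sorted(rows)
    L = len(next(iter(rows.values())))
    for l in range(L):
        for a, b in itertools.combinations(ids, 2):
            oa, ob = ordinals[a][l], ordinals[b][l]
            if oa is not None and ob is not None:
                pairs.add((a, oa, b, ob))
    return pairs
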