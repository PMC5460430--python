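"""Cluster-weighted pair counting, ambiguity redistribution and normalization.

For every alignment column and every cross-cluster sequence pair whose two
symbols are both residues, the pair's cluster weight ``w`` is added to the
count table: once to the cell of the observed symbols (which may be an
ambiguity code such as B), and — when at least one side is ambiguous —
additionally spread over the canonical expansions, ``w / (|Theta_x| |Theta_y|)``
per canonical combination.  A single observed A-B pair between two singleton
clusters therefore yields n(A,N) = n(A,D) = 0.5 and n(A,B) = 1, while the
normalizer N_k grows by exactly 1: each observed pairing is counted once.

Group frequencies then apply the double-counting correction

    mu_k(x, y) = ( sum_{a in Theta_x} sum_{b in Theta_y} n_k(a, b) - n_k(x, y) )
                 / ( |Theta_x| |Theta_y| )
    p_k(x, y)  = ( mu_k(x, y) + n_k(x, y) ) / N_k

whose mu term vanishes identically on canonical-canonical cells.  Groups are
finally summed and rescaled into one global frequency table.

Table convention: all tables are symmetric over the 24-symbol extended
alphabet and a cell holds the *unordered* pair mass (it appears at both
``[x, y]`` and ``[y, x]``).  Totals therefore weight off-diagonal cells by
one half; :func:`ordered_joint` converts to the ordered representation used
for scoring.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable

import numpy as np

from .alphabet import (
    EXTENDED,
    GAP_CODE,
    MEMBER_CODES,
    MEMBERSHIP,
    N_CANONICAL,
    N_EXTENDED,
    SET_SIZES,
)
from .clustering import ClusterAssignment, weight_matrix
from .errors import ZeroObservationsError

if TYPE_CHECKING:
    from .msa_io import GroupAlignment


def ordered_joint(p: np.ndarray) -> np.ndarray:
    """Ordered-pair representation: diagonal kept, off-diagonal mass halved."""
    out = p / 2.0
    np.fill_diagonal(out, np.diagonal(p))
    return out


def ordered_total(p: np.ndarray) -> float:
    """Total unordered mass of a symmetric table (off-diagonals count once)."""
    return float(ordered_joint(p).sum())


def compute_marginals(p: np.ndarray) -> np.ndarray:
    """Per-symbol marginals of a 24 x 24 table.

    A canonical marginal sums its conservation cell and half of every
    substitution cell, p(a) = p(a,a) + 1/2 sum_{b != a} p(a,b); an ambiguity
    code's marginal is the sum over its member residues.
    """
    canon = ordered_joint(p[:N_CANONICAL, :N_CANONICAL]).sum(axis=1)
    return MEMBERSHIP @ canon


@dataclass
class PairCounts:
    """Weighted, ambiguity-redistributed pair counts of one group."""

    group_id: str
    n: np.ndarray          # (24, 24) symmetric, unordered-mass convention
    N_k: float             # total weighted observed pairings
    s_k: int               # sequences in the group (for per-sequence mode)


@dataclass
class GroupFrequencies:
    """Normalized pair frequencies p_k of one group (24 x 24 symmetric)."""

    group_id: str
    p: np.ndarray


@dataclass
class FrequencyTable:
    """Database-wide joint pair frequencies and marginals.

    The canonical 20 x 20 block carries unordered mass summing to one;
    ambiguity-code rows re-express mass that is already distributed over the
    canonical block and are kept only to score those symbols.
    """

    p: np.ndarray                      # (24, 24) symmetric
    marginals: np.ndarray              # (24,)
    meta: dict = field(default_factory=dict)

    def digest(self) -> str:
        return hashlib.sha256(np.ascontiguousarray(self.p).tobytes()).hexdigest()[:12]


def count_group_pairs(g: "GroupAlignment", c: ClusterAssignment) -> PairCounts:
    """Accumulate one group's weighted pair counts over all columns.

    Gap/residue and gap/gap pairings are skipped; every other pairing of two
    aligned symbols contributes its cluster weight, redistributed over
    canonical residues when an ambiguity code is involved.
    """
    if c.labels.shape[0] != g.s_k:
        raise ValueError("cluster assignment does not match the group")
    n = np.zeros((N_EXTENDED, N_EXTENDED))
    w_mat = weight_matrix(c)
    codes = g.codes
    non_gap = codes != GAP_CODE
    ambiguous = codes >= N_CANONICAL  # gap code sits above the ambiguity codes
    ambiguous &= non_gap
    N_k = 0.0
    s = g.s_k
    for i in range(s):
        for j in range(i + 1, s):
            w = w_mat[i, j]
            if w == 0.0:
                continue
            both = non_gap[i] & non_gap[j]
            if not both.any():
                continue
            a = codes[i][both].astype(np.intp)
            b = codes[j][both].astype(np.intp)
            N_k += w * a.size
            # direct observed-symbol counts (symmetric storage)
            np.add.at(n, (a, b), w)
            off = a != b
            np.add.at(n, (b[off], a[off]), w)
            # canonical redistribution where an ambiguity code is involved
            amb = ambiguous[i][both] | ambiguous[j][both]
            for x, y in zip(a[amb], b[amb]):
                _distribute(n, int(x), int(y), w)
    return PairCounts(group_id=g.group_id, n=n, N_k=N_k, s_k=g.s_k)


def _distribute(n: np.ndarray, x: int, y: int, w: float) -> None:
    """Spread weight w of an observed (x, y) pairing over Theta_x x Theta_y."""
    mx = MEMBER_CODES[x]
    my = MEMBER_CODES[y]
    share = w / (mx.size * my.size)
    for a in mx:
        for b in my:
            n[a, b] += share
            if a != b:
                n[b, a] += share


def group_frequencies(pc: PairCounts, mode: str = "per-observation") -> GroupFrequencies:
    """Normalize one group's counts into frequencies p_k.

    ``mode="per-observation"`` divides the mu-corrected counts by the total weighted
    pairings N_k (so the canonical block sums to one); ``mode="per-sequence"``
    divides the same corrected counts by the group's sequence count s_k, an
    alternative normalization that damps large groups by size rather than by
    observation count.
    """
    if mode not in ("per-observation", "per-sequence"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    if pc.N_k <= 0.0:
        raise ZeroObservationsError(
            f"group {pc.group_id!r}: no observed residue pairs (N_k = 0)"
        )
    canon = pc.n[:N_CANONICAL, :N_CANONICAL]
    block_sums = MEMBERSHIP @ canon @ MEMBERSHIP.T      # sum over set members
    mu = (block_sums - pc.n) / np.outer(SET_SIZES, SET_SIZES)
    denom = pc.N_k if mode == "per-observation" else float(pc.s_k)
    return GroupFrequencies(group_id=pc.group_id, p=(mu + pc.n) / denom)


def accumulate(groups: Iterable[GroupFrequencies], *, mode: str = "per-observation") -> FrequencyTable:
    """Sum per-group frequencies and rescale into the global table.

    The rescaling constant is the canonical block's unordered total, so the
    canonical sub-table sums to one; ambiguity-code cells (which double-
    represent canonical mass) are scaled by the same constant.
    """
    groups = list(groups)
    if not groups:
        raise ValueError("need at least one group")
    p = np.zeros((N_EXTENDED, N_EXTENDED))
    for gf in groups:
        p += gf.p
    total = ordered_total(p[:N_CANONICAL, :N_CANONICAL])
    if total <= 0.0:
        raise ZeroObservationsError("no canonical pair mass accumulated")
    p /= total
    marginals = compute_marginals(p)
    canon_ord = ordered_joint(p[:N_CANONICAL, :N_CANONICAL])
    zeros = [
        (EXTENDED[a], EXTENDED[b])
        for a in range(N_CANONICAL)
        for b in range(a, N_CANONICAL)
        if canon_ord[a, b] == 0.0
    ]
    return FrequencyTable(
        p=p,
        marginals=marginals,
        meta={"mode": mode, "n_groups": len(groups), "zero_cells": zeros},
    )
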