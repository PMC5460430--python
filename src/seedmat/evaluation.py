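"""Homology-search benchmark statistics and MSA quality scoring.

Given a hit list of (query, target, E-value) relations over a database whose
sequences carry SCOP-style superfamily labels, the coverage

    Q = (1/S) * sum_i  t_i / (s_i^2 - s_i)

is the quadratically normalized fraction of true same-superfamily relations
retrieved after truncating the E-value-ranked list at a false-positive
budget of ``epq`` errors per query (0.01 epq admits one false positive per
100 queries).  Superfamily ``i`` holds ``s_i`` sequences and contributes
``t_i`` retained true-positive relations; singletons (s_i < 2) have no
retrievable relations and are excluded from the average.

Uncertainty of Q under changes of database composition is estimated by a
Bayesian bootstrap: per replicate, flat-Dirichlet sequence weights reweight
each retained true-positive relation by the product of its two sequence
weights, against the correspondingly weighted quadratic superfamily
normalization.  Differences between two matrices' coverage distributions are
expressed as Z = (Qbar_M - Qbar_P) / sqrt((var_M + var_P) / N).

The q-score compares a test MSA against a trusted reference: the fraction of
residue pairs aligned in the reference that the test aligns identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np
import pandas as pd

from .alphabet import GAP_CODE

if TYPE_CHECKING:
    from .msa_io import GroupAlignment


@dataclass
class HitList:
    """E-value-ranked homology relations plus the superfamily labelling.

    Self-hits are removed and duplicate (query, target) relations deduplicated
    (keeping the best E-value) at construction; E-values must be finite.
    """

    query: np.ndarray
    target: np.ndarray
    e_value: np.ndarray
    superfamily_of: dict[str, str]

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, str, float]],
        superfamily_of: Mapping[str, str],
    ) -> "HitList":
        rows = list(records)
        sf = dict(superfamily_of)
        unlabeled = sorted(
            {sid for q, t, _ in rows for sid in (q, t) if sid not in sf}
        )
        if unlabeled:
            raise KeyError(f"ids without superfamily label: {unlabeled[:10]}")
        seen: set[tuple[str, str]] = set()
        q_out: list[str] = []
        t_out: list[str] = []
        e_out: list[float] = []
        order = sorted(range(len(rows)), key=lambda k: rows[k][2])
        for k in order:
            q, t, e = rows[k]
            if q == t:
                continue
            if not np.isfinite(e):
                raise ValueError(f"non-finite E-value for relation ({q}, {t})")
            if (q, t) in seen:
                continue
            seen.add((q, t))
            q_out.append(q)
            t_out.append(t)
            e_out.append(float(e))
        return cls(
            query=np.array(q_out, dtype=object),
            target=np.array(t_out, dtype=object),
            e_value=np.array(e_out, dtype=float),
            superfamily_of=sf,
        )

    def __len__(self) -> int:
        return self.query.size


@dataclass
class CoverageResult:
    """Coverage Q with its per-superfamily tallies and list cutoff."""

    Q: float
    t_i: dict[str, int]
    s_i: dict[str, int]
    cutoff_index: int
    n_queries: int
    mean: float | None = None
    variance: float | None = None


def _sorted_order(h: HitList) -> np.ndarray:
    # stable: equal E-values keep construction (input) order
    return np.argsort(h.e_value, kind="stable")


def _retained_prefix(h: HitList, epq: float) -> tuple[np.ndarray, int, int]:
    """Indices (sorted by E-value) of the longest prefix whose false-positive
    count stays within the epq budget."""
    if epq <= 0:
        raise ValueError("epq must be positive")
    n_queries = len(h.superfamily_of)
    order = _sorted_order(h)
    sf_q = np.array([h.superfamily_of[q] for q in h.query[order]], dtype=object)
    sf_t = np.array([h.superfamily_of[t] for t in h.target[order]], dtype=object)
    is_fp = sf_q != sf_t
    cum_fp = np.cumsum(is_fp)
    budget = epq * n_queries
    cutoff = int(np.searchsorted(cum_fp, budget, side="right"))
    return order[:cutoff], cutoff, n_queries


def coverage_at_epq(h: HitList, epq: float = 0.01) -> CoverageResult:
    """Quadratically normalized coverage at a fixed errors-per-query cutoff."""
    retained, cutoff, n_queries = _retained_prefix(h, epq)
    s_i: dict[str, int] = {}
    for sid, sf in h.superfamily_of.items():
        s_i[sf] = s_i.get(sf, 0) + 1
    eligible = {sf for sf, s in s_i.items() if s >= 2}
    if not eligible:
        raise ValueError("no superfamily with at least two sequences")
    t_i = {sf: 0 for sf in s_i}
    for k in retained:
        sf_q = h.superfamily_of[h.query[k]]
        if sf_q == h.superfamily_of[h.target[k]]:
            t_i[sf_q] += 1
    Q = float(
        np.mean([t_i[sf] / (s_i[sf] ** 2 - s_i[sf]) for sf in sorted(eligible)])
    )
    return CoverageResult(
        Q=Q, t_i=t_i, s_i=s_i, cutoff_index=cutoff, n_queries=n_queries
    )


def bootstrap_coverage(
    h: HitList,
    reps: int = 500,
    seed: int = 0,
    *,
    epq: float = 0.01,
    equal_weights: bool = False,
) -> tuple[float, float]:
    """Concerted Bayesian bootstrap of the coverage.

    Per replicate, sequence weights are drawn from a flat Dirichlet over all
    labelled sequences; each retained true-positive relation is weighted by
    ``w_query * w_target`` and superfamily ``i``'s denominator becomes the
    weighted quadratic normalization ``(sum w)^2 - sum w^2`` over its
    members.  With equal weights this reduces exactly to the unweighted Q
    (the ``equal_weights`` switch exists for that degenerate-limit check).
    Returns the sample mean and variance over replicates.
    """
    if reps < 2:
        raise ValueError("need at least two bootstrap replicates")
    seqs = sorted(h.superfamily_of)
    n = len(seqs)
    if n < 2:
        raise ValueError("bootstrap needs at least two labelled sequences")
    seq_idx = {sid: k for k, sid in enumerate(seqs)}
    sf_names = sorted({sf for sf, s in _sf_sizes(h).items() if s >= 2})
    if not sf_names:
        raise ValueError("no superfamily with at least two sequences")
    sf_idx = {sf: k for k, sf in enumerate(sf_names)}
    member_of = np.array(
        [sf_idx.get(h.superfamily_of[sid], -1) for sid in seqs], dtype=int
    )

    retained, _, _ = _retained_prefix(h, epq)
    tp_q: list[int] = []
    tp_t: list[int] = []
    tp_sf: list[int] = []
    for k in retained:
        sf = h.superfamily_of[h.query[k]]
        if sf == h.superfamily_of[h.target[k]] and sf in sf_idx:
            tp_q.append(seq_idx[h.query[k]])
            tp_t.append(seq_idx[h.target[k]])
            tp_sf.append(sf_idx[sf])
    tp_q_arr = np.array(tp_q, dtype=int)
    tp_t_arr = np.array(tp_t, dtype=int)
    tp_sf_arr = np.array(tp_sf, dtype=int)

    rng = np.random.default_rng(seed)
    n_sf = len(sf_names)
    qs = np.empty(reps)
    for r in range(reps):
        w = np.full(n, 1.0 / n) if equal_weights else rng.dirichlet(np.ones(n))
        num = np.zeros(n_sf)
        if tp_q_arr.size:
            np.add.at(num, tp_sf_arr, w[tp_q_arr] * w[tp_t_arr])
        w_sum = np.zeros(n_sf)
        w_sq = np.zeros(n_sf)
        ok = member_of >= 0
        np.add.at(w_sum, member_of[ok], w[ok])
        np.add.at(w_sq, member_of[ok], w[ok] ** 2)
        den = w_sum**2 - w_sq
        qs[r] = float(np.mean(num / den))
    return float(qs.mean()), float(qs.var(ddof=1))


def _sf_sizes(h: HitList) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for sf in h.superfamily_of.values():
        sizes[sf] = sizes.get(sf, 0) + 1
    return sizes


def z_score(
    mean_m: float, var_m: float, mean_p: float, var_p: float, n: int
) -> float:
    """Z = (Qbar_M - Qbar_P) / sqrt((var_M + var_P) / N); |Z| >= 1.96 marks a
    significant difference at the 95% level."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if var_m < 0 or var_p < 0:
        raise ValueError("variances must be non-negative")
    diff = mean_m - mean_p
    pooled = (var_m + var_p) / n
    if pooled == 0.0:
        if diff == 0.0:
            return 0.0
        warnings.warn("zero variance with differing means: Z is infinite")
        return float(np.copysign(np.inf, diff))
    return float(diff / np.sqrt(pooled))


def is_significant(z: float, level: float = 1.96) -> bool:
    return abs(z) >= level


# ---------------------------------------------------------------------------
# MSA quality


def q_score(test: "GroupAlignment", ref: "GroupAlignment") -> float:
    """Fraction of reference-aligned residue pairs reproduced by the test MSA.

    Residues are identified by (sequence id, residue ordinal); both MSAs must
    contain the same sequences with identical ungapped residues.
    """
    if sorted(test.ids) != sorted(ref.ids):
        raise ValueError("test and reference MSAs contain different sequences")
    t_rows = {sid: row for sid, row in zip(test.ids, test.codes)}
    # per sequence: column index of each residue ordinal, in both MSAs
    t_col: dict[str, np.ndarray] = {}
    r_col: dict[str, np.ndarray] = {}
    for sid, r_row in zip(ref.ids, ref.codes):
        t_row = t_rows[sid]
        r_res = r_row[r_row != GAP_CODE]
        t_res = t_row[t_row != GAP_CODE]
        if not np.array_equal(r_res, t_res):
            raise ValueError(f"sequence {sid!r}: residues differ between MSAs")
        r_col[sid] = np.flatnonzero(r_row != GAP_CODE)
        t_col[sid] = np.flatnonzero(t_row != GAP_CODE)

    # invert: reference column -> residue ordinal (or -1)
    r_ord = {
        sid: _column_to_ordinal(cols, ref.L) for sid, cols in r_col.items()
    }
    total = 0
    matched = 0
    ids = list(ref.ids)
    for i in range(len(ids)):
        oi = r_ord[ids[i]]
        ti = t_col[ids[i]]
        for j in range(i + 1, len(ids)):
            oj = r_ord[ids[j]]
            tj = t_col[ids[j]]
            both = (oi >= 0) & (oj >= 0)
            a = oi[both]
            b = oj[both]
            total += a.size
            matched += int(np.count_nonzero(ti[a] == tj[b]))
    if total == 0:
        raise ValueError("reference MSA aligns no residue pairs")
    return matched / total


def _column_to_ordinal(cols: np.ndarray, L: int) -> np.ndarray:
    out = np.full(L, -1, dtype=int)
    out[cols] = np.arange(cols.size)
    return out


# ---------------------------------------------------------------------------
# Tabular I/O


def read_hits_tsv(path: str | Path) -> list[tuple[str, str, float]]:
    """Read a hit list as TSV with columns query, target, e_value."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    needed = {"query", "target", "e_value"}
    if not needed.issubset(cols):
        raise ValueError(f"hit list must have columns {sorted(needed)}")
    return list(
        zip(df["query"].astype(str), df["target"].astype(str), df["e_value"])
    )


def read_superfamily_tsv(path: str | Path) -> dict[str, str]:
    """Read an id -> superfamily mapping as two-column TSV."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.lower() for c in df.columns]
    if not {"id", "superfamily"}.issubset(df.columns):
        raise ValueError("mapping must have columns id, superfamily")
    return dict(zip(df["id"].astype(str), df["superfamily"].astype(str)))
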