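"""Gap-aware percent-identity clustering of aligned sequences.

Redundant sequences inside one seed alignment would otherwise dominate the
pair counts, so sequences that are at least ``t`` % identical are merged into
clusters and every cross-cluster pair is down-weighted by the product of the
two cluster sizes (within-cluster pairs are dropped entirely).  A cluster is
thereby counted like a single sequence.

The unnormalized similarity between two aligned rows counts positions where
both carry the *same* non-gap symbol:

    phi(A, B) = sum_l  delta(a_l, b_l) [1 - delta(a_l, gap)] [1 - delta(b_l, gap)]

and the fractional identity Phi = phi / min(lambda_A, lambda_B), where
lambda is the residue (non-gap) count of a row.  Clusters are the connected
components of the graph with an edge wherever 100 * Phi >= t, i.e. the
transitive closure of the "at least t % similar to some member" rule — an
order-independent formulation of single-linkage merging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .alphabet import GAP_CODE
from .errors import AllGapSequenceError

if TYPE_CHECKING:
    from .msa_io import GroupAlignment


def pair_similarity(a: np.ndarray, b: np.ndarray) -> tuple[int, float]:
    """Identity count ``phi`` and fraction ``Phi`` of two aligned code rows.

    Identical ambiguity codes (B vs B) count as a match; an ambiguity code
    against one of its members (B vs N) does not — the Kronecker delta acts
    on symbols, not on the sets behind them.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("aligned rows must have equal length")
    non_gap = (a != GAP_CODE) & (b != GAP_CODE)
    phi = int(np.count_nonzero(non_gap & (a == b)))
    lam_a = int(np.count_nonzero(a != GAP_CODE))
    lam_b = int(np.count_nonzero(b != GAP_CODE))
    shorter = min(lam_a, lam_b)
    if shorter == 0:
        raise AllGapSequenceError("similarity undefined: one row has no residues")
    return phi, phi / shorter


def similarity_counts(g: "GroupAlignment") -> tuple[np.ndarray, np.ndarray]:
    """Pairwise identity counts ``phi`` (s x s, int) and residue counts
    ``lambda`` (s,) for a whole group."""
    codes = g.codes
    s = g.s_k
    lam = np.count_nonzero(codes != GAP_CODE, axis=1)
    if np.any(lam == 0):
        empty = [g.ids[i] for i in np.flatnonzero(lam == 0)]
        raise AllGapSequenceError(
            f"group {g.group_id!r}: all-gap sequence(s) {empty}"
        )
    phi = np.zeros((s, s), dtype=np.int64)
    non_gap = codes != GAP_CODE
    for i in range(s):
        both = non_gap[i] & non_gap[i + 1 :]
        match = (codes[i] == codes[i + 1 :]) & both
        phi[i, i + 1 :] = match.sum(axis=1)
    phi = phi + phi.T
    np.fill_diagonal(phi, lam)
    return phi, lam


@dataclass
class ClusterAssignment:
    """Partition of one group's sequences at clustering threshold t."""

    group_id: str
    t: float
    labels: np.ndarray        # cluster id per sequence index
    sizes: np.ndarray         # |c| per cluster id

    @property
    def n_clusters(self) -> int:
        return int(self.sizes.size)

    @property
    def size_of(self) -> np.ndarray:
        """Cluster size of each sequence's own cluster (s,)."""
        return self.sizes[self.labels]


def cluster_group(g: "GroupAlignment", t: float) -> ClusterAssignment:
    """Partition a group at threshold ``t`` (percent, inclusive comparison).

    The comparison ``100 * phi >= t * min(lambda_i, lambda_j)`` is carried
    out on the integer identity counts, so integer thresholds involve no
    floating-point rounding.
    """
    if not 0 <= t <= 100:
        raise ValueError("clustering threshold t must be in [0, 100]")
    phi, lam = similarity_counts(g)
    shorter = np.minimum.outer(lam, lam)
    adjacency = (100.0 * phi) >= (t * shorter)
    n, labels = connected_components(csr_matrix(adjacency), directed=False)
    sizes = np.bincount(labels, minlength=n)
    return ClusterAssignment(group_id=g.group_id, t=t, labels=labels, sizes=sizes)


def pair_weight(c: ClusterAssignment, i: int, j: int) -> float:
    """Henikoff cluster weight of the sequence pair (i, j).

    Zero for two members of one cluster (their substitutions are ignored),
    otherwise ``1 / (|c_x| * |c_y|)``.
    """
    if i == j:
        raise ValueError("self-pairs are never counted")
    if c.labels[i] == c.labels[j]:
        return 0.0
    return 1.0 / (c.sizes[c.labels[i]] * c.sizes[c.labels[j]])


def weight_matrix(c: ClusterAssignment) -> np.ndarray:
    """All pairwise weights as a symmetric (s, s) array with a zero diagonal."""
    size_of = c.size_of.astype(float)
    w = 1.0 / np.outer(size_of, size_of)
    same = c.labels[:, None] == c.labels[None, :]
    w[same] = 0.0
    return w
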