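"""End-to-end matrix construction: cluster, count, normalize, score."""

from __future__ import annotations

import warnings
from typing import Iterable

from .clustering import cluster_group
from .counting import (
    FrequencyTable,
    accumulate,
    count_group_pairs,
    group_frequencies,
)
from .errors import ZeroObservationsError
from .logodds import SubstitutionMatrix, score_matrix
from .msa_io import GroupAlignment


def build_frequency_table(
    groups: Iterable[GroupAlignment],
    t: float = 60,
    *,
    mode: str = "per-observation",
) -> FrequencyTable:
    """Cluster and count every group at threshold ``t``, then merge.

    Groups that contribute no residue pairs (e.g. everything collapsed into
    one cluster) are skipped with a warning, mirroring how degenerate seed
    alignments are handled in practice.
    """
    per_group = []
    for g in groups:
        assignment = cluster_group(g, t)
        counts = count_group_pairs(g, assignment)
        try:
            per_group.append(group_frequencies(counts, mode=mode))
        except ZeroObservationsError:
            warnings.warn(
                f"group {g.group_id!r} skipped: no cross-cluster residue pairs",
                stacklevel=2,
            )
    if not per_group:
        raise ZeroObservationsError("no group contributed any residue pairs")
    table = accumulate(per_group, mode=mode)
    table.meta["t"] = t
    return table


def build_matrix(
    groups: Iterable[GroupAlignment],
    t: float = 60,
    *,
    mode: str = "per-observation",
    pseudocount: float = 0.0,
    rounding: str = "half-away",
    bits_per_unit: float = 1.0,
) -> SubstitutionMatrix:
    """Build the rounded log-odds matrix from seed alignments at threshold t."""
    table = build_frequency_table(groups, t, mode=mode)
    return score_matrix(
        table,
        t=t,
        pseudocount=pseudocount,
        rounding=rounding,
        bits_per_unit=bits_per_unit,
    )
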