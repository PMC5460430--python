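"""Seed-MSA simulator with a known ground-truth substitution structure.

Groups are generated column-independently: each column draws a latent
ancestor residue and every sequence emits a residue conditionally on it.
The emission kernel is the matrix square root of the reversible chain
implied by the target joint (J_half = D^{1/2} (D^{-1/2} J D^{-1/2})^{1/2}
D^{1/2}, D the diagonal of marginals), so that the joint distribution of
*any two* sequences at a column is exactly the configured ``target_joint``.
The log-odds table of that joint is therefore the recovery target for the
whole construction pipeline.

On top of the residue alignment the simulator injects geometric-length gap
runs, masks residues to their ambiguity codes, and appends exact duplicate
rows, emulating the gappy, partly redundant, occasionally ambiguous nature
of curated seed alignments.  No phylogeny is simulated — columns are
independent — which is sufficient to exercise counting, clustering and
normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import alphabet
from .msa_io import GroupAlignment

#: Background amino-acid frequencies, shrunk 70% toward uniform so that the
#: rarest pair types are still well observed at the default dataset scale.
_SWISSPROT_LIKE = {
    "A": 0.079, "R": 0.051, "N": 0.045, "D": 0.054, "C": 0.019,
    "Q": 0.043, "E": 0.063, "G": 0.074, "H": 0.022, "I": 0.051,
    "L": 0.091, "K": 0.057, "M": 0.022, "F": 0.039, "P": 0.052,
    "S": 0.071, "T": 0.058, "W": 0.013, "Y": 0.032, "V": 0.065,
}
_UNIFORM_SHRINK = 0.7

#: Biochemically similar residue classes used to give the default joint a
#: realistic off-diagonal structure (substitutions concentrate within class).
RESIDUE_CLASSES: tuple[str, ...] = ("AGSTP", "ILVM", "FWY", "KRH", "DE", "NQ", "C")

#: Ambiguity masking: residues with a two-letter code collapse to it, all
#: others mask to X.
_MASK_CODE = {}
for _code, _members in (("B", "ND"), ("Z", "EQ"), ("J", "IL")):
    for _m in _members:
        _MASK_CODE[alphabet.CODE_OF[_m]] = alphabet.CODE_OF[_code]


def default_background() -> np.ndarray:
    """Marginal residue frequencies of the default generator."""
    m = np.array([_SWISSPROT_LIKE[a] for a in alphabet.CANONICAL])
    m /= m.sum()
    return (1.0 - _UNIFORM_SHRINK) * m + _UNIFORM_SHRINK / m.size


def default_target_joint(
    conservation: float = 0.40,
    class_mix: float = 0.25,
    background_mix: float = 0.35,
) -> np.ndarray:
    """Mixture joint: conserved columns + within-class substitution +
    independent background, normalized to sum to one (ordered form)."""
    if not np.isclose(conservation + class_mix + background_mix, 1.0):
        raise ValueError("mixture weights must sum to 1")
    m = default_background()
    within = np.zeros((20, 20))
    for cls in RESIDUE_CLASSES:
        idx = [alphabet.CODE_OF[a] for a in cls]
        block = np.outer(m[idx], m[idx])
        within[np.ix_(idx, idx)] += block
    within /= within.sum()
    joint = (
        conservation * np.diag(m)
        + class_mix * within
        + background_mix * np.outer(m, m)
    )
    return joint / joint.sum()


@dataclass
class SimConfig:
    """Study conditions for one synthetic seed-alignment dataset.

    Defaults describe a mid-sized curated collection: 200 groups of 8
    sequences over 50 columns, 10% gap content in geometric runs of mean
    length 3, and ambiguity codes on 1% of residues.
    """

    n_groups: int = 200
    seqs_per_group: int | tuple[int, int] = 8
    L: int = 50
    target_joint: np.ndarray | None = None
    gap_rate: float = 0.1
    gap_run_mean: float = 3.0
    ambig_rate: float = 0.01
    duplicate_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_joint is None:
            self.target_joint = default_target_joint()
        J = np.asarray(self.target_joint, dtype=float)
        if J.shape != (20, 20):
            raise ValueError("target_joint must be 20 x 20")
        if not np.allclose(J, J.T, atol=1e-12):
            raise ValueError("target_joint must be symmetric")
        if np.any(J <= 0):
            raise ValueError("target_joint must be strictly positive")
        if not np.isclose(J.sum(), 1.0, atol=1e-9):
            raise ValueError("target_joint must sum to 1")
        self.target_joint = J / J.sum()
        for name in ("gap_rate", "ambig_rate", "duplicate_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.L < 1 or self.n_groups < 1:
            raise ValueError("need at least one column and one group")
        if self.gap_run_mean < 1.0:
            raise ValueError("gap_run_mean must be >= 1")


def _emission_kernel(joint: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Ancestor distribution and conditional emission rows from the matrix
    square root of the reversible chain behind ``joint``."""
    marg = joint.sum(axis=1)
    d = np.sqrt(marg)
    T = joint / np.outer(d, d)
    vals, vecs = np.linalg.eigh(T)
    half = vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None))) @ vecs.T
    j_half = np.clip(half * np.outer(d, d), 0.0, None)
    ancestor = j_half.sum(axis=1)
    ancestor /= ancestor.sum()
    conditional = j_half / j_half.sum(axis=1, keepdims=True)
    return ancestor, conditional


def simulate_group(cfg: SimConfig, group_index: int) -> GroupAlignment:
    """Deterministically generate one group for (cfg.seed, group_index)."""
    ss = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(group_index,))
    r_res, r_gap, r_amb, r_dup = (np.random.default_rng(c) for c in ss.spawn(4))

    if isinstance(cfg.seqs_per_group, tuple):
        lo, hi = cfg.seqs_per_group
        s = int(r_res.integers(lo, hi + 1))
    else:
        s = int(cfg.seqs_per_group)
    if s < 1:
        raise ValueError("groups must contain at least one sequence")
    L = cfg.L

    ancestor, conditional = _emission_kernel(cfg.target_joint)
    anc = r_res.choice(20, size=L, p=ancestor)
    cum = np.cumsum(conditional, axis=1)
    u = r_res.random((s, L))
    codes = (cum[anc][None, :, :] < u[:, :, None]).sum(axis=2).astype(np.int8)

    if cfg.gap_rate > 0:
        start_p = cfg.gap_rate / cfg.gap_run_mean
        for row in codes:
            l = 0
            while l < L:
                if r_gap.random() < start_p:
                    run = int(r_gap.geometric(1.0 / cfg.gap_run_mean))
                    row[l : l + run] = alphabet.GAP_CODE
                    l += run
                else:
                    l += 1
            if np.all(row == alphabet.GAP_CODE):  # keep every row scoreable
                keep = int(r_gap.integers(L))
                row[keep] = codes.dtype.type(anc[keep])

    if cfg.ambig_rate > 0:
        mask = (r_amb.random((s, L)) < cfg.ambig_rate) & (
            codes != alphabet.GAP_CODE
        )
        for i, l in zip(*np.nonzero(mask)):
            codes[i, l] = _MASK_CODE.get(
                int(codes[i, l]), alphabet.CODE_OF["X"]
            )

    ids = [f"g{group_index}_s{i}" for i in range(s)]
    if cfg.duplicate_rate > 0:
        dup = np.nonzero(r_dup.random(s) < cfg.duplicate_rate)[0]
        if dup.size:
            codes = np.vstack([codes, codes[dup]])
            ids += [f"g{group_index}_s{i}_dup" for i in dup]

    return GroupAlignment(group_id=f"group{group_index}", ids=ids, codes=codes)


def simulate_dataset(cfg: SimConfig) -> list[GroupAlignment]:
    """All ``cfg.n_groups`` groups of the configured dataset."""
    return [simulate_group(cfg, k) for k in range(cfg.n_groups)]


def without_duplicates(cfg: SimConfig) -> SimConfig:
    """The same study conditions with duplicate injection switched off."""
    return replace(cfg, duplicate_rate=0.0)


def ground_truth_logodds(cfg: SimConfig) -> np.ndarray:
    """log2 of the target joint (ordered form) over its marginal product —
    what the construction pipeline should recover."""
    J = np.asarray(cfg.target_joint)
    marg = J.sum(axis=1)
    return np.log2(J / np.outer(marg, marg))
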