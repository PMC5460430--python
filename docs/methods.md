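# Methods

This note documents the models, conventions and numerical choices behind
`seedmat`, and what the synthetic benchmarks do and do not demonstrate.

## Input model and canonicalization

A *group* is one curated seed MSA: equal-length rows over the 20 canonical
amino acids, the ambiguity codes B (= N/D), J (= I/L), Z (= E/Q), X (= any),
and gaps. Both gap spellings (`-`, `.`) merge into one internal gap symbol
and lowercase letters are uppercased, so Pfam-style insert-state columns are
treated as ordinary gapped columns. We found no principled reason to
discard insert states given that the counting stage skips gap pairings
anyway; a caller who wants them gone can drop columns before building.
Rare residues U (selenocysteine) and O (pyrrolysine) map to X by default
(`nonstandard="error"` rejects them); `*` is an error by default and can be
treated as a gap (`stop="gap"`), which drops just that residue rather than
the column. Canonicalization is total and idempotent: every character maps
to exactly one symbol or raises.

## Table convention

All pair tables are symmetric over the 24-symbol extended alphabet, and a
cell holds *unordered* pair mass (mirrored into both `[x,y]` and `[y,x]`).
Totals and marginals therefore weight off-diagonal cells by ½; the
*ordered* representation (diagonal kept, off-diagonal halved) is used for
scoring, which makes `S = log2 p_ord(a,b) − log2 p(a)p(b)` coincide with
the conventional factor-2 off-diagonal denominator of log-odds scoring.
Marginals are `p(a) = p(a,a) + ½ Σ_{b≠a} p(a,b)`; an ambiguity code's
marginal is the sum over its members. One consequence worth noting: a
third party that defines marginals without the ½ weighting of substitution
events will reproduce score rankings but not entropies to four decimals.

## Clustering and weighting

Identity between aligned rows counts positions carrying the *same non-gap
symbol* (identical ambiguity codes match; a code never matches one of its
members), normalized by the smaller residue count of the two rows.
Clusters at threshold *t* are the connected components of the graph with an
edge wherever `100·φ ≥ t·min(λ_i, λ_j)` — integer arithmetic for integer
*t*, so threshold comparisons are exact and inclusive ("at least *t* %").
Connected components make the partition order-independent, unlike a greedy
incremental pass. Cross-cluster pairs count with weight `1/(|c_x||c_y|)`;
within-cluster pairs are ignored. A consequence tested explicitly: adding
an exact duplicate of a sequence whose cluster otherwise contains only
identical copies leaves the final frequency table bit-for-bit unchanged
(the halved weights and the dropped within-cluster pair cancel). If the
cluster mixes non-identical members the cancellation is only approximate,
because the duplicate shifts that cluster's internal residue shares.

## Counting, ambiguity redistribution and normalization

Per column and cross-cluster pair with two residue symbols, the weight *w*
is added once to the observed-symbol cell; when an ambiguity code is
involved, *w* is additionally spread in equal shares `w/(|Θ_x||Θ_y|)` over
the canonical expansions. The normalizer N_k accumulates *w* once per
observed pairing. Group frequencies apply the correction

    μ(x,y) = ( Σ_{a∈Θ_x} Σ_{b∈Θ_y} n(a,b) − n(x,y) ) / (|Θ_x||Θ_y|)
    p(x,y) = ( μ(x,y) + n(x,y) ) / N_k

μ vanishes identically on canonical cells; on ambiguity-code cells it adds
the block average of the member cells, which is also how those rows become
scoreable when no code was ever observed — the classical
"average the member frequencies" fallback emerges from the same formula.
The default denominator is N_k; `mode="per-sequence"` divides by the
group's sequence count instead (a historical alternative reading of group
size normalization — the two differ by the groups' relative pair yields,
and scores are not invariant to the choice, so both are exposed and the
per-observation normalization is the default). Accumulation sums the
per-group tables and rescales by the canonical block's unordered total;
ambiguity cells, which re-express canonical mass, are scaled by the same
constant and never enter entropy or normalization sums.

A deliberate limitation of equal-share redistribution, quantified in the
test suite: a masked member of an ambiguity set that is aligned to another
member (most often the *same* residue, e.g. B-from-N against a conserved N)
donates half its weight to the set's internal substitution cell. With 1%
masking this inflates the N–D, E–Q and I–L cells by tens of percent
(0.3–0.45 bits under the default generator) while every other canonical
score moves by well under 0.1 bit. The effect is proportional to the
masking rate, not to dataset size; at the ≪1% ambiguity rates of real
databases it is negligible.

## Scoring

Scores are computed in bits and rounded half-away-from-zero (the tie
behavior of "round to the next integer" is ambiguous; `rounding="half-even"`
is available, and `bits_per_unit=0.5` emits half-bit units for ecosystem
compatibility). A zero canonical cell is a hard error listing the
offending pairs — the honest remedy is more data or a higher clustering
threshold, matching the practice of discarding matrices built at thresholds
that leave substitutions unobserved; an additive pseudocount is available
for experimentation only. Relative entropy `H = Σ p_ord S_raw` over the
canonical block equals the KL divergence between the observed pairing
distribution and independence (checked against an independent KL oracle at
1e−10); the expected score `E = Σ p(a)p(b) S_raw` is necessarily ≤ 0 and
strictly negative for any non-product table.

## Evaluation statistics

*Coverage.* Hit lists are sorted by E-value ascending with ties kept in
input order (determinism); self-hits are removed and duplicate ordered
relations deduplicated keeping the best E-value. "Errors per query" counts
erroneous *relations*, and the query denominator is the number of labelled
database sequences (every sequence is searched). The list is truncated at
the longest prefix whose false-positive count stays within `epq ×
n_queries`; retained true positives are tallied per the query's
superfamily and averaged as `t_i/(s_i²−s_i)` over superfamilies with at
least two members. True/false labels are strict same/different-superfamily
by default.

*Bootstrap.* Per replicate, sequence weights are drawn from a flat
Dirichlet; each retained true-positive relation is weighted `w_q·w_t`
against the per-superfamily denominator `(Σw)²−Σw²`. The retained set is
fixed from the unweighted cutoff (the reweighting varies database
composition, not the ranking), and the quadratic form reduces exactly to
the unweighted coverage at equal weights — a degenerate-limit switch exists
for that check. Sample mean and variance (ddof = 1) feed the Z-score; with
both variances zero and equal means Z is 0, with differing means it is
signed infinity with a warning.

*q-score.* Residues are identified by (sequence id, residue ordinal); the
score is the fraction of reference-aligned residue pairs the test MSA
aligns identically, after verifying both MSAs carry the same ungapped
sequences.

## Synthetic generator

Columns are independent: each draws a latent ancestor residue and every
sequence emits conditionally on it. The emission kernel is built from the
matrix square root of the reversible chain behind the configured joint
(`J_half = D^{1/2}(D^{-1/2} J D^{-1/2})^{1/2} D^{1/2}`), so the joint
distribution of any *pair* of sequences at a column equals the target joint
exactly — emitting from the target's own conditional instead would make a
sequence pair two Markov steps apart and bias recovery toward a
time-doubled matrix. Eigenvalues are clipped at zero and the kernel's rare
negative round-off entries truncated; the default joint is comfortably
positive definite.

The default joint is a three-part mixture — 40% conserved columns, 25%
within-class substitution over seven biochemical classes (AGSTP, ILVM,
FWY, KRH, DE, NQ, C), 35% independent background — over background
frequencies shrunk 70% toward uniform. The shrinkage keeps the rarest pair
types (W/C against anything) well observed at the default dataset size of
200 groups × 8 sequences × 50 columns, so recovery quality reflects the
estimator rather than starvation of single cells; mean pairwise identity
comes out near 49%, plausible for curated seed alignments. Gap runs start
at per-position rate `gap_rate/gap_run_mean` with geometric lengths (mean
3), giving ≈10% gap content by default; 1% of residues mask to their
ambiguity code (members of two-letter sets to B/Z/J, everything else to X);
duplicates are appended per-sequence with a configurable rate (off by
default). Each noise stage uses its own child RNG stream of
`(seed, group_index)`, so switching one stage off does not perturb the
others — which is what makes the ambiguity-perturbation and
duplicate-robustness comparisons exact.

What passing synthetic tests shows: counting, weighting, normalization and
scoring invert the generative model (raw-score correlation with the ground
truth exceeds 0.99 at the default scale, with errors shrinking as groups
are added). What it does not show: behavior under phylogenetic
correlation, column-rate heterogeneity, or alignment error — real seed
alignments have all three, and no claim about real-data matrix quality
follows from these tests alone.

## Problem sizes

Default test and example runs use the 200 × 8 × 50 generator scale
(≈ 250k weighted pairs, a few seconds on one CPU); oracle equivalence
tests run on exhaustive small inputs (≤ 5 sequences, ≤ 10 columns, ≤ 200
hit-list records) where brute-force enumeration is the reference.
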