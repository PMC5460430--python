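# seedmat

Amino-acid substitution matrices built from gapped, manually curated seed
multiple sequence alignments — plus the benchmark statistics used to compare
such matrices in homology search and MSA construction.

## The problem

Homology search tools (SSEARCH, BLAST) and MSA programs (MUSCLE, MAFFT)
score residue substitutions with a log-odds matrix. The classic matrices are
estimated from small, heavily filtered datasets: gapped columns are thrown
away and ambiguity codes (B, J, Z, X) are ignored. Curated seed alignments
— one expert-built MSA per protein family or domain ("group") — offer a far
larger and more diverse basis, but exploiting them requires handling gaps,
redundancy within a family, widely varying family sizes, and ambiguity
codes head-on. `seedmat` implements that construction and the statistics
needed to evaluate the result.

## The method

For residues *a*, *b* with joint pair frequency *p(a,b)* and marginals
*p(a)*, the score is the rounded log-odds

    S(a,b) = log2 p(a,b) − log2( p(a) p(b) )        [bits]

with *p* estimated per group and merged:

- **Clustering** — within a group, sequences at least *t* % identical
  (gap-aware identity Φ = φ / min(λ_A, λ_B), transitively closed) merge
  into clusters; a cross-cluster pair counts with weight 1/(|c_x||c_y|) and
  within-cluster pairs are ignored, so a cluster acts as one sequence.
- **Gaps** — only gap-containing *pairings* are skipped, never whole
  columns; indel regions still contribute.
- **Ambiguity codes** — an observed pair like A–B is counted once on the
  (A,B) cell and spread in equal shares over the canonical readings
  ((A,N) and (A,D) get 0.5 each); a correction term μ then removes the
  double representation when normalizing, so each observation carries unit
  mass.
- **Group normalization** — each group's counts are normalized (default: by
  its total weighted pair count) before summation, so huge families do not
  dominate.
- **Diagnostics** — relative entropy H = Σ p(a,b) S(a,b) (bits) and
  expected score E = Σ p(a)p(b) S(a,b) < 0 accompany every matrix.

Evaluation utilities implement the quadratically normalized coverage
**Q = (1/S) Σ t_i/(s_i² − s_i)** of an E-value-ranked hit list truncated at
a fixed errors-per-query budget, its Bayesian-bootstrap mean/variance with
flat-Dirichlet sequence weights, the Z-score
(Q̄_M − Q̄_P)/√((σ²_M+σ²_P)/N) for matrix comparisons, and the q-score (the
fraction of reference-aligned residue pairs a test MSA reproduces).

A synthetic generator (`seedmat.synthetic`) emits seed-alignment sets whose
residue pairs follow a configured joint distribution *exactly*, with gaps,
ambiguity codes and duplicate sequences layered on top — so the whole
pipeline is testable against a known ground truth without any downloads.

## Worked example

```python
from seedmat import SimConfig, simulate_dataset, build_matrix

groups = simulate_dataset(SimConfig(n_groups=100, seed=7))
m = build_matrix(groups, t=60)
print(f"H = {m.H:.4f} bit, E = {m.E:.4f} bit")
print(m.score("W", "W"), m.score("I", "L"), m.score("W", "C"))
```

prints

```
H = 1.2520 bit, E = -0.8970 bit
4 1 -1
```

H is the information per aligned residue pair carried by the matrix; the
negative expected score confirms the matrix is usable for local alignment;
conserved tryptophan scores high, the within-class I/L substitution is
mildly favored, and the rare W–C substitution is penalized. The
`examples/` directory holds one short script per capability (building from
Stockholm files, ambiguity counting, clustering weights, search-benchmark
statistics, q-score, parameter recovery); each prints the numbers it
computes and a line on what they mean. A thin CLI wraps the same calls:

```
seedmat simulate --n-groups 100 -o seeds.sto
seedmat build seeds.sto -t 60 -o seedmat60.mat
```

The matrix file is the standard whitespace-separated square dialect with
`#` metadata comments, readable by the usual search tools' custom-matrix
options (and by `Bio.Align.substitution_matrices.read`).

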