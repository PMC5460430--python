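"""Scoring a homology-search hit list: coverage, bootstrap, Z-score.

A toy database of five sequences in two superfamilies and an E-value-ranked
hit list with two false positives.  At 0.3 errors per query the list is cut
before the second false positive; coverage averages the quadratically
normalized true-positive fractions per superfamily.  The Bayesian bootstrap
then attaches an uncertainty to that coverage, and a Z-score compares two
hypothetical matrices.
"""

from seedmat import HitList, bootstrap_coverage, coverage_at_epq, z_score

superfamily = {"a1": "sf1", "a2": "sf1", "a3": "sf1", "b1": "sf2", "b2": "sf2"}
hits = [
    ("a1", "a2", 1e-10), ("a2", "a1", 1e-9), ("a1", "b1", 1e-8),
    ("a2", "a3", 1e-7), ("b1", "b2", 1e-6), ("b2", "a1", 1e-5),
    ("a3", "a1", 1e-4), ("b2", "b1", 1e-3),
]
h = HitList.from_records(hits, superfamily)

res = coverage_at_epq(h, epq=0.3)
print(f"cutoff after {res.cutoff_index} of {len(h)} relations "
      f"(budget = 0.3 x {res.n_queries} queries)")
print(f"retained true positives per superfamily: {res.t_i}")
print(f"coverage Q = {res.Q:.3f}")

mean, var = bootstrap_coverage(h, reps=500, seed=1, epq=0.3)
print(f"bootstrap: mean = {mean:.3f}, variance = {var:.5f} over 500 replicates")

z = z_score(mean, var, mean - 0.08, var, 500)
print(f"Z against a matrix 0.08 worse: {z:.2f} "
      f"({'significant' if abs(z) >= 1.96 else 'not significant'} at 95%)")
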