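"""Percent-identity clustering and the weights it induces.

Two sequences that are 73.5% identical merge at threshold t = 62; once
clusters exist, a pair drawn from clusters of sizes 2 and 3 counts with
weight 1/6 and pairs inside one cluster are ignored entirely — a cluster
behaves like a single sequence.
"""

import numpy as np

from seedmat import GroupAlignment, cluster_group, pair_similarity, pair_weight
from seedmat.clustering import ClusterAssignment

a = "A" * 147 + "C" * 53
b = "A" * 147 + "D" * 53
g = GroupAlignment.from_strings("demo", [("a", a), ("b", b)])
phi, frac = pair_similarity(g.codes[0], g.codes[1])
print(f"phi = {phi} identical positions, Phi = {frac:.3f}")
print(f"clusters at t=62: {cluster_group(g, 62).n_clusters} (merged)")
print(f"clusters at t=80: {cluster_group(g, 80).n_clusters} (kept apart)")

assignment = ClusterAssignment(
    group_id="demo", t=62,
    labels=np.array([0, 0, 1, 1, 1]), sizes=np.array([2, 3]),
)
print(f"cross-cluster weight (|c|=2 vs |c|=3): {pair_weight(assignment, 0, 2):.4f}")
print(f"within-cluster weight: {pair_weight(assignment, 0, 1)}")
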