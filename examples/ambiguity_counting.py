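"""How ambiguity codes enter the pair counts.

One aligned column pairing an A against a B (= N or D) between two
unrelated sequences: the count lands once on the observed (A, B) cell and
is also spread in equal halves over the canonical readings (A, N) and
(A, D).  The normalizer counts the observation once, so the corrected
frequencies come out as 0.5 / 0.5 / 1.
"""

from seedmat import GroupAlignment, cluster_group, count_group_pairs, group_frequencies
from seedmat.alphabet import CODE_OF

group = GroupAlignment.from_strings("demo", [("s1", "A"), ("s2", "B")])
clusters = cluster_group(group, t=62)
print(f"clusters: {clusters.n_clusters} (the two sequences share no residue)")

counts = count_group_pairs(group, clusters)
A, N, D, B = (CODE_OF[x] for x in "ANDB")
print(f"n(A,N) = {counts.n[A, N]}, n(A,D) = {counts.n[A, D]}, "
      f"n(A,B) = {counts.n[A, B]}, N_k = {counts.N_k}")

freqs = group_frequencies(counts)
print(f"p(A,N) = {freqs.p[A, N]}, p(A,D) = {freqs.p[A, D]}, "
      f"p(A,B) = {freqs.p[A, B]}")
print("each observed pairing carries unit mass: the ambiguous cell keeps the"
      " full count, the canonical cells split it")
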