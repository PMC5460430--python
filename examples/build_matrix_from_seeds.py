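"""Build a substitution matrix from a set of seed alignments.

Simulates a small Pfam-seed-like Stockholm file, then runs the full
construction: percent-identity clustering at t = 60, cluster-weighted pair
counting, per-group normalization, and log2-odds scoring.  Prints the
matrix diagnostics and a few familiar score entries.
"""

import tempfile
from pathlib import Path

from seedmat import (
    SimConfig,
    build_matrix,
    read_stockholm,
    simulate_dataset,
    write_matrix,
    write_stockholm,
)

with tempfile.TemporaryDirectory() as tmp:
    sto = Path(tmp) / "seeds.sto"
    write_stockholm(simulate_dataset(SimConfig(n_groups=100, seed=7)), sto)
    groups = read_stockholm(sto)
    print(f"read {len(groups)} groups, {sum(g.s_k for g in groups)} sequences")

    m = build_matrix(groups, t=60)
    # H: information per aligned pair; E: expected score under independence,
    # which must be negative for local alignment to work.
    print(f"t = {m.t}, H = {m.H:.4f} bit, E = {m.E:.4f} bit")
    for a, b in [("W", "W"), ("I", "L"), ("A", "A"), ("W", "C")]:
        print(f"  S({a},{b}) = {m.score(a, b):+d}")

    out = Path(tmp) / "seedmat60.mat"
    write_matrix(m, out, include_stop=True)
    print(f"matrix file starts with: {out.read_text().splitlines()[0]!r}")
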