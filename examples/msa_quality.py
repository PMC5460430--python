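"""Scoring a test MSA against a trusted reference with the q-score.

Three short sequences; the test alignment slides one residue of s3 out of
place, destroying two of the six residue pairs the reference aligns.
"""

from seedmat import GroupAlignment, q_score

ref = GroupAlignment.from_strings(
    "ref", [("s1", "ABC-"), ("s2", "AB-D"), ("s3", "-BCD")]
)
test = GroupAlignment.from_strings(
    "test", [("s1", "ABC-"), ("s2", "AB-D"), ("s3", "B-CD")]
)

print(f"identical MSAs:  q = {q_score(ref, ref):.3f}")
print(f"one misplaced residue: q = {q_score(test, ref):.3f} "
      "(4 of the reference's 6 aligned pairs survive)")
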