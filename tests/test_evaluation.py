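from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seedmat import (
    HitList,
    bootstrap_coverage,
    coverage_at_epq,
    q_score,
    z_score,
)
from seedmat.evaluation import is_significant, read_hits_tsv, read_superfamily_tsv

import _oracles

SF = {"a1": "sf1", "a2": "sf1", "a3": "sf1", "b1": "sf2", "b2": "sf2"}

EIGHT_RECORDS = [
    ("a1", "a2", 1e-10),
    ("a2", "a1", 1e-9),
    ("a1", "b1", 1e-8),   # false positive
    ("a2", "a3", 1e-7),
    ("b1", "b2", 1e-6),
    ("b2", "a1", 1e-5),   # false positive
    ("a3", "a1", 1e-4),
    ("b2", "b1", 1e-3),
]


class TestCoverage:
    def test_hand_built_example(self):
        """Budget of 1.5 errors keeps the first five records: sf1 retains 3 of
        its 6 ordered relations, sf2 one of two."""
        h = HitList.from_records(EIGHT_RECORDS, SF)
        res = coverage_at_epq(h, epq=0.3)  # 0.3 * 5 queries = 1.5 errors
        assert res.cutoff_index == 5
        assert res.t_i["sf1"] == 3
        assert res.t_i["sf2"] == 1
        assert res.Q == pytest.approx(0.5)
        assert res.Q == pytest.approx(
            _oracles.longest_valid_prefix_coverage(EIGHT_RECORDS, SF, 0.3)
        )

    def test_perfect_retrieval(self):
        sf = {"x1": "s", "x2": "s", "x3": "s"}
        records = [
            (q, t, 1e-8)
            for q in sf
            for t in sf
            if q != t
        ]
        h = HitList.from_records(records, sf)
        assert coverage_at_epq(h, epq=0.5).Q == pytest.approx(1.0)

    def test_epq_budget_admits_one_fp_per_100_queries(self):
        sf = {f"q{i}": f"f{i // 2}" for i in range(100)}  # 50 families of 2
        records = [(f"q{2*i}", f"q{2*i+1}", 10.0 ** -(60 - i)) for i in range(40)]
        records.append(("q0", "q3", 1e-15))   # FP, best E-value
        records.append(("q1", "q4", 1e-14))   # FP, second best
        h = HitList.from_records(records, sf)
        res = coverage_at_epq(h, epq=0.01)    # budget: exactly one error
        retained_fp = res.cutoff_index - sum(res.t_i.values())
        assert retained_fp == 1

    def test_superfamily_relabeling_invariance(self):
        relabeled = {sid: "X" + sf for sid, sf in SF.items()}
        q1 = coverage_at_epq(HitList.from_records(EIGHT_RECORDS, SF), 0.3).Q
        q2 = coverage_at_epq(
            HitList.from_records(EIGHT_RECORDS, relabeled), 0.3
        ).Q
        assert q1 == pytest.approx(q2)

    def test_self_hits_dropped(self):
        with_self = EIGHT_RECORDS + [("a1", "a1", 1e-30)]
        h = HitList.from_records(with_self, SF)
        assert len(h) == len(EIGHT_RECORDS)

    def test_unlabeled_id_rejected(self):
        with pytest.raises(KeyError):
            HitList.from_records([("a1", "zz", 1e-5)], SF)

    def test_no_multi_member_superfamily_rejected(self):
        sf = {"a": "s1", "b": "s2"}
        h = HitList.from_records([("a", "b", 1e-5)], sf)
        with pytest.raises(ValueError):
            coverage_at_epq(h, 0.5)

    @given(data=st.data())
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_matches_exhaustive_prefix_oracle(self, data):
        n_seq = data.draw(st.integers(4, 12))
        ids = [f"s{i}" for i in range(n_seq)]
        sf = {sid: f"f{data.draw(st.integers(0, 2))}" for sid in ids}
        # ensure a scoreable superfamily exists
        sf[ids[0]] = sf[ids[1]] = "f0"
        all_pairs = [(q, t) for q in ids for t in ids if q != t]
        k = data.draw(st.integers(1, min(60, len(all_pairs))))
        chosen = data.draw(
            st.permutations(all_pairs).map(lambda p: p[:k])
        )
        evs = data.draw(
            st.lists(
                st.floats(1e-30, 10.0, allow_nan=False),
                min_size=k,
                max_size=k,
            )
        )
        records = [(q, t, e) for (q, t), e in zip(chosen, evs)]
        epq = data.draw(st.floats(0.01, 1.0))
        got = coverage_at_epq(HitList.from_records(records, sf), epq).Q
        want = _oracles.longest_valid_prefix_coverage(records, sf, epq)
        assert got == pytest.approx(want, abs=1e-12)


class TestBootstrap:
    def test_equal_weight_limit_recovers_unweighted(self):
        h = HitList.from_records(EIGHT_RECORDS, SF)
        mean, var = bootstrap_coverage(
            h, reps=10, seed=1, epq=0.3, equal_weights=True
        )
        assert mean == pytest.approx(coverage_at_epq(h, 0.3).Q)
        assert var == pytest.approx(0.0, abs=1e-18)

    def test_deterministic_for_fixed_seed(self):
        h = HitList.from_records(EIGHT_RECORDS, SF)
        a = bootstrap_coverage(h, reps=50, seed=7, epq=0.3)
        b = bootstrap_coverage(h, reps=50, seed=7, epq=0.3)
        assert a == b

    def test_mean_consistent_with_unweighted_coverage(self):
        sf = {f"s{i}": f"f{i // 4}" for i in range(24)}  # 6 families of 4
        rng = np.random.default_rng(3)
        records = []
        for fam in range(6):
            members = [f"s{4 * fam + j}" for j in range(4)]
            for q in members:
                for t in members:
                    if q != t and rng.random() < 0.7:
                        records.append((q, t, float(rng.uniform(1e-20, 1e-5))))
        records.append(("s0", "s5", 1e-25))  # one early false positive
        h = HitList.from_records(records, sf)
        q0 = coverage_at_epq(h, epq=0.05).Q
        reps = 2000
        mean, var = bootstrap_coverage(h, reps=reps, seed=11, epq=0.05)
        se = np.sqrt(var / reps)
        assert abs(mean - q0) <= 3 * se + 0.02 * q0

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_coverage(
                HitList.from_records(EIGHT_RECORDS, SF), reps=1, seed=0
            )


class TestZScore:
    def test_equal_means(self):
        assert z_score(0.4, 0.1, 0.4, 0.2, 500) == 0.0

    def test_formula_value(self):
        z = z_score(0.5, 0.125, 0.4, 0.125, 500)
        assert z == pytest.approx(4.472, abs=1e-3)
        assert is_significant(z)

    def test_zero_variance_divergence(self):
        with pytest.warns(UserWarning):
            z = z_score(0.5, 0.0, 0.4, 0.0, 500)
        assert np.isposinf(z)

    def test_insignificant_small_difference(self):
        assert not is_significant(z_score(0.41, 0.2, 0.4, 0.2, 500))


REF_ROWS = {"s1": "ABC-", "s2": "AB-D", "s3": "-BCD"}
TEST_ROWS = {"s1": "ABC-", "s2": "AB-D", "s3": "B-CD"}


def group_from(rows: dict[str, str]):
    from seedmat import GroupAlignment

    return GroupAlignment.from_strings("q", list(rows.items()))


class TestQScore:
    def test_identical_msas_score_one(self):
        g = group_from(REF_ROWS)
        assert q_score(g, g) == pytest.approx(1.0)

    def test_misplaced_residue_counted_against(self):
        got = q_score(group_from(TEST_ROWS), group_from(REF_ROWS))
        ref_pairs = _oracles.aligned_pairs(REF_ROWS)
        test_pairs = _oracles.aligned_pairs(TEST_ROWS)
        want = len(ref_pairs & test_pairs) / len(ref_pairs)
        assert got == pytest.approx(want)
        assert got == pytest.approx(4 / 6)

    def test_totally_different_alignment_scores_zero(self):
        ref = group_from({"x": "AC", "y": "AC"})
        test = group_from({"x": "AC--", "y": "--AC"})
        assert q_score(test, ref) == pytest.approx(0.0)

    def test_residue_content_must_match(self):
        with pytest.raises(ValueError, match="residues differ"):
            q_score(group_from({"s1": "AC"}), group_from({"s1": "AD"}))

    def test_sequence_sets_must_match(self):
        with pytest.raises(ValueError):
            q_score(group_from({"s1": "AC"}), group_from({"s9": "AC"}))

    @given(position=st.integers(0, 4))
    @settings(max_examples=10, derandomize=True, deadline=None)
    def test_gap_column_insertion_is_neutral(self, position):
        ref = group_from(REF_ROWS)
        padded = group_from(
            {
                sid: seq[:position] + "-" + seq[position:]
                for sid, seq in REF_ROWS.items()
            }
        )
        assert q_score(padded, ref) == pytest.approx(1.0)
        assert q_score(ref, padded) == pytest.approx(1.0)


class TestTabularIO:
    def test_round_trip_tsv(self, tmp_path):
        hits = tmp_path / "hits.tsv"
        hits.write_text("query\ttarget\te_value\na1\ta2\t1e-9\na1\tb1\t1e-4\n")
        fam = tmp_path / "sf.tsv"
        fam.write_text(
            "id\tsuperfamily\n"
            + "\n".join(f"{sid}\t{sf}" for sid, sf in SF.items())
        )
        records = read_hits_tsv(hits)
        mapping = read_superfamily_tsv(fam)
        h = HitList.from_records(records, mapping)
        assert len(h) == 2
        assert mapping["b2"] == "sf2"
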