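"""Set algebra: count rules, cutoffs, merges, difference-from-union,
mismatch-tolerant difference."""

import numpy as np
import pytest

from kmerset import (ALLOWED_RULES, CutoffSpec, apply_rule, canonicalize,
                     diff_from_union, diff_with_mismatches, encode_kmer,
                     merge, read_entries)
from kmerset.listfile import MAX_COUNT

from conftest import (canonical_hamming, make_kml, merge_oracle,
                      overlapping_pair, random_canonical_table, rule_oracle)


class TestApplyRule:
    @pytest.mark.parametrize("rule,c1,c2,expected", [
        ("one", 5, 9, 1), ("two", 5, 9, 2),
        ("add", 2, 3, 5), ("subtract", 5, 3, 2), ("subtract", 3, 5, 0),
        ("min", 2, 3, 2), ("max", 2, 3, 3),
        ("first", 7, None, 7), ("second", None, 4, 4),
        ("add", None, 3, 3), ("first", 7, 2, 7),
    ])
    def test_known_values(self, rule, c1, c2, expected):
        assert apply_rule(rule, c1, c2) == expected

    def test_saturates_at_count_limit(self):
        assert apply_rule("add", MAX_COUNT, MAX_COUNT) == MAX_COUNT

    def test_rejects_unknown_rule_and_double_absence(self):
        with pytest.raises(ValueError):
            apply_rule("sum", 1, 1)
        with pytest.raises(ValueError):
            apply_rule("add", None, None)


class TestMerge:
    def test_union_add_example(self, tmp_path):
        a = make_kml(tmp_path / "a.kml", {6: 2}, 3)
        b = make_kml(tmp_path / "b.kml", {6: 3, 44: 1}, 3)
        merge(a, b, tmp_path / "u.kml", "union", rule="add")
        assert read_entries(tmp_path / "u.kml")[1] == [(6, 5), (44, 1)]

    def test_intersection_min_with_cutoffs(self, tmp_path):
        a = make_kml(tmp_path / "a.kml", {6: 1, 44: 5}, 3)
        b = make_kml(tmp_path / "b.kml", {6: 2, 44: 2}, 3)
        merge(a, b, tmp_path / "i.kml", "intersection", rule="min",
              cutoffs=CutoffSpec(2, 2))
        assert read_entries(tmp_path / "i.kml")[1] == [(44, 2)]

    def test_difference_first(self, tmp_path):
        a = make_kml(tmp_path / "a.kml", {6: 2}, 3)
        b = make_kml(tmp_path / "b.kml", {6: 3, 44: 1}, 3)
        merge(a, b, tmp_path / "d.kml", "difference", rule="first")
        assert read_entries(tmp_path / "d.kml")[1] == []
        a2 = make_kml(tmp_path / "a2.kml", {6: 3, 44: 1}, 3)
        b2 = make_kml(tmp_path / "b2.kml", {6: 2}, 3)
        merge(a2, b2, tmp_path / "d2.kml", "difference", rule="first")
        assert read_entries(tmp_path / "d2.kml")[1] == [(44, 1)]

    def test_self_difference_is_empty(self, tmp_path):
        a = make_kml(tmp_path / "a.kml", {6: 2, 44: 7}, 3)
        merge(a, a, tmp_path / "d.kml", "difference")
        assert read_entries(tmp_path / "d.kml")[1] == []

    def test_k_mismatch_rejected(self, tmp_path):
        a = make_kml(tmp_path / "a.kml", {6: 2}, 3)
        b = make_kml(tmp_path / "b.kml", {6: 2}, 4)
        with pytest.raises(ValueError, match="k mismatch"):
            merge(a, b, tmp_path / "x.kml", "union")

    @pytest.mark.parametrize("op,bad_rule", [
        ("union", "subtract"), ("union", "min"), ("union", "second"),
        ("difference", "add"), ("difference", "min"), ("difference", "max"),
        ("difference", "second"),
    ])
    def test_forbidden_rule_rejected_before_output(self, tmp_path, op, bad_rule):
        a = make_kml(tmp_path / "a.kml", {6: 2}, 3)
        out = tmp_path / "out.kml"
        with pytest.raises(ValueError, match="not permitted"):
            merge(a, a, out, op, rule=bad_rule)
        assert not out.exists()

    def test_matches_dictionary_oracle_all_ops_and_rules(self, tmp_path, rng):
        """Presence-then-rule semantics agree with the dictionary oracle
        across ops, permitted rules and cutoffs."""
        for trial in range(15):
            ta, tb = overlapping_pair(rng, 8, n=25)
            a = make_kml(tmp_path / f"a{trial}.kml", ta, 8)
            b = make_kml(tmp_path / f"b{trial}.kml", tb, 8)
            c1 = int(rng.integers(1, 4))
            c2 = int(rng.integers(1, 4))
            for op, rules in ALLOWED_RULES.items():
                for rule in rules:
                    out = tmp_path / "out.kml"
                    merge(a, b, out, op, rule=rule, cutoffs=CutoffSpec(c1, c2))
                    expected = merge_oracle(ta, tb, op, rule, c1, c2)
                    assert dict(read_entries(out)[1]) == expected, (op, rule)

    def test_subtract_equal_counts_word_omitted(self, tmp_path):
        a = make_kml(tmp_path / "a.kml", {6: 3, 44: 5}, 3)
        b = make_kml(tmp_path / "b.kml", {6: 3}, 3)
        merge(a, b, tmp_path / "s.kml", "intersection", rule="subtract")
        assert read_entries(tmp_path / "s.kml")[1] == []


class TestAlgebraicLaws:
    def test_partition_union_totality_commutativity_cutoffs(self, tmp_path, rng):
        for trial in range(25):
            ta, tb = overlapping_pair(rng, 8, n=20)
            a = make_kml(tmp_path / "a.kml", ta, 8)
            b = make_kml(tmp_path / "b.kml", tb, 8)
            hi = merge(a, b, tmp_path / "i.kml", "intersection")
            hd = merge(a, b, tmp_path / "d.kml", "difference")
            wi = {w for w, _ in read_entries(tmp_path / "i.kml")[1]}
            wd = {w for w, _ in read_entries(tmp_path / "d.kml")[1]}
            assert wi | wd == set(ta) and not (wi & wd)
            hu = merge(a, b, tmp_path / "u.kml", "union", rule="add")
            assert hu.total_count == sum(ta.values()) + sum(tb.values())
            # symmetric rules commute (within each op's permitted set)
            for op, rules in (("union", ("one", "two", "add", "max")),
                              ("intersection", ("one", "two", "add", "min", "max"))):
                for rule in rules:
                    merge(a, b, tmp_path / "ab.kml", op, rule=rule)
                    merge(b, a, tmp_path / "ba.kml", op, rule=rule)
                    assert (tmp_path / "ab.kml").read_bytes() == \
                        (tmp_path / "ba.kml").read_bytes(), (op, rule)

    def test_raising_cutoff_only_removes_words(self, tmp_path, rng):
        ta, tb = overlapping_pair(rng, 8, n=30)
        a = make_kml(tmp_path / "a.kml", ta, 8)
        b = make_kml(tmp_path / "b.kml", tb, 8)
        for op in ("union", "intersection", "difference"):
            prev = None
            for cutoff in (1, 2, 4, 8):
                merge(a, b, tmp_path / "o.kml", op,
                      cutoffs=CutoffSpec(cutoff, 1))
                words = {w for w, _ in read_entries(tmp_path / "o.kml")[1]}
                if prev is not None:
                    assert words <= prev, (op, cutoff)
                prev = words


class TestDiffFromUnion:
    def test_fig_examples(self, tmp_path):
        a = make_kml(tmp_path / "a.kml", {44: 1}, 3)
        b = make_kml(tmp_path / "b.kml", {6: 5}, 3)
        merge(a, b, tmp_path / "u.kml", "union", rule="add")
        diff_from_union(a, tmp_path / "u.kml", tmp_path / "f.kml")
        assert read_entries(tmp_path / "f.kml")[1] == [(44, 1)]
        a2 = make_kml(tmp_path / "a2.kml", {6: 2}, 3)
        u2 = make_kml(tmp_path / "u2.kml", {6: 5, 44: 1}, 3)
        diff_from_union(a2, u2, tmp_path / "f2.kml")
        assert read_entries(tmp_path / "f2.kml")[1] == []

    def test_equivalent_to_plain_difference(self, tmp_path, rng):
        """Against union_add(A, B), difference-from-union equals the plain
        first-rule difference of A and B."""
        for trial in range(100):
            ta, tb = overlapping_pair(rng, 8, n=15)
            a = make_kml(tmp_path / "a.kml", ta, 8)
            b = make_kml(tmp_path / "b.kml", tb, 8)
            merge(a, b, tmp_path / "u.kml", "union", rule="add")
            diff_from_union(a, tmp_path / "u.kml", tmp_path / "dfu.kml")
            merge(a, b, tmp_path / "d.kml", "difference", rule="first")
            assert (tmp_path / "dfu.kml").read_bytes() == \
                (tmp_path / "d.kml").read_bytes()

    def test_rejects_non_superset_union(self, tmp_path):
        a = make_kml(tmp_path / "a.kml", {6: 2, 44: 1}, 3)
        u = make_kml(tmp_path / "u.kml", {6: 5}, 3)  # 44 missing
        with pytest.raises(ValueError, match="missing from union"):
            diff_from_union(a, u, tmp_path / "f.kml")
        u2 = make_kml(tmp_path / "u2.kml", {6: 1, 44: 1}, 3)  # 6 below A's 2
        with pytest.raises(ValueError, match="below"):
            diff_from_union(a, u2, tmp_path / "f.kml")


class TestDiffWithMismatches:
    def test_m0_is_plain_difference(self, tmp_path, rng):
        ta, tb = overlapping_pair(rng, 8, n=20)
        a = make_kml(tmp_path / "a.kml", ta, 8)
        b = make_kml(tmp_path / "b.kml", tb, 8)
        diff_with_mismatches(a, b, tmp_path / "m0.kml", 0)
        merge(a, b, tmp_path / "d.kml", "difference", rule="first")
        assert (tmp_path / "m0.kml").read_bytes() == (tmp_path / "d.kml").read_bytes()

    def test_one_mismatch_eliminates_neighbor(self, tmp_path):
        a = make_kml(tmp_path / "a.kml",
                     {canonicalize(encode_kmer("AAA"), 3): 1}, 3)
        b = make_kml(tmp_path / "b.kml",
                     {canonicalize(encode_kmer("AAC"), 3): 1}, 3)
        diff_with_mismatches(a, b, tmp_path / "m.kml", 1)
        assert read_entries(tmp_path / "m.kml")[1] == []

    def test_m_exceeding_k_rejected(self, tmp_path):
        a = make_kml(tmp_path / "a.kml", {0: 1}, 3)
        with pytest.raises(ValueError, match="outside"):
            diff_with_mismatches(a, a, tmp_path / "m.kml", 4)

    @pytest.mark.parametrize("m", [0, 1, 2])
    def test_matches_exhaustive_hamming_oracle(self, tmp_path, rng, m):
        """Survivors are exactly the A-words beyond strand-aware Hamming
        distance m from every B-word."""
        k = 8
        for trial in range(5):
            ta = random_canonical_table(rng, k, 50)
            tb = random_canonical_table(rng, k, 50)
            a = make_kml(tmp_path / "a.kml", ta, k)
            b = make_kml(tmp_path / "b.kml", tb, k)
            diff_with_mismatches(a, b, tmp_path / "m.kml", m)
            expected = {w: c for w, c in ta.items()
                        if all(canonical_hamming(w, bw, k) > m for bw in tb)}
            assert dict(read_entries(tmp_path / "m.kml")[1]) == expected
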