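"""Stratification builders against combinatorial oracles."""

from itertools import combinations
from math import comb

import numpy as np
import pytest

import csistrat as cs
from csistrat.data import FormatError
from csistrat.stratify import read_strata, write_strata

from conftest import random_table


class TestCompoundKey:
    def test_enumerated_example(self, tiny_table):
        strata = cs.stratify_by_compound(tiny_table)
        by_key = {s.key_value: s for s in strata}
        assert set(v[1] for v in by_key["c1"].views) == {("s1", "s2"), ("s1", "s3"), ("s2", "s3")}
        assert by_key["c2"].views == (("c2", ("s1", "s1")),)

    def test_empty_table_empty_list(self):
        t = cs.InteractionTable(frozenset(), compound_ids=("c",), sequence_ids=("s",))
        assert cs.stratify_by_compound(t) == []

    def test_binomial_view_count(self):
        pos = frozenset(("c1", f"s{i}") for i in range(10))
        strata = cs.stratify_by_compound(cs.InteractionTable(pos))
        assert strata[0].n_views == comb(10, 2)


class TestSequenceKey:
    def test_mirror_example(self):
        t = cs.InteractionTable(frozenset({("c1", "s1"), ("c2", "s1")}))
        strata = cs.stratify_by_sequence(t)
        assert strata[0].views == (("s1", ("c1", "c2")),)

    def test_singleton_self_pair(self):
        t = cs.InteractionTable(frozenset({("c9", "s1")}))
        assert cs.stratify_by_sequence(t)[0].views == (("s1", ("c9", "c9")),)


@pytest.mark.parametrize("builder,group_idx", [
    (cs.stratify_by_compound, 0),
    (cs.stratify_by_sequence, 1),
])
def test_view_counts_match_closed_form_on_random_tables(builder, group_idx):
    """Total views == sum over keys of C(n,2), plus one per singleton key."""
    rng = np.random.default_rng(42)
    for _ in range(100):
        table = random_table(rng, n_c=rng.integers(2, 8), n_s=rng.integers(2, 8))
        degree: dict[str, int] = {}
        for pair in table.positives:
            degree[pair[group_idx]] = degree.get(pair[group_idx], 0) + 1
        expected = sum(comb(n, 2) if n > 1 else 1 for n in degree.values())
        strata = builder(table)
        assert sum(s.n_views for s in strata) == expected
        assert len(strata) == len(degree)


def test_every_positive_contributes_and_keys_disjoint():
    rng = np.random.default_rng(3)
    table = random_table(rng, n_c=7, n_s=7, p=0.35)
    strata = cs.stratify_by_compound(table)
    seen_views = set()
    for s in strata:
        for v in s.views:
            assert v not in seen_views  # each view in exactly one stratum
            seen_views.add(v)
    for c, s in table.positives:
        stratum = next(x for x in strata if x.key_value == c)
        assert any(s in v[1] for v in stratum.views)
    mirror = cs.stratify_by_sequence(table)
    for c, s in table.positives:
        stratum = next(x for x in mirror if x.key_value == s)
        assert any(c in v[1] for v in stratum.views)


def test_determinism_and_stable_order():
    rng = np.random.default_rng(5)
    table = random_table(rng, 8, 8)
    a = cs.stratify_by_compound(table)
    b = cs.stratify_by_compound(table)
    assert a == b
    assert [s.key_value for s in a] == sorted(s.key_value for s in a)


class TestReactionFeature:
    @pytest.fixture
    def single(self):
        return [cs.ReactionRecord("r1", ("m1", "m2"), ("m3",), ("e1", "e2"))]

    def test_three_view_enumeration(self, single):
        (stratum,) = cs.stratify_by_reaction_feature(single, "reaction")
        v1, v2, v3 = stratum.views
        assert set(v1) == {("m1", "m3"), ("m2", "m3")}
        assert set(v2) == {(m, e) for m in ("m1", "m2", "m3") for e in ("e1", "e2")}
        assert v3 == (("e1", "e2"),)

    def test_rclass_groups_pool_views(self):
        recs = [
            cs.ReactionRecord("r1", ("m1",), ("m2",), ("e1",), rclass_id="RC1"),
            cs.ReactionRecord("r2", ("m1",), ("m3",), ("e2",), rclass_id="RC1"),
        ]
        (stratum,) = cs.stratify_by_reaction_feature(recs, "rclass")
        assert set(stratum.views[0]) == {("m1", "m2"), ("m1", "m3")}
        assert stratum.members == {"m1", "m2", "m3", "e1", "e2"}

    def test_single_enzyme_self_pair(self):
        recs = [cs.ReactionRecord("r1", ("m1",), ("m2",), ("e1",))]
        (stratum,) = cs.stratify_by_reaction_feature(recs, "reaction")
        assert stratum.views[2] == (("e1", "e1"),)

    def test_missing_key_field_names_reaction(self, single):
        with pytest.raises(FormatError, match="r1"):
            cs.stratify_by_reaction_feature(single, "ec")

    def test_random_sets_match_exhaustive_enumeration(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            recs = []
            for i in range(rng.integers(1, 6)):
                R = [f"m{j}" for j in rng.choice(10, size=rng.integers(1, 3), replace=False)]
                P = [f"m{j}" for j in rng.choice(np.arange(10, 20), size=rng.integers(1, 3), replace=False)]
                E = [f"e{j}" for j in rng.choice(6, size=rng.integers(1, 3), replace=False)]
                recs.append(cs.ReactionRecord(f"r{i}", tuple(R), tuple(P), tuple(E),
                                              rclass_id=f"RC{rng.integers(2)}"))
            strata = cs.stratify_by_reaction_feature(recs, "rclass")
            for stratum in strata:
                members = [r for r in recs if r.rclass_id == stratum.key_value]
                e_v1, e_v2, e_v3 = set(), set(), set()
                for r in members:
                    e_v1 |= {(a, b) for a in r.reactant_ids for b in r.product_ids}
                    e_v2 |= {(c, s) for c in set(r.reactant_ids) | set(r.product_ids)
                             for s in r.enzyme_ids}
                    ez = sorted(set(r.enzyme_ids))
                    e_v3 |= {(ez[0], ez[0])} if len(ez) == 1 else set(combinations(ez, 2))
                assert set(stratum.views[0]) == e_v1
                assert set(stratum.views[1]) == e_v2
                assert set(stratum.views[2]) == e_v3


class TestStats:
    def test_set_arithmetic_example(self):
        a = cs.Stratum("compound", "c1", (("c1", ("s1", "s2")),), frozenset({"s1", "s2"}))
        b = cs.Stratum("compound", "c2", (("c2", ("s2", "s3")),), frozenset({"s2", "s3"}))
        stats = cs.compute_strata_stats([a, b])
        assert stats.mean_shared == 1.0
        assert stats.mean_jaccard == pytest.approx(1 / 3)

    def test_identical_and_disjoint(self):
        mk = lambda k, m: cs.Stratum("compound", k, (), frozenset(m))
        assert cs.compute_strata_stats([mk("a", "xy"), mk("b", "xy")]).mean_jaccard == 1.0
        stats = cs.compute_strata_stats([mk("a", "xy"), mk("b", "zw")])
        assert stats.mean_shared == 0.0 and stats.mean_jaccard == 0.0

    def test_fewer_than_two_strata_undefined(self):
        stats = cs.compute_strata_stats([cs.Stratum("compound", "a", (), frozenset("x"))])
        assert stats.mean_shared is None and stats.mean_jaccard is None

    def test_oracle_on_random_strata(self):
        rng = np.random.default_rng(1)
        table = random_table(rng, 8, 8, p=0.4)
        strata = cs.stratify_by_compound(table)
        stats = cs.compute_strata_stats(strata)
        pairs = [(a, b) for i, a in enumerate(strata) for b in strata[i + 1:]]
        exp_shared = np.mean([len(a.members & b.members) for a, b in pairs])
        exp_jac = np.mean([len(a.members & b.members) / len(a.members | b.members)
                           for a, b in pairs])
        assert stats.mean_shared == pytest.approx(exp_shared)
        assert stats.mean_jaccard == pytest.approx(exp_jac)


def test_strata_jsonl_round_trip(tmp_path, tiny_table):
    strata = cs.stratify_by_compound(tiny_table)
    p = tmp_path / "strata.jsonl"
    write_strata(strata, p)
    assert read_strata(p) == strata
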