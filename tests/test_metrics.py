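"""Ranking metrics against brute-force oracles and hand-computed cases."""

import numpy as np
import pytest

import csistrat as cs


def oracle_ap(labels, scores):
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    ranked = np.asarray(labels)[order]
    hits = 0
    precs = []
    for rank, lab in enumerate(ranked, start=1):
        if lab == 1:
            hits += 1
            precs.append(hits / rank)
    return sum(precs) / len(precs) if precs else None


def oracle_rprec(labels, scores):
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    ranked = np.asarray(labels)[order]
    R = int(ranked.sum())
    return None if R == 0 else float(ranked[:R].sum() / R)


class TestHandCases:
    def test_perfect_ranking(self):
        assert cs.average_precision([1, 1, 0], [3, 2, 1]) == 1.0

    def test_interleaved(self):
        # ranked labels [1, 0, 1] -> (1/1 + 2/3) / 2
        assert cs.average_precision([1, 0, 1], [3, 2, 1]) == pytest.approx(5 / 6)

    def test_single_positive_last(self):
        assert cs.average_precision([0, 0, 1], [3, 2, 1]) == pytest.approx(1 / 3)

    def test_r_precision_halves(self):
        assert cs.r_precision([1, 1, 0, 0], [4, 3, 2, 1]) == 1.0
        assert cs.r_precision([1, 0, 1, 0], [4, 3, 2, 1]) == 0.5

    def test_no_positives_returns_none(self):
        assert cs.average_precision([0, 0], [1, 2]) is None
        assert cs.r_precision([0], [1]) is None

    def test_map_at_3_truncation(self):
        assert cs.average_precision_at_k([1, 0, 1], [3, 2, 1], 3) == pytest.approx(5 / 6)
        # only positive falls below the cut -> 0
        assert cs.average_precision_at_k([0, 0, 0, 1], [4, 3, 2, 1], 3) == 0.0


def test_matches_oracles_on_1000_random_instances():
    rng = np.random.default_rng(123)
    for _ in range(1000):
        n = int(rng.integers(2, 51))
        labels = rng.integers(0, 2, size=n)
        scores = rng.normal(size=n)
        exp_ap = oracle_ap(labels, scores)
        exp_rp = oracle_rprec(labels, scores)
        if exp_ap is None:
            assert cs.average_precision(labels, scores) is None
            continue
        assert abs(cs.average_precision(labels, scores) - exp_ap) < 1e-12
        assert abs(cs.r_precision(labels, scores) - exp_rp) < 1e-12


def test_agrees_with_sklearn_on_distinct_scores():
    from sklearn.metrics import average_precision_score

    rng = np.random.default_rng(7)
    for _ in range(50):
        n = int(rng.integers(5, 40))
        labels = rng.integers(0, 2, size=n)
        if labels.sum() == 0:
            labels[0] = 1
        scores = rng.permutation(n).astype(float)  # no ties
        assert cs.average_precision(labels, scores) == pytest.approx(
            average_precision_score(labels, scores), abs=1e-12
        )


def test_invariance_to_monotone_transform():
    rng = np.random.default_rng(11)
    labels = rng.integers(0, 2, size=30)
    labels[0] = 1
    scores = rng.normal(size=30)
    base = cs.average_precision(labels, scores)
    for f in (np.exp, np.tanh, lambda x: 3 * x + 7):
        assert cs.average_precision(labels, f(scores)) == pytest.approx(base)


def test_map_at_k_with_large_k_equals_map():
    rng = np.random.default_rng(13)
    for _ in range(30):
        n = int(rng.integers(2, 20))
        labels = rng.integers(0, 2, size=n)
        if labels.sum() == 0:
            labels[0] = 1
        scores = rng.normal(size=n)
        assert cs.average_precision_at_k(labels, scores, n + 5) == pytest.approx(
            cs.average_precision(labels, scores)
        )


def test_random_scorer_ap_near_half_on_balanced_labels():
    rng = np.random.default_rng(99)
    aps = []
    for _ in range(1000):
        labels = np.concatenate([np.ones(100), np.zeros(100)])
        scores = rng.normal(size=200)
        aps.append(cs.average_precision(labels, scores))
    assert abs(np.mean(aps) - 0.5) < 0.05


class TestTies:
    def test_stable_order_decides(self):
        assert cs.average_precision([1, 0], [1.0, 1.0]) == 1.0
        assert cs.average_precision([0, 1], [1.0, 1.0]) == 0.5

    def test_permuting_tied_items_can_change_value(self):
        a = cs.average_precision([1, 0, 0], [1.0, 1.0, 1.0])
        b = cs.average_precision([0, 0, 1], [1.0, 1.0, 1.0])
        assert a != b  # documented contract of the stable tie rule


class TestGrouped:
    def test_single_group_hand_case(self):
        pairs = [("c1", "s1"), ("c1", "s2"), ("c1", "s3")]
        out = cs.grouped_metrics(pairs, [1, 0, 1], [3, 2, 1], "compound", k_cut=3)
        assert out["MAP_at_k"] == pytest.approx(5 / 6)
        assert out["Precision_at_1"] == 1.0

    def test_perfect_groups_all_ones(self):
        pairs = [("c1", "s1"), ("c1", "s2"), ("c2", "s1"), ("c2", "s2")]
        out = cs.grouped_metrics(pairs, [1, 0, 1, 0], [2, 1, 2, 1], "compound")
        assert all(out[m] == 1.0 for m in ("MAP", "R_precision", "MAP_at_k", "Precision_at_1"))

    def test_groups_without_positives_skipped_and_counted(self):
        pairs = [("c1", "s1"), ("c2", "s1")]
        out = cs.grouped_metrics(pairs, [1, 0], [1, 1], "compound")
        assert out["n_groups"] == 1 and out["n_skipped"] == 1

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            cs.grouped_metrics([], [], [], "compound")

    def test_build_report_values_in_unit_interval(self):
        rng = np.random.default_rng(5)
        pairs = [(f"c{i % 4}", f"s{i % 5}") for i in range(40)]
        labels = rng.integers(0, 2, size=40)
        labels[:5] = 1
        report = cs.build_report(pairs, labels, rng.normal(size=40))
        for d in (report.overall, report.by_compound, report.by_sequence):
            for v in d.values():
                assert 0.0 <= v <= 1.0
        assert "min(R, 3)" in report.to_json() or "min(R" in report.to_json()
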