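"""Ranking metrics for interaction prediction.

Overall metrics (AP, R-precision) score the whole test set as one ranked
list; grouped metrics restrict the ranking to each compound's (or each
sequence's) candidate list, compute AP, R-precision, AP@k and Precision@1
within the group, and average unweighted over groups that contain at least
one positive (groups without positives are skipped and counted).

Ties are broken by stable original-order index so reported values are
reproducible; permuting tied items can therefore change a metric, which is
a property of any deterministic tie rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

OVERALL_METRICS = ("AP", "R_precision")
GROUP_METRICS = ("MAP", "R_precision", "MAP_at_k", "Precision_at_1")


def _ranked_labels(labels, scores) -> np.ndarray:
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    order = np.argsort(-scores, kind="stable")
    return labels[order]


def average_precision(labels, scores) -> float | None:
    """Mean over positives of precision at that positive's rank.

    Returns None when the list holds no positive (the caller skips the
    group rather than raising).
    """
    ranked = _ranked_labels(labels, scores)
    n_pos = int(ranked.sum())
    if n_pos == 0:
        return None
    hits = np.flatnonzero(ranked)  # 0-based ranks of positives
    precisions = np.arange(1, n_pos + 1) / (hits + 1)
    return float(precisions.mean())


def r_precision(labels, scores) -> float | None:
    """Fraction of positives within the top-R items, R = number of positives."""
    ranked = _ranked_labels(labels, scores)
    n_pos = int(ranked.sum())
    if n_pos == 0:
        return None
    return float(ranked[:n_pos].sum() / n_pos)


def average_precision_at_k(labels, scores, k: int) -> float | None:
    """AP over the ranking truncated at k, normalized by min(R, k)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = _ranked_labels(labels, scores)
    n_pos = int(ranked.sum())
    if n_pos == 0:
        return None
    top = ranked[:k]
    hits = np.flatnonzero(top)
    if hits.size == 0:
        return 0.0
    precisions = np.arange(1, hits.size + 1) / (hits + 1)
    return float(precisions.sum() / min(n_pos, k))


def precision_at_1(labels, scores) -> float | None:
    ranked = _ranked_labels(labels, scores)
    if ranked.sum() == 0:
        return None
    return float(ranked[0])


@dataclass
class RankingReport:
    """Grouped ranking metrics in the shape of the standard results table."""

    overall: dict = field(default_factory=dict)
    by_compound: dict = field(default_factory=dict)
    by_sequence: dict = field(default_factory=dict)
    n_groups: dict = field(default_factory=dict)
    n_skipped: dict = field(default_factory=dict)
    k_cut: int = 3

    def to_json(self) -> str:
        return json.dumps(
            {
                "overall": self.overall,
                "by_compound": self.by_compound,
                "by_sequence": self.by_sequence,
                "n_groups": self.n_groups,
                "n_skipped": self.n_skipped,
                "k_cut": self.k_cut,
                "map_at_k_convention": "truncate candidates at k, normalize by min(R, k)",
            },
            indent=2,
        )

    def to_tsv(self) -> str:
        lines = ["\tAP\tR-precision\tMAP\tR-precision\tMAP@%d\tPrecision@1" % self.k_cut]
        lines.append(
            "overall\t%.4f\t%.4f\t\t\t\t" % (self.overall["AP"], self.overall["R_precision"])
        )
        for name, d in (("compound", self.by_compound), ("sequence", self.by_sequence)):
            lines.append(
                "%s\t\t\t%.4f\t%.4f\t%.4f\t%.4f"
                % (name, d["MAP"], d["R_precision"], d["MAP_at_k"], d["Precision_at_1"])
            )
        return "\n".join(lines) + "\n"


def grouped_metrics(pairs, labels, scores, group_by: str, k_cut: int = 3) -> dict:
    """Average per-group metrics over groups holding at least one positive.

    ``pairs`` is a sequence of (compound_id, sequence_id); ``group_by`` is
    "compound" or "sequence".
    """
    if len(pairs) == 0:
        raise ValueError("empty input")
    if group_by not in ("compound", "sequence"):
        raise ValueError(f"group_by must be 'compound' or 'sequence', got {group_by!r}")
    idx = 0 if group_by == "compound" else 1
    groups: dict[str, list[int]] = {}
    for i, pair in enumerate(pairs):
        groups.setdefault(pair[idx], []).append(i)
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    sums = dict.fromkeys(GROUP_METRICS, 0.0)
    n_used = 0
    n_skipped = 0
    for key in sorted(groups):
        rows = groups[key]
        gl, gs = labels[rows], scores[rows]
        ap = average_precision(gl, gs)
        if ap is None:
            n_skipped += 1
            continue
        sums["MAP"] += ap
        sums["R_precision"] += r_precision(gl, gs)
        sums["MAP_at_k"] += average_precision_at_k(gl, gs, k_cut)
        sums["Precision_at_1"] += precision_at_1(gl, gs)
        n_used += 1
    if n_used == 0:
        raise ValueError("no group contains a positive")
    out = {m: sums[m] / n_used for m in GROUP_METRICS}
    out["n_groups"] = n_used
    out["n_skipped"] = n_skipped
    return out


def build_report(pairs, labels, scores, k_cut: int = 3) -> RankingReport:
    """Overall and grouped metrics for a scored set of labelled pairs."""
    report = RankingReport(k_cut=k_cut)
    report.overall = {
        "AP": average_precision(labels, scores),
        "R_precision": r_precision(labels, scores),
    }
    for name, group_by in (("by_compound", "compound"), ("by_sequence", "sequence")):
        d = grouped_metrics(pairs, labels, scores, group_by, k_cut)
        report.n_groups[name] = d.pop("n_groups")
        report.n_skipped[name] = d.pop("n_skipped")
        setattr(report, name, d)
    return report
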