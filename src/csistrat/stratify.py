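"""Stratification of interaction data into keyed congruent views.

A stratum is one key value together with every congruent view it supports:

* compound key ``c``: views ``(c, (s_i, s_j))`` over unordered pairs of
  sequences interacting with ``c`` (the lone-partner case yields the
  self-pair ``(s, s)``);
* sequence key ``s``: the mirror image with compound pairs;
* reaction-feature key (the reaction itself, its RCLASS, or its EC number):
  three view lists per key — reactant-product pairs, compound-sequence
  pairs (compounds being reactants or products), and unordered enzyme
  pairs — pooled and deduplicated over every reaction grouped under the key.

Views under the same key are congruent; views across keys are the
non-congruent candidates contrasted in a training batch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from math import nan

from .data import FormatError, InteractionTable, ReactionRecord

KEY_KINDS = ("compound", "sequence", "reaction", "rclass", "ec")


@dataclass(frozen=True)
class Stratum:
    """One stratification key with its congruent views.

    ``views`` is a tuple of ``(key_value, (id_i, id_j))`` tuples for
    compound/sequence keys, or the triple ``(v1, v2, v3)`` of view-tuple
    lists for reaction-feature keys. ``members`` is the id set on the
    non-key side (all ids for reaction-feature keys), used for the overlap
    statistics.
    """

    kind: str
    key_value: str
    views: tuple
    members: frozenset[str]

    @property
    def n_views(self) -> int:
        if self.kind in ("compound", "sequence"):
            return len(self.views)
        return sum(len(v) for v in self.views)


def _unordered_pairs(items: list[str]) -> list[tuple[str, str]]:
    """Distinct unordered pairs in lexicographic order; singleton -> self-pair."""
    items = sorted(items)
    if len(items) == 1:
        return [(items[0], items[0])]
    return list(combinations(items, 2))


def stratify_by_compound(table: InteractionTable) -> list[Stratum]:
    """One stratum per compound; views are its sequence pairs."""
    partners: dict[str, list[str]] = {}
    for c, s in table.positives:
        partners.setdefault(c, []).append(s)
    strata = []
    for c in sorted(partners):
        pairs = _unordered_pairs(partners[c])
        views = tuple((c, p) for p in pairs)
        strata.append(Stratum("compound", c, views, frozenset(partners[c])))
    return strata


def stratify_by_sequence(table: InteractionTable) -> list[Stratum]:
    """One stratum per sequence; views are its compound pairs."""
    partners: dict[str, list[str]] = {}
    for c, s in table.positives:
        partners.setdefault(s, []).append(c)
    strata = []
    for s in sorted(partners):
        pairs = _unordered_pairs(partners[s])
        views = tuple((s, p) for p in pairs)
        strata.append(Stratum("sequence", s, views, frozenset(partners[s])))
    return strata


def _dedup(seq):
    seen = set()
    out = []
    for x in seq:
        if x not in seen:
            seen.add(x)
            out.append(x)
    return out


def stratify_by_reaction_feature(
    reactions: list[ReactionRecord], key_kind: str
) -> list[Stratum]:
    """Group reactions by a feature key and pool their three view lists.

    ``key_kind`` is ``"reaction"`` (each reaction its own key), ``"rclass"``
    or ``"ec"``. For rclass/ec a reaction with an empty key field is an
    error; grouping pools views across all member reactions of a key.
    """
    if not reactions:
        return []
    if key_kind not in ("reaction", "rclass", "ec"):
        raise ValueError(f"unknown reaction-feature key kind: {key_kind!r}")
    groups: dict[str, list[ReactionRecord]] = {}
    for rec in reactions:
        key = {
            "reaction": rec.reaction_id,
            "rclass": rec.rclass_id,
            "ec": rec.ec_number,
        }[key_kind]
        if not key:
            raise FormatError(
                f"reaction {rec.reaction_id!r} has no {key_kind} value"
            )
        groups.setdefault(key, []).append(rec)

    strata = []
    for key in sorted(groups):
        v1: list[tuple[str, str]] = []
        v2: list[tuple[str, str]] = []
        v3: list[tuple[str, str]] = []
        members: set[str] = set()
        for rec in groups[key]:
            v1.extend((r, p) for r in rec.reactant_ids for p in rec.product_ids)
            compounds = _dedup(list(rec.reactant_ids) + list(rec.product_ids))
            v2.extend((c, s) for c in compounds for s in rec.enzyme_ids)
            v3.extend(_unordered_pairs(list(set(rec.enzyme_ids))))
            members.update(compounds)
            members.update(rec.enzyme_ids)
        views = (tuple(_dedup(v1)), tuple(_dedup(v2)), tuple(_dedup(v3)))
        strata.append(Stratum(key_kind, key, views, frozenset(members)))
    return strata


@dataclass(frozen=True)
class StrataStats:
    """Per-stratum sizes plus mean pairwise overlap across strata.

    ``mean_shared`` is the mean of |A ∩ B| over unordered stratum pairs
    (A, B member sets); ``mean_jaccard`` the mean of |A ∩ B| / |A ∪ B|.
    Both are None when fewer than two strata exist.
    """

    sizes: dict = field(default_factory=dict)  # key_value -> (n_members, n_views)
    mean_shared: float | None = None
    mean_jaccard: float | None = None
    n_strata: int = 0


def compute_strata_stats(strata: list[Stratum]) -> StrataStats:
    sizes = {s.key_value: (len(s.members), s.n_views) for s in strata}
    if len(strata) < 2:
        return StrataStats(sizes, None, None, len(strata))
    shared_sum = 0.0
    jaccard_sum = 0.0
    n_pairs = 0
    member_sets = [s.members for s in strata]
    for a, b in combinations(member_sets, 2):
        inter = len(a & b)
        union = len(a | b)
        shared_sum += inter
        jaccard_sum += inter / union if union else 0.0
        n_pairs += 1
    return StrataStats(
        sizes, shared_sum / n_pairs, jaccard_sum / n_pairs, len(strata)
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_strata(strata: list[Stratum], path) -> None:
    """JSON-lines, one stratum per line."""
    with open(path, "w") as fh:
        for s in strata:
            fh.write(
                json.dumps(
                    {
                        "kind": s.kind,
                        "key": s.key_value,
                        "views": s.views,
                        "members": sorted(s.members),
                    }
                )
                + "\n"
            )


def read_strata(path) -> list[Stratum]:
    def as_pairs(v):
        return tuple((v0, tuple(v1) if isinstance(v1, list) else v1) for v0, v1 in v)

    strata = []
    with open(path) as fh:
        for line in fh:
            d = json.loads(line)
            if d["kind"] in ("compound", "sequence"):
                views = as_pairs(d["views"])
            else:
                views = tuple(tuple(tuple(p) for p in vl) for vl in d["views"])
            strata.append(Stratum(d["kind"], d["key"], views, frozenset(d["members"])))
    return strata


def write_strata_stats(stats: StrataStats, path) -> None:
    """TSV: one stratum per row plus a trailing summary block."""
    with open(path, "w") as fh:
        fh.write("key\tn_members\tn_views\n")
        for key, (nm, nv) in stats.sizes.items():
            fh.write(f"{key}\t{nm}\t{nv}\n")
        fh.write(f"#n_strata\t{stats.n_strata}\n")
        shared = nan if stats.mean_shared is None else stats.mean_shared
        jac = nan if stats.mean_jaccard is None else stats.mean_jaccard
        fh.write(f"#mean_shared\t{shared}\n#mean_jaccard\t{jac}\n")
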