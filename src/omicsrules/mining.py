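"""Frequent directional gene-set mining with dynamic thresholds.

Frequent item sets are mined with FP-growth over a prefix tree built on
descending item frequency; the candidate sets are then re-filtered by
their per-set dynamic support threshold, and rules (all antecedent/
consequent bipartitions) are kept only when confidence and lift clear
the set's dynamic confidence and lift thresholds.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from omicsrules.discretize import TransactionDB
from omicsrules.netdist import PairMatrix, ThresholdParams, avg_wesd, dbv_threshold


class MiningError(ValueError):
    pass


@dataclass
class GeneSetRecord:
    """A frequent directional item set with its support and, once the
    dynamic filter has run, its per-set support threshold."""

    items: frozenset[str]
    support: float
    count: int
    dbvs: float | None = None


@dataclass
class Rule:
    antecedent: frozenset[str]
    consequent: frozenset[str]
    support: float
    confidence: float
    lift: float
    avg_wesd: float = np.nan
    dbvc: float = np.nan
    dbvl: float = np.nan

    def __post_init__(self) -> None:
        if not self.antecedent or not self.consequent:
            raise MiningError("antecedent and consequent must be non-empty")
        if self.antecedent & self.consequent:
            raise MiningError("antecedent and consequent overlap")

    @property
    def items(self) -> frozenset[str]:
        return self.antecedent | self.consequent

    def label(self) -> str:
        lhs = ", ".join(sorted(self.antecedent))
        rhs = ", ".join(sorted(self.consequent))
        return f"{lhs} -> {rhs}"


def item_frequencies(db: TransactionDB, min_support: float = 0.0) -> dict[str, float]:
    """Per-item support, restricted to items at or above ``min_support``.

    The returned dict is ordered by descending support, ties broken
    lexicographically — the insertion order used by the FP-tree.
    """
    if db.n_transactions == 0:
        raise MiningError("empty transaction database")
    counts: dict[str, int] = defaultdict(int)
    for tx in db.transactions:
        for item in tx:
            counts[item] += 1
    n = db.n_transactions
    kept = {it: c / n for it, c in counts.items() if c / n >= min_support}
    return dict(sorted(kept.items(), key=lambda kv: (-kv[1], kv[0])))


class _FPNode:
    __slots__ = ("item", "count", "parent", "children", "link")

    def __init__(self, item: str | None, parent: "_FPNode | None"):
        self.item = item
        self.count = 0
        self.parent = parent
        self.children: dict[str, _FPNode] = {}
        self.link: _FPNode | None = None


def _build_tree(
    transactions: list[tuple[list[str], int]],
    min_count: int,
) -> tuple[_FPNode, dict[str, _FPNode], dict[str, int]]:
    counts: dict[str, int] = defaultdict(int)
    for items, weight in transactions:
        for item in items:
            counts[item] += weight
    frequent = {it: c for it, c in counts.items() if c >= min_count}
    order = {
        it: rank
        for rank, it in enumerate(
            sorted(frequent, key=lambda it: (-frequent[it], it))
        )
    }
    root = _FPNode(None, None)
    heads: dict[str, _FPNode] = {}
    for items, weight in transactions:
        path = sorted((it for it in items if it in order), key=order.__getitem__)
        node = root
        for item in path:
            child = node.children.get(item)
            if child is None:
                child = _FPNode(item, node)
                node.children[item] = child
                if item in heads:
                    tail = heads[item]
                    while tail.link is not None:
                        tail = tail.link
                    tail.link = child
                else:
                    heads[item] = child
            child.count += weight
            node = child
    return root, heads, frequent


def _mine_tree(
    heads: dict[str, _FPNode],
    frequent: dict[str, int],
    suffix: frozenset[str],
    min_count: int,
    max_size: int,
    out: dict[frozenset[str], int],
) -> None:
    # items in ascending frequency: bottom-up conditional pattern growth
    for item in sorted(frequent, key=lambda it: (frequent[it], it)):
        new_suffix = suffix | {item}
        out[new_suffix] = frequent[item]
        if len(new_suffix) >= max_size:
            continue
        # conditional pattern base for `item`
        conditional: list[tuple[list[str], int]] = []
        node = heads[item]
        while node is not None:
            path = []
            parent = node.parent
            while parent is not None and parent.item is not None:
                path.append(parent.item)
                parent = parent.parent
            if path:
                conditional.append((path[::-1], node.count))
            node = node.link
        if conditional:
            _, sub_heads, sub_frequent = _build_tree(conditional, min_count)
            if sub_frequent:
                _mine_tree(sub_heads, sub_frequent, new_suffix, min_count, max_size, out)


def mine_frequent(
    db: TransactionDB,
    min_support: float,
    max_size: int = 4,
    absolute: bool = False,
) -> list[GeneSetRecord]:
    """All item sets of size >= 1 with support >= ``min_support``.

    ``min_support`` is a fraction of the transaction count unless
    ``absolute`` is set, in which case it is a raw count. Results are
    sorted by (size, items) for determinism.
    """
    if db.n_transactions == 0:
        raise MiningError("empty transaction database")
    n = db.n_transactions
    min_count = float(min_support) if absolute else float(min_support) * n
    # support >= threshold with exact integer counts; guard float fuzz
    min_count_int = max(int(np.ceil(min_count - 1e-9)), 1)
    transactions = [(sorted(tx), 1) for tx in db.transactions]
    _, heads, frequent = _build_tree(transactions, min_count_int)
    found: dict[frozenset[str], int] = {}
    if frequent:
        _mine_tree(heads, frequent, frozenset(), min_count_int, max_size, found)
    records = [
        GeneSetRecord(items=items, support=count / n, count=count)
        for items, count in found.items()
    ]
    records.sort(key=lambda r: (len(r.items), tuple(sorted(r.items))))
    return records


def filter_by_dbvs(
    records: list[GeneSetRecord],
    wv_msc: PairMatrix,
    uv_min_s: float,
) -> list[GeneSetRecord]:
    """Keep sets whose support meets their own dynamic support threshold."""
    kept = []
    for rec in records:
        threshold = dbv_threshold(rec.items, wv_msc, uv_min_s)
        if rec.support >= threshold - 1e-12:
            kept.append(
                GeneSetRecord(
                    items=rec.items, support=rec.support, count=rec.count, dbvs=threshold
                )
            )
    return kept


def generate_rules(
    records: list[GeneSetRecord],
    supports: dict[frozenset[str], float],
    wv_mcc: PairMatrix,
    wv_mlc: PairMatrix,
    wesd: PairMatrix,
    params: ThresholdParams,
) -> list[Rule]:
    """Enumerate every bipartition of each frequent set of size >= 2 and
    keep rules clearing the set's dynamic confidence AND lift thresholds.

    ``supports`` must contain every subset of every record (guaranteed by
    support anti-monotonicity when records come from the same mining run
    without a dynamic filter in between; the dynamic set filter only
    shrinks the record list, not the support table).
    """
    rules: list[Rule] = []
    for rec in records:
        if len(rec.items) < 2:
            continue
        dbvc = dbv_threshold(rec.items, wv_mcc, params.uv_min_c)
        dbvl = dbv_threshold(rec.items, wv_mlc, params.ud_min_l)
        mean_dist = avg_wesd(rec.items, wesd)
        items = sorted(rec.items)
        for r in range(1, len(items)):
            for antecedent in itertools.combinations(items, r):
                a = frozenset(antecedent)
                b = rec.items - a
                supp_a = supports.get(a)
                supp_b = supports.get(b)
                assert supp_a, "antecedent of a frequent set must have support > 0"
                assert supp_b, "consequent of a frequent set must have support > 0"
                confidence = rec.support / supp_a
                lift = confidence / supp_b
                if confidence >= dbvc - 1e-12 and lift >= dbvl - 1e-12:
                    rules.append(
                        Rule(
                            antecedent=a,
                            consequent=b,
                            support=rec.support,
                            confidence=confidence,
                            lift=lift,
                            avg_wesd=mean_dist,
                            dbvc=dbvc,
                            dbvl=dbvl,
                        )
                    )
    rules.sort(key=lambda r: (tuple(sorted(r.antecedent)), tuple(sorted(r.consequent))))
    return rules


def support_table(records: list[GeneSetRecord]) -> dict[frozenset[str], float]:
    return {rec.items: rec.support for rec in records}


def mine_rules(
    db: TransactionDB,
    wv_msc: PairMatrix,
    wv_mcc: PairMatrix,
    wv_mlc: PairMatrix,
    wesd: PairMatrix,
    params: ThresholdParams,
    max_size: int = 4,
) -> tuple[list[GeneSetRecord], list[Rule]]:
    """Full mining stage: FP-growth, dynamic set filter, rule generation."""
    frequent = mine_frequent(db, params.uv_min_s, max_size=max_size)
    supports = support_table(frequent)
    kept_sets = filter_by_dbvs(frequent, wv_msc, params.uv_min_s)
    rules = generate_rules(kept_sets, supports, wv_mcc, wv_mlc, wesd, params)
    return kept_sets, rules
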