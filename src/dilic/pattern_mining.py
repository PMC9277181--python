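"""Frequent-pattern mining over keyword-set transactions.

Classic level-wise apriori: items are the canonical keyword-set strings a
document's transaction contains, support is counted as document presence
(not occurrence multiplicity), and supports are recorded separately for
the positive and negative classes.  ``brute_force_frequent`` enumerates
the whole lattice and is the test oracle; on any input within its guard
the two must agree exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

from .corpus_io import Label
from .text_processing import Transaction


@dataclass(frozen=True)
class Pattern:
    """A frequent itemset over keyword-set items with per-class support."""

    items: frozenset[str]
    support_pos: int
    support_neg: int

    @property
    def length(self) -> int:
        return len(self.items)

    @property
    def support(self) -> int:
        return self.support_pos + self.support_neg

    def sort_key(self) -> tuple:
        return (self.length, tuple(sorted(self.items)))


def _validate(transactions: list[Transaction], min_support: float) -> int:
    if not transactions:
        raise ValueError("empty transaction list")
    if not any(t.item_freq for t in transactions):
        raise ValueError("all transactions are empty")
    if not 0 < min_support <= 1:
        raise ValueError("min_support must be in (0, 1]")
    return math.ceil(min_support * len(transactions) - 1e-9)


def _count_classes(
    itemsets: list[frozenset[str]], transactions: list[Transaction]
) -> dict[frozenset[str], tuple[int, int]]:
    counts = {s: [0, 0] for s in itemsets}
    for t in transactions:
        items = t.items
        idx = 0 if t.label is Label.POSITIVE else 1
        for s in itemsets:
            if s <= items:
                counts[s][idx] += 1
    return {s: (c[0], c[1]) for s, c in counts.items()}


def mine_patterns(
    transactions: list[Transaction],
    min_support: float = 0.01,
    max_pattern_len: int = 3,
) -> list[Pattern]:
    """Apriori over the transactions' keyword-set items.

    Returns every itemset of size 1..max_pattern_len whose document
    frequency is at least ``ceil(min_support * n_transactions)``, with
    per-class supports, sorted by (length, items) for reproducible output.
    """
    min_count = _validate(transactions, min_support)
    n = len(transactions)
    min_count = max(min_count, 1)

    # L1: single pass over transactions
    counts: dict[str, list[int]] = {}
    for t in transactions:
        idx = 0 if t.label is Label.POSITIVE else 1
        for item in t.items:
            counts.setdefault(item, [0, 0])[idx] += 1
    frequent: dict[frozenset[str], tuple[int, int]] = {
        frozenset([item]): (c[0], c[1])
        for item, c in counts.items()
        if c[0] + c[1] >= min_count
    }
    patterns = dict(frequent)

    level = sorted(frequent, key=lambda s: tuple(sorted(s)))
    k = 1
    # pre-extract each transaction's frequent-item set for faster scans
    frequent_items = {next(iter(s)) for s in frequent}
    t_items = [
        (0 if t.label is Label.POSITIVE else 1, t.items & frequent_items)
        for t in transactions
    ]
    while level and k < max_pattern_len:
        k += 1
        candidates = _apriori_gen(level)
        if not candidates:
            break
        counts_k = {c: [0, 0] for c in candidates}
        for idx, items in t_items:
            if len(items) < k:
                continue
            for combo in combinations(sorted(items), k):
                s = frozenset(combo)
                if s in counts_k:
                    counts_k[s][idx] += 1
        level = []
        for s, c in counts_k.items():
            if c[0] + c[1] >= min_count:
                patterns[s] = (c[0], c[1])
                level.append(s)
        level.sort(key=lambda s: tuple(sorted(s)))

    out = [
        Pattern(items=s, support_pos=sp, support_neg=sn)
        for s, (sp, sn) in patterns.items()
    ]
    out.sort(key=Pattern.sort_key)
    return out


def _apriori_gen(level: list[frozenset[str]]) -> set[frozenset[str]]:
    """Level-wise join + prune: join k-itemsets sharing a (k-1)-prefix,
    keep candidates whose every k-subset is frequent."""
    prev = set(level)
    sorted_tuples = sorted(tuple(sorted(s)) for s in level)
    candidates: set[frozenset[str]] = set()
    by_prefix: dict[tuple[str, ...], list[str]] = {}
    for tup in sorted_tuples:
        by_prefix.setdefault(tup[:-1], []).append(tup[-1])
    for prefix, lasts in by_prefix.items():
        for a, b in combinations(lasts, 2):
            cand = frozenset(prefix + (a, b))
            if all(cand - {x} in prev for x in cand):
                candidates.add(cand)
    return candidates


def brute_force_frequent(
    transactions: list[Transaction],
    min_support: float = 0.01,
    max_pattern_len: int = 3,
    item_guard: int = 20,
) -> list[Pattern]:
    """Exhaustive oracle: enumerate every itemset up to max_pattern_len
    over the full item universe and count supports directly.

    Guarded to small universes (default ≤ 20 distinct items); identical
    output contract to :func:`mine_patterns`.
    """
    min_count = _validate(transactions, min_support)
    min_count = max(min_count, 1)
    universe = sorted({i for t in transactions for i in t.items})
    if len(universe) > item_guard:
        raise ValueError(f"brute-force guard exceeded: {len(universe)} items > {item_guard}")
    itemsets = [
        frozenset(c)
        for k in range(1, min(len(universe), max_pattern_len) + 1)
        for c in combinations(universe, k)
    ]
    counted = _count_classes(itemsets, transactions)
    out = [
        Pattern(items=s, support_pos=sp, support_neg=sn)
        for s, (sp, sn) in counted.items()
        if sp + sn >= min_count
    ]
    out.sort(key=Pattern.sort_key)
    return out
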