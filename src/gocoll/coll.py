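"""Level-by-level cross-ontology mining (COLL).

The driver starts from the transaction set at its deepest annotation
level, mines pairwise rules, then repeatedly *generalizes* — every term at
the current level is replaced by all of its is-a/part-of parents — and
mines again, one level at a time, until the termination level is reached.
Same-namespace rules are discarded at every level; each cross-ontology
rule is kept only if the current level is at or below its category pair's
trusted depth (level >= termination level).  Across levels, the first
(deepest) discovery of a term pair wins.  The accumulated set finally
passes two redundancy prunes rooted in the GO true-path rule:

* rules whose two terms stand in a child-ancestor relationship carry no
  new information and are removed;
* given X -> Y, the generalized X -> Ancestor(Y) is implied; it is
  removed when its confidence is within ``delta`` (default 10 points) of
  the specific rule's.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator

from .annotations import TransactionSet
from .mining import (
    CROSS_CATEGORIES,
    SAME_ONTOLOGY,
    MiningConfig,
    Rule,
    apriori_pairs,
    pair_key,
)
from .ontology import OntologyGraph

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TerminationLevels:
    """Per category-pair deepest trusted generalization levels.

    ``minlevel`` (the minimum of the three) is where the generalization
    loop stops: below it no category is trusted.
    """

    mf_cc: int
    cc_bp: int
    bp_mf: int

    @property
    def minlevel(self) -> int:
        return min(self.mf_cc, self.cc_bp, self.bp_mf)

    def for_pair(self, key: str) -> int:
        return {"mf_cc": self.mf_cc, "cc_bp": self.cc_bp, "bp_mf": self.bp_mf}[key]

    def for_category(self, category: str) -> int:
        return self.for_pair(pair_key(category))


class RuleSet:
    """Rules keyed by (antecedent, consequent); first insertion wins.

    Holds only cross-ontology rules — adding a same-namespace rule is a
    programming error.
    """

    def __init__(self) -> None:
        self._rules: dict[tuple[str, str], Rule] = {}

    def add(self, rule: Rule) -> bool:
        """Insert unless the key is already present; returns True if added."""
        if rule.category == SAME_ONTOLOGY:
            raise ValueError(f"same-ontology rule {rule.key} cannot enter a RuleSet")
        if rule.key in self._rules:
            return False
        self._rules[rule.key] = rule
        return True

    def __iter__(self) -> Iterator[Rule]:
        return iter(self._rules[k] for k in sorted(self._rules))

    def __len__(self) -> int:
        return len(self._rules)

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._rules

    def get(self, key: tuple[str, str]) -> Rule | None:
        return self._rules.get(key)

    def per_level_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for r in self._rules.values():
            counts[r.level] = counts.get(r.level, 0) + 1
        return dict(sorted(counts.items(), reverse=True))

    def per_category_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CROSS_CATEGORIES}
        for r in self._rules.values():
            counts[r.category] += 1
        return counts


@dataclass
class LevelRecord:
    """Per-level mining diagnostics (totals are pre-dedup)."""

    level: int
    n_rules_mined: int
    n_cross_ontology: int
    per_pair: dict[str, int]


@dataclass
class CollStats:
    """Run diagnostics: per-level records plus pruning bookkeeping."""

    levels: list[LevelRecord] = field(default_factory=list)
    total_mined: int = 0
    n_after_dedup: int = 0
    n_after_child_ancestor: int = 0
    n_final: int = 0


def generalize_level(
    t: TransactionSet, g: OntologyGraph, level: int
) -> TransactionSet:
    """Replace every term at ``level`` by all of its transitive parents.

    Set-union semantics deduplicate when a parent is already present.
    Terms at other levels pass through untouched.  A term at the target
    level with no is-a/part-of parent (an orphan or a namespace root mixed
    into deep data) is kept unchanged with a warning — dropping it would
    silently delete annotations.
    """
    if level < 2:
        raise ValueError("cannot generalize at level < 2")
    n_stuck = 0
    new_transactions: dict[str, frozenset[str]] = {}
    for gid, items in t.transactions.items():
        out: set[str] = set()
        for term in items:
            if g.level_or_fallback(term) == level and term not in g.orphans:
                parents = g.find_parents(term)
                if parents:
                    out |= parents
                else:
                    out.add(term)
                    n_stuck += 1
            else:
                out.add(term)
        new_transactions[gid] = frozenset(out)
    if n_stuck:
        logger.warning(
            "%d term occurrence(s) at level %d had no transitive parent and "
            "were kept unchanged", n_stuck, level
        )
    max_level = max(
        (g.level_or_fallback(term) for items in new_transactions.values()
         for term in items),
        default=0,
    )
    return TransactionSet(transactions=new_transactions, max_level=max_level)


def prune_same_ontology(rules: set[Rule]) -> set[Rule]:
    """Keep only rules whose terms come from two different namespaces."""
    return {r for r in rules if r.category in CROSS_CATEGORIES}


def prune_child_ancestor(rules: set[Rule] | RuleSet, g: OntologyGraph) -> set[Rule]:
    """Drop rules whose terms are related by ancestry (true-path implied)."""
    return {
        r
        for r in rules
        if not (
            g.is_ancestor(r.antecedent, r.consequent)
            or g.is_ancestor(r.consequent, r.antecedent)
        )
    }


def prune_redundant_ancestor(
    rules: set[Rule] | RuleSet, g: OntologyGraph, delta: float = 0.10
) -> set[Rule]:
    """Drop X -> Ancestor(Y) when X -> Y exists with a confidence gap
    < ``delta``; the more detailed rule is retained."""
    rules = set(rules)
    by_antecedent: dict[str, list[Rule]] = {}
    for r in rules:
        by_antecedent.setdefault(r.antecedent, []).append(r)
    removed: set[Rule] = set()
    for group in by_antecedent.values():
        for specific in group:
            for general in group:
                if general is specific:
                    continue
                gap = abs(general.confidence - specific.confidence)
                # strict <, guarded against float noise at the boundary
                if g.is_ancestor(general.consequent, specific.consequent) and (
                    delta - gap > 1e-9
                ):
                    removed.add(general)
    return rules - removed


def iter_level_rules(
    t0: TransactionSet,
    g: OntologyGraph,
    cfg: MiningConfig,
    minlevel: int,
) -> Iterator[tuple[int, TransactionSet, set[Rule]]]:
    """Yield (level, transactions, mined rules) from the deepest level of
    ``t0`` down to ``minlevel``, generalizing one level per step.

    The initial pass mines ``t0`` as-is (annotations mix levels); each
    subsequent pass mines the freshly generalized transactions.
    """
    level = t0.max_level
    t = t0
    if minlevel > level:
        logger.warning(
            "termination minlevel %d is deeper than the data's max level %d; "
            "nothing to mine", minlevel, level
        )
        return
    yield level, t, apriori_pairs(t, cfg, level=level, g=g)
    while level > minlevel:
        t = generalize_level(t, g, level)
        level -= 1
        yield level, t, apriori_pairs(t, cfg, level=level, g=g)


def run_coll(
    t0: TransactionSet,
    g: OntologyGraph,
    cfg: MiningConfig,
    term: TerminationLevels,
    delta: float = 0.10,
    stats: CollStats | None = None,
) -> RuleSet:
    """Full COLL: level-by-level mining, category-aware accumulation and
    all pruning passes.

    Single-level baseline behaviour is the degenerate case where all
    termination levels equal ``t0.max_level``: only the initial pass runs.
    Pass ``stats`` to collect per-level diagnostics.
    """
    if term.minlevel < 1:
        raise ValueError("termination minlevel must be >= 1")
    result = RuleSet()
    for level, _t, mined in iter_level_rules(t0, g, cfg, term.minlevel):
        cross = prune_same_ontology(mined)
        if stats is not None:
            per_pair = {k: 0 for k in ("mf_cc", "bp_mf", "cc_bp")}
            for r in cross:
                per_pair[pair_key(r.category)] += 1
            stats.levels.append(
                LevelRecord(level, len(mined), len(cross), per_pair)
            )
            stats.total_mined += len(mined)
        for r in sorted(cross, key=lambda r: r.key):
            if level >= term.for_category(r.category):
                result.add(r)  # first (deepest) discovery wins
    if stats is not None:
        stats.n_after_dedup = len(result)

    kept = prune_child_ancestor(result, g)
    if stats is not None:
        stats.n_after_child_ancestor = len(kept)
    kept = prune_redundant_ancestor(kept, g, delta=delta)
    final = RuleSet()
    for r in sorted(kept, key=lambda r: r.key):
        final.add(r)
    if stats is not None:
        stats.n_final = len(final)
    return final
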