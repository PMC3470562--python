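"""Monte-Carlo termination-level selection.

Generalization cannot be allowed to run all the way to the namespace
roots: very abstract terms co-occur by chance and the rule stream fills
with false discoveries.  To find the deepest level at which random data
starts producing cross-ontology rules, synthetic annotation corpora are
drawn under a null model with the same *shape* as the target dataset
(transaction count and per-transaction itemset sizes), mined with the
full level-by-level loop down to level 1, and the per-level false
discovery rate

    FDR(CO_i) = (CO_i / R_i) * 100

is averaged over replicate datasets, where CO_i is the number of rules of
a cross-ontology category pair discovered at generalization level i and
R_i the total number of rules mined at that level.  The termination level
of a pair is the level immediately deeper than the first level, scanning
from the deepest level toward the roots, whose average FDR reaches a
threshold (default 0.01).

Three null models are provided:

* ``uniform``     — terms drawn uniformly from the whole ontology;
* ``by-ontology`` — level drawn from the target's annotation-level
  distribution, namespace from the per-level namespace distribution, then
  a uniform term at that (level, namespace): mirrors the target's
  abstraction profile;
* ``replacement`` — annotations resampled with replacement from the
  multiset of all annotation instances in the target.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chisquare

from .annotations import TransactionSet
from .coll import TerminationLevels, iter_level_rules, prune_same_ontology
from .mining import PAIR_KEYS, MiningConfig, pair_key
from .ontology import NAMESPACES, OntologyGraph

logger = logging.getLogger(__name__)

GENERATOR_METHODS = ("uniform", "by-ontology", "replacement")


@dataclass
class LevelDistribution:
    """Empirical distribution of annotation instances over levels and
    (level, namespace) cells of a target dataset."""

    level_counts: Counter
    level_ns_counts: Counter
    total: int

    def p_level(self) -> dict[int, float]:
        return {lv: c / self.total for lv, c in sorted(self.level_counts.items())}

    def p_ns_given_level(self, level: int) -> dict[str, float]:
        total = self.level_counts[level]
        return {
            ns: self.level_ns_counts[(level, ns)] / total
            for ns in NAMESPACES
            if self.level_ns_counts[(level, ns)]
        }


def level_distribution(t: TransactionSet, g: OntologyGraph) -> LevelDistribution:
    """Count every annotation instance (repeats across transactions
    included) by level and by (level, namespace)."""
    if len(t) == 0:
        raise ValueError("empty transaction set")
    level_counts: Counter = Counter()
    level_ns_counts: Counter = Counter()
    total = 0
    for term in t.annotation_instances():
        lv = g.level_or_fallback(term)
        level_counts[lv] += 1
        level_ns_counts[(lv, g.namespace(term))] += 1
        total += 1
    return LevelDistribution(level_counts, level_ns_counts, total)


def transaction_shape(t: TransactionSet) -> list[int]:
    """Per-transaction itemset sizes, in deterministic (gene id) order."""
    return [len(t.transactions[gid]) for gid in sorted(t.transactions)]


def _buffered(batch_fn, batch_size: int = 8192):
    """Turn a vectorised sampler ``batch_fn(n) -> list`` into a
    one-at-a-time draw with an internal prefetch buffer (the draw order,
    and hence determinism per seed, is preserved)."""
    buffer: list = []
    pos = 0

    def draw_one():
        nonlocal buffer, pos
        if pos >= len(buffer):
            buffer = batch_fn(batch_size)
            pos = 0
        item = buffer[pos]
        pos += 1
        return item

    return draw_one


def _build_synthetic(
    shape: list[int], draw_one, vocab_size: int
) -> TransactionSet:
    """Assemble transactions of the requested sizes; duplicate draws
    within a transaction are rejected and redrawn, so the shape is
    preserved exactly."""
    if max(shape, default=0) > vocab_size:
        raise ValueError(
            f"an itemset of size {max(shape)} cannot be drawn from a "
            f"vocabulary of {vocab_size} term(s)"
        )
    transactions: dict[str, frozenset[str]] = {}
    for i, size in enumerate(shape):
        items: set[str] = set()
        while len(items) < size:
            items.add(draw_one())
        transactions[f"SYN{i:06d}"] = frozenset(items)
    return transactions


def _finish(transactions: dict[str, frozenset[str]], g: OntologyGraph) -> TransactionSet:
    max_level = max(
        (g.level_or_fallback(t) for items in transactions.values() for t in items),
        default=0,
    )
    return TransactionSet(transactions=transactions, max_level=max_level)


def gen_uniform_random(
    g: OntologyGraph, shape: list[int], seed: int
) -> TransactionSet:
    """Annotations drawn uniformly from all terms of the three
    sub-ontologies."""
    rng = np.random.default_rng(seed)
    vocab = sorted(g.terms)
    draw = _buffered(lambda n: [vocab[i] for i in rng.integers(len(vocab), size=n)])
    return _finish(_build_synthetic(shape, draw, len(vocab)), g)


def gen_random_by_ontology(
    g: OntologyGraph, d: LevelDistribution, shape: list[int], seed: int
) -> TransactionSet:
    """Three-stage draw: level from ``d``, namespace from ``d`` at that
    level, then a uniform term at that (level, namespace)."""
    rng = np.random.default_rng(seed)
    p_level = d.p_level()
    levels = list(p_level)
    level_probs = np.array([p_level[lv] for lv in levels])
    ns_choices: dict[int, tuple[list[str], np.ndarray]] = {}
    pools: dict[tuple[int, str], list[str]] = {}
    for lv in levels:
        pns = d.p_ns_given_level(lv)
        ns_choices[lv] = (list(pns), np.array(list(pns.values())))
        for ns in pns:
            pool = g.terms_at(lv, ns)
            if not pool:
                raise ValueError(
                    f"target has annotations at level {lv} namespace {ns} "
                    "but the ontology has no terms there"
                )
            pools[(lv, ns)] = pool

    def batch(n: int) -> list[str]:
        lv_idx = rng.choice(len(levels), size=n, p=level_probs)
        out: list[str] = []
        for i in lv_idx:
            lv = levels[i]
            names, probs = ns_choices[lv]
            ns = names[rng.choice(len(names), p=probs)] if len(names) > 1 else names[0]
            pool = pools[(lv, ns)]
            out.append(pool[rng.integers(len(pool))])
        return out

    vocab_size = sum(len(p) for p in pools.values())
    return _finish(_build_synthetic(shape, _buffered(batch), vocab_size), g)


def gen_sampling_replacement(
    t: TransactionSet, g: OntologyGraph, shape: list[int], seed: int
) -> TransactionSet:
    """Annotations resampled uniformly with replacement from the multiset
    of all annotation instances in the target."""
    if len(t) == 0:
        raise ValueError("empty target transaction set")
    rng = np.random.default_rng(seed)
    background = sorted(t.annotation_instances())
    draw = _buffered(
        lambda n: [background[i] for i in rng.integers(len(background), size=n)]
    )
    return _finish(_build_synthetic(shape, draw, len(set(background))), g)


def make_generator(method: str, g: OntologyGraph, target: TransactionSet):
    """Bind a named null model to its target; returns f(shape, seed)."""
    if method == "uniform":
        return lambda shape, seed: gen_uniform_random(g, shape, seed)
    if method == "by-ontology":
        d = level_distribution(target, g)
        return lambda shape, seed: gen_random_by_ontology(g, d, shape, seed)
    if method == "replacement":
        return lambda shape, seed: gen_sampling_replacement(target, g, shape, seed)
    raise ValueError(f"unknown generator method {method!r}; "
                     f"choose from {GENERATOR_METHODS}")


def level_gof_pvalue(
    synthetic: TransactionSet, g: OntologyGraph, d: LevelDistribution
) -> float:
    """Chi-square goodness of fit of a synthetic dataset's annotation
    level histogram against a target distribution.

    Any mass at a level outside the target's support is an automatic
    mismatch (p = 0).
    """
    observed: Counter = Counter()
    n = 0
    for term in synthetic.annotation_instances():
        observed[g.level_or_fallback(term)] += 1
        n += 1
    p_level = d.p_level()
    if any(lv not in p_level for lv in observed):
        return 0.0
    levels = sorted(p_level)
    f_obs = np.array([observed.get(lv, 0) for lv in levels], dtype=float)
    f_exp = np.array([p_level[lv] * n for lv in levels])
    if len(levels) < 2:
        return 1.0
    return float(chisquare(f_obs, f_exp).pvalue)


# ---------------------------------------------------------------------------
# FDR table and termination selection
# ---------------------------------------------------------------------------


@dataclass
class FDRTable:
    """Average per-level, per-pair false discovery rates over replicates.

    ``fdr`` is indexed by generalization level (descending) with one
    column per category pair; values are on the percent-like scale of the
    (CO_i / R_i) * 100 formula.
    """

    fdr: pd.DataFrame
    n_datasets: int

    def to_tsv(self) -> str:
        out = self.fdr.copy()
        out.index.name = "level"
        return out.to_csv(sep="\t", float_format="%.5f")


def fdr_table(
    g: OntologyGraph,
    target: TransactionSet,
    cfg: MiningConfig,
    generator: str = "by-ontology",
    n_datasets: int = 50,
    seed: int = 0,
) -> FDRTable:
    """Average FDR of random cross-ontology rules per level and pair.

    Each replicate draws a synthetic dataset with the target's shape
    (replicate ``i`` uses ``seed + i``), runs the level-by-level loop to
    level 1, and records per level the total rule count R_i and the
    cross-ontology count CO_i for each pair.  Per-replicate FDR values
    (0 whenever R_i = 0) are averaged across replicates.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    gen = generator if callable(generator) else make_generator(generator, g, target)
    shape = transaction_shape(target)
    per_replicate: list[dict[tuple[int, str], float]] = []
    all_levels: set[int] = set()
    for rep in range(n_datasets):
        synth = gen(shape, seed + rep)
        table: dict[tuple[int, str], float] = {}
        for level, _t, mined in iter_level_rules(synth, g, cfg, minlevel=1):
            all_levels.add(level)
            r_i = len(mined)
            co = {k: 0 for k in PAIR_KEYS}
            for r in prune_same_ontology(mined):
                co[pair_key(r.category)] += 1
            for k in PAIR_KEYS:
                table[(level, k)] = (co[k] / r_i) * 100 if r_i else 0.0
        per_replicate.append(table)

    levels = sorted(all_levels, reverse=True)
    data = {
        k: [
            float(np.mean([rep.get((lv, k), 0.0) for rep in per_replicate]))
            for lv in levels
        ]
        for k in PAIR_KEYS
    }
    df = pd.DataFrame(data, index=levels, columns=list(PAIR_KEYS))
    return FDRTable(fdr=df, n_datasets=n_datasets)


def termination_levels(f: FDRTable, threshold: float = 0.01) -> TerminationLevels:
    """Select per-pair termination levels from an FDR table.

    Scanning from the deepest level toward the roots, the termination
    level is the level immediately deeper than the first level whose FDR
    reaches ``threshold`` (>=, so a value printed exactly at the threshold
    crosses).  If no level crosses, the shallowest level of the table is
    used.  ``minlevel`` is the minimum over the three pairs.
    """
    if f.fdr.empty:
        raise ValueError("empty FDR table")
    levels = sorted(f.fdr.index, reverse=True)
    chosen: dict[str, int] = {}
    for k in PAIR_KEYS:
        term = levels[-1]  # shallowest, if nothing crosses
        for lv in levels:
            if f.fdr.loc[lv, k] >= threshold:
                term = lv + 1
                break
        chosen[k] = term
    return TerminationLevels(
        mf_cc=chosen["mf_cc"], cc_bp=chosen["cc_bp"], bp_mf=chosen["bp_mf"]
    )
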