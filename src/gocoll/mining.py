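"""Pairwise association rule mining under support / confidence / chi-square.

Rules here are single-antecedent, single-consequent term pairs X -> Y:

* support  s(X->Y) = P(X and Y)  — fraction of transactions with both,
* confidence c(X->Y) = P(Y | X)  — fraction of X-transactions with Y,
* a 1-df chi-square test on the 2x2 contingency table of X and Y
  (no continuity correction) supplies a p-value measuring dependence.

``apriori_pairs`` applies the Apriori property at the item stage: an item
whose own support is below the threshold can appear in no rule, so only
frequent items generate candidate pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

from scipy.stats import chi2

from .annotations import TransactionSet
from .ontology import OntologyGraph, UnknownTermError

logger = logging.getLogger(__name__)

#: The six directed cross-ontology categories plus the same-namespace bucket.
SAME_ONTOLOGY = "same_ontology"
CROSS_CATEGORIES = ("MF->CC", "CC->MF", "CC->BP", "BP->CC", "BP->MF", "MF->BP")

#: Unordered category pairs, as used for termination levels / FDR columns.
PAIR_KEYS = ("mf_cc", "bp_mf", "cc_bp")
_PAIR_OF_CATEGORY = {
    "MF->CC": "mf_cc", "CC->MF": "mf_cc",
    "BP->MF": "bp_mf", "MF->BP": "bp_mf",
    "CC->BP": "cc_bp", "BP->CC": "cc_bp",
}


def pair_key(category: str) -> str:
    """Collapse a directed category into its unordered pair key."""
    return _PAIR_OF_CATEGORY[category]


@dataclass(frozen=True)
class MiningConfig:
    """Interestingness thresholds.

    Defaults are the standard COLL operating point: a deliberately low
    support (0.05%) because rare but reliable co-annotations are the
    interesting ones, a high confidence (60%), and chi-square p <= 0.01.
    """

    min_support: float = 0.0005
    min_confidence: float = 0.60
    p_threshold: float = 0.01

    def __post_init__(self) -> None:
        for name, v in (
            ("min_support", self.min_support),
            ("min_confidence", self.min_confidence),
            ("p_threshold", self.p_threshold),
        ):
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")


@dataclass(frozen=True)
class Rule:
    """An association rule antecedent -> consequent with its statistics."""

    antecedent: str
    consequent: str
    support: float
    confidence: float
    p_value: float
    level: int | None = None
    category: str | None = None

    def __post_init__(self) -> None:
        if self.antecedent == self.consequent:
            raise ValueError("antecedent and consequent must differ")

    @property
    def key(self) -> tuple[str, str]:
        return (self.antecedent, self.consequent)


def chi_square_2x2(n11: int, n10: int, n01: int, n00: int) -> tuple[float, float]:
    """Chi-square statistic and p-value for a 2x2 table, 1 df, no Yates
    correction.

    Cells: n11 = both, n10 = X only, n01 = Y only, n00 = neither.  A zero
    marginal makes independence untestable; the statistic is defined as 0
    (p = 1) in that case.
    """
    n = n11 + n10 + n01 + n00
    r1, r0 = n11 + n10, n01 + n00
    c1, c0 = n11 + n01, n10 + n00
    if 0 in (r1, r0, c1, c0):
        return 0.0, 1.0
    stat = n * (n11 * n00 - n10 * n01) ** 2 / (r1 * r0 * c1 * c0)
    if min(r1 * c1, r1 * c0, r0 * c1, r0 * c0) / n < 5:
        logger.debug("2x2 table with an expected cell < 5; chi-square is "
                     "approximate")
    return stat, float(chi2.sf(stat, df=1))


def rule_metrics(
    t: TransactionSet, x: str, y: str
) -> tuple[float, float, float]:
    """(support, confidence, p_value) for the rule x -> y over ``t``."""
    if x == y:
        raise ValueError("x and y must differ")
    n = len(t)
    if n == 0:
        raise ValueError("empty transaction set")
    n_x = n_y = n_both = 0
    for items in t.transactions.values():
        has_x, has_y = x in items, y in items
        n_x += has_x
        n_y += has_y
        n_both += has_x and has_y
    if n_x == 0:
        raise ValueError(f"{x} occurs in no transaction; confidence undefined")
    support = n_both / n
    confidence = n_both / n_x
    _, p = chi_square_2x2(n_both, n_x - n_both, n_y - n_both, n - n_x - n_y + n_both)
    return support, confidence, p


def classify_category(antecedent: str, consequent: str, g: OntologyGraph) -> str:
    """Directed namespace category of a term pair; same namespace ->
    ``same_ontology``."""
    ns_a, ns_c = g.namespace(antecedent), g.namespace(consequent)
    if ns_a == ns_c:
        return SAME_ONTOLOGY
    return f"{ns_a}->{ns_c}"


def apriori_pairs(
    t: TransactionSet,
    cfg: MiningConfig,
    level: int | None = None,
    g: OntologyGraph | None = None,
) -> set[Rule]:
    """All rules x -> y meeting the thresholds of ``cfg``.

    Candidate pairs are generated only from items that are individually
    frequent (support >= min_support): since s(x->y) <= s(x), an
    infrequent item can appear in no rule.  When ``g`` is supplied each
    rule is annotated with its namespace category; ``level`` records the
    generalization level at discovery.
    """
    n = len(t)
    if n == 0:
        raise ValueError("empty transaction set")
    occ: dict[str, set[int]] = {}
    for idx, items in enumerate(t.transactions.values()):
        for item in items:
            occ.setdefault(item, set()).add(idx)
    min_count = cfg.min_support * n
    frequent = {item: txns for item, txns in occ.items() if len(txns) >= min_count}

    rules: set[Rule] = set()
    for x, y in combinations(sorted(frequent), 2):
        tx, ty = frequent[x], frequent[y]
        n_both = len(tx & ty)
        support = n_both / n
        if support < cfg.min_support or n_both == 0:
            continue
        _, p = chi_square_2x2(
            n_both, len(tx) - n_both, len(ty) - n_both, n - len(tx) - len(ty) + n_both
        )
        if p > cfg.p_threshold:
            continue
        for ante, cons, n_ante in ((x, y, len(tx)), (y, x, len(ty))):
            confidence = n_both / n_ante
            if confidence < cfg.min_confidence:
                continue
            category = classify_category(ante, cons, g) if g is not None else None
            rules.add(
                Rule(
                    antecedent=ante,
                    consequent=cons,
                    support=support,
                    confidence=confidence,
                    p_value=p,
                    level=level,
                    category=category,
                )
            )
    return rules
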