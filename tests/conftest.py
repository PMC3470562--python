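"""Shared toy ontologies and transaction sets.

All OBO/GAF content is generated or inlined as text and goes through the
production parsers, so every test exercises real I/O.
"""

from __future__ import annotations

import io
import itertools

import pytest

import numpy as np
from scipy.stats import chi2_contingency

from gocoll import TransactionSet, parse_obo
from gocoll.mining import MiningConfig


def _stanza(tid: str, ns: str, is_a=(), part_of=(), other=()) -> str:
    lines = [f"[Term]", f"id: {tid}", f"name: {tid} name", f"namespace: {ns}"]
    lines += [f"is_a: {p}" for p in is_a]
    lines += [f"relationship: part_of {p}" for p in part_of]
    lines += [f"relationship: {rel} {p}" for rel, p in other]
    return "\n".join(lines)


def make_obo(*stanzas: str) -> str:
    return "format-version: 1.2\n\n" + "\n\n".join(stanzas) + "\n"


MF = "molecular_function"
BP = "biological_process"
CC = "cellular_component"

# Three-level MF and BP chains plus a CC root: the smallest ontology on
# which the full generalization loop is interesting.
M0, M1, M2 = "GO:2000000", "GO:2000001", "GO:2000002"
B0, B1, B2 = "GO:3000000", "GO:3000001", "GO:3000002"
C0 = "GO:1000000"

CHAINS_OBO = make_obo(
    _stanza(M0, MF),
    _stanza(M1, MF, is_a=[M0]),
    _stanza(M2, MF, is_a=[M1]),
    _stanza(B0, BP),
    _stanza(B1, BP, is_a=[B0]),
    _stanza(B2, BP, is_a=[B1]),
    _stanza(C0, CC),
)

# A diamond: D has two parents P1 (is_a) and P2 (part_of), both under R.
R, P1, P2, D = "GO:2000010", "GO:2000011", "GO:2000012", "GO:2000013"
DIAMOND_OBO = make_obo(
    _stanza(R, MF),
    _stanza(P1, MF, is_a=[R]),
    _stanza(P2, MF, part_of=[R]),
    _stanza(D, MF, is_a=[P1], part_of=[P2]),
)


@pytest.fixture(scope="session")
def chains_graph():
    return parse_obo(io.StringIO(CHAINS_OBO))


@pytest.fixture(scope="session")
def diamond_graph():
    return parse_obo(io.StringIO(DIAMOND_OBO))


def transactions(itemsets: dict[str, set[str]], g) -> TransactionSet:
    txns = {gid: frozenset(items) for gid, items in itemsets.items()}
    max_level = max(
        (g.level_or_fallback(t) for items in txns.values() for t in items), default=0
    )
    return TransactionSet(transactions=txns, max_level=max_level)


@pytest.fixture()
def toy4(chains_graph) -> TransactionSet:
    """The four-transaction worked example: the (M2, B2) pair co-occurs in
    2 of 4 transactions, M2 alone in a third."""
    return transactions(
        {"g1": {M2, B2}, "g2": {M2, B2}, "g3": {M2, B1}, "g4": {C0}},
        chains_graph,
    )


def brute_force_pairs(t: TransactionSet, cfg: MiningConfig, g=None) -> set[tuple]:
    """Independent oracle: exhaustively test every ordered pair of items
    against the thresholds by direct counting.  Returns (ante, cons) keys."""
    items = sorted({i for s in t.transactions.values() for i in s})
    n = len(t)
    out = set()
    for x, y in itertools.permutations(items, 2):
        n_x = sum(x in s for s in t.transactions.values())
        n_y = sum(y in s for s in t.transactions.values())
        n_both = sum(x in s and y in s for s in t.transactions.values())
        if n_both == 0:
            continue
        support = n_both / n
        confidence = n_both / n_x
        table = np.array([[n_both, n_x - n_both],
                          [n_y - n_both, n - n_x - n_y + n_both]])
        if 0 in table.sum(axis=0) or 0 in table.sum(axis=1):
            p = 1.0
        else:
            p = chi2_contingency(table, correction=False).pvalue
        if support >= cfg.min_support and confidence >= cfg.min_confidence \
                and p <= cfg.p_threshold:
            out.add((x, y))
    return out
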