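"""GAF annotation reading and transaction construction.

Each gene product becomes one *transaction*: the duplicate-free set of GO
terms annotated to it.  Co-occurrence of terms within transactions is the
signal the miner works on, so the filters applied here (evidence-code
exclusion, NOT qualifiers, terms absent from the ontology) directly define
the mined corpus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, TextIO

from .ontology import GO_ID_PATTERN, OntologyGraph

logger = logging.getLogger(__name__)


class GafFormatError(ValueError):
    """Raised for a GAF row with the wrong column count."""


@dataclass(frozen=True)
class Annotation:
    """One GAF row reduced to the fields the miner needs."""

    gene_id: str
    term: str
    evidence: str
    aspect: str  # C / F / P

    def __post_init__(self) -> None:
        if not self.evidence or self.evidence != self.evidence.upper():
            raise ValueError(f"evidence code {self.evidence!r} must be uppercase")


@dataclass
class TransactionSet:
    """Gene-product transactions at a stated maximum level.

    ``max_level`` is the level of the deepest annotation present; the
    generalization loop starts there and walks toward the roots.
    """

    transactions: dict[str, frozenset[str]]
    max_level: int

    def __len__(self) -> int:
        return len(self.transactions)

    def items(self):
        return self.transactions.items()

    def annotation_instances(self) -> Iterable[str]:
        """Every annotation, counting repeats across transactions."""
        for items in self.transactions.values():
            yield from items


_GAF_COLUMN_COUNTS = (15, 17)  # GAF 1.x / GAF 2.x


def read_gaf(
    source: str | TextIO,
    excluded_evidence: frozenset[str] | set[str] = frozenset(),
) -> list[Annotation]:
    """Read a GAF 2.0/2.2 file into a list of :class:`Annotation`.

    Rows whose evidence code is in ``excluded_evidence`` are dropped
    (e.g. ``{"IEA"}`` removes electronically inferred annotations), as are
    rows with a ``NOT`` qualifier — a negated annotation is not a
    co-occurrence.  Rows whose GO id does not match the accession pattern
    are skipped with a warning.
    """
    if isinstance(source, str):
        with open(source, "rt", encoding="utf-8") as fh:
            lines = fh.readlines()
    else:
        lines = source.readlines()
    excluded = {e.upper() for e in excluded_evidence}

    annots: list[Annotation] = []
    for rowno, raw in enumerate(lines, start=1):
        if not raw.strip() or raw.startswith("!"):
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) not in _GAF_COLUMN_COUNTS:
            raise GafFormatError(
                f"row {rowno}: expected 15 or 17 tab-separated columns, "
                f"got {len(fields)}"
            )
        gene_id, qualifier, go_id = fields[1], fields[3], fields[4]
        evidence, aspect = fields[6].upper(), fields[8]
        if "NOT" in qualifier.split("|"):
            continue
        if evidence in excluded:
            continue
        if not GO_ID_PATTERN.match(go_id):
            logger.warning("row %d: %r is not a GO accession; skipped", rowno, go_id)
            continue
        annots.append(
            Annotation(gene_id=gene_id, term=go_id, evidence=evidence, aspect=aspect)
        )
    return annots


_ASPECT_BY_NAMESPACE = {"CC": "C", "MF": "F", "BP": "P"}


def build_transactions(
    annots: list[Annotation], g: OntologyGraph
) -> TransactionSet:
    """Group annotations by gene product into duplicate-free itemsets.

    Annotations to terms absent from ``g`` are dropped with a logged
    count.  The aspect column is cross-checked against the ontology
    namespace; on mismatch the ontology wins and a warning is logged.
    """
    itemsets: dict[str, set[str]] = {}
    n_unknown = 0
    n_aspect_mismatch = 0
    for a in annots:
        if a.term not in g:
            n_unknown += 1
            continue
        expected = _ASPECT_BY_NAMESPACE[g.namespace(a.term)]
        if a.aspect and a.aspect != expected:
            n_aspect_mismatch += 1
        itemsets.setdefault(a.gene_id, set()).add(a.term)
    if n_unknown:
        logger.warning("%d annotation(s) to terms absent from the ontology dropped",
                       n_unknown)
    if n_aspect_mismatch:
        logger.warning("%d annotation(s) with aspect/namespace mismatch; "
                       "ontology namespace used", n_aspect_mismatch)
    transactions = {gid: frozenset(items) for gid, items in itemsets.items() if items}
    max_level = max(
        (g.level_or_fallback(t) for items in transactions.values() for t in items),
        default=0,
    )
    logger.info("built %d transaction(s), max level %d", len(transactions), max_level)
    return TransactionSet(transactions=transactions, max_level=max_level)
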