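"""Synthetic toy ontologies and annotation corpora.

Every other module is exercised against small generated inputs: three
rooted term trees (one per GO namespace, with an optional fraction of
"diamond" terms carrying a second parent) serialized to real OBO text,
and gene-annotation corpora with *planted* cross-ontology co-occurrences
serialized to real GAF 2.2 — so tests go through the production parsers,
not just in-memory objects.

Term accessions are allocated deterministically per namespace
(CC = GO:1xxxxxx, MF = GO:2xxxxxx, BP = GO:3xxxxxx) so planted rules can
name terms before the ontology is built.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .annotations import _ASPECT_BY_NAMESPACE
from .ontology import BP, CC, MF, NAMESPACES, OntologyGraph, parse_obo

logger = logging.getLogger(__name__)

_NS_LONG = {CC: "cellular_component", MF: "molecular_function", BP: "biological_process"}
_NS_BASE = {CC: 1_000_000, MF: 2_000_000, BP: 3_000_000}


def term_id(namespace: str, index: int) -> str:
    """Deterministic toy accession for the ``index``-th term (breadth
    first, root = 0) of a namespace."""
    return f"GO:{_NS_BASE[namespace] + index:07d}"


@dataclass
class FixtureSpec:
    """Parameters of a toy ontology + annotation corpus.

    Each namespace is a ``branching``-ary tree of ``depth`` levels;
    ``diamond_fraction`` of the terms at levels >= 3 get a second parent
    (a part-of edge, so both transitive relations are exercised).  Each of
    ``n_genes`` gene products receives its planted pairs (both terms
    co-assigned with the stated probability) plus up to
    ``annotations_per_gene`` background annotations drawn uniformly from
    the leaf terms, each slot filled with probability ``noise``.
    """

    depth: int = 4
    branching: int = 2
    diamond_fraction: float = 0.0
    n_genes: int = 200
    annotations_per_gene: int = 4
    planted_rules: list[tuple[str, str, float]] = field(default_factory=list)
    noise: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 2 or self.branching < 1:
            raise ValueError("depth must be >= 2 and branching >= 1")
        for a, b, p in self.planted_rules:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"planted probability {p} outside [0, 1]")
        if not (0.0 <= self.noise <= 1.0):
            raise ValueError("noise probability must be in [0, 1]")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FixtureSpec":
        data = json.loads(text)
        data["planted_rules"] = [tuple(r) for r in data.get("planted_rules", [])]
        return cls(**data)


def make_toy_ontology(spec: FixtureSpec) -> tuple[OntologyGraph, str]:
    """Build the three toy namespace DAGs and serialize them to OBO.

    Returns the graph *as parsed back from the OBO text* together with
    the text itself, so the production parser is always in the loop.
    """
    rng = np.random.default_rng(spec.seed)
    stanzas: list[str] = []
    for ns in NAMESPACES:
        # Breadth-first tree: level l (1-based) holds branching**(l-1) terms.
        level_start = [0]
        count = 0
        for lv in range(1, spec.depth + 1):
            level_start.append(count)
            count += spec.branching ** (lv - 1)
        for lv in range(1, spec.depth + 1):
            n_here = spec.branching ** (lv - 1)
            start = level_start[lv]
            for j in range(n_here):
                idx = start + j
                tid = term_id(ns, idx)
                lines = [
                    "[Term]",
                    f"id: {tid}",
                    f"name: {ns.lower()} term {idx}",
                    f"namespace: {_NS_LONG[ns]}",
                ]
                if lv > 1:
                    parent_idx = level_start[lv - 1] + j // spec.branching
                    lines.append(f"is_a: {term_id(ns, parent_idx)}")
                    if lv >= 3 and rng.random() < spec.diamond_fraction:
                        candidates = [
                            level_start[lv - 1] + k
                            for k in range(spec.branching ** (lv - 2))
                            if level_start[lv - 1] + k != parent_idx
                        ]
                        if candidates:
                            second = candidates[rng.integers(len(candidates))]
                            lines.append(
                                f"relationship: part_of {term_id(ns, second)}"
                            )
                        else:
                            logger.warning(
                                "no second-parent candidate for %s; diamond skipped",
                                tid,
                            )
                stanzas.append("\n".join(lines))
    obo_text = "format-version: 1.2\n\n" + "\n\n".join(stanzas) + "\n"
    return parse_obo(io.StringIO(obo_text)), obo_text


_GAF_HEADER = "!gaf-version: 2.2\n"


def _gaf_row(gene: str, term: str, aspect: str, evidence: str = "IDA") -> str:
    cols = [
        "TOY", gene, gene, "", term, "TOY:0000001", evidence, "", aspect,
        "", "", "protein", "taxon:9031", "20120101", "TOY", "", "",
    ]
    return "\t".join(cols)


def make_toy_annotations(g: OntologyGraph, spec: FixtureSpec) -> str:
    """Generate a GAF 2.2 corpus over ``g`` per the fixture spec.

    For each gene, each planted (a, b, p) pair co-assigns both terms with
    probability p; background annotations are drawn uniformly from the
    ontology's leaves.
    """
    for a, b, _p in spec.planted_rules:
        if a not in g or b not in g:
            raise ValueError(f"planted pair ({a}, {b}) references unknown terms")
        if g.namespace(a) == g.namespace(b):
            raise ValueError(
                f"planted pair ({a}, {b}) must span two different namespaces"
            )
    rng = np.random.default_rng(spec.seed + 1)  # independent of ontology draws
    leaves = g.leaves()
    rows: list[str] = []
    for i in range(spec.n_genes):
        gene = f"GENE{i:05d}"
        items: set[str] = set()
        for a, b, p in spec.planted_rules:
            if rng.random() < p:
                items |= {a, b}
        for _slot in range(spec.annotations_per_gene):
            if rng.random() < spec.noise:
                items.add(leaves[rng.integers(len(leaves))])
        for term in sorted(items):
            rows.append(_gaf_row(gene, term, _ASPECT_BY_NAMESPACE[g.namespace(term)]))
    return _GAF_HEADER + "\n".join(rows) + ("\n" if rows else "")
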