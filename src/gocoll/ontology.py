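"""Gene Ontology structure: OBO parsing, levels, parents and ancestry.

The GO is three rooted DAGs (Cellular Component, Molecular Function,
Biological Process).  Only *is-a* and *part-of* edges are transitive, so
generalization — replacing a term by its parents — follows those two
relation types exclusively; every other relationship (``regulates``,
``has_part``, ...) is retained in the graph but never traversed.

A term's *level* is 1 + the length of the longest is-a/part-of path to its
namespace root (roots sit at level 1).  The longest-path definition
guarantees every transitive parent is strictly shallower than its child,
which is what makes level-by-level generalization terminate.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: The three GO sub-ontologies, by conventional short code.
CC, MF, BP = "CC", "MF", "BP"
NAMESPACES = (CC, MF, BP)

_NAMESPACE_CODES = {
    "cellular_component": CC,
    "molecular_function": MF,
    "biological_process": BP,
}

#: Relations along which annotation generalization is allowed.
TRANSITIVE_RELATIONS = frozenset({"is_a", "part_of"})

GO_ID_PATTERN = re.compile(r"^GO:\d{7}$")


class OboParseError(ValueError):
    """Raised for a structurally invalid OBO document."""


class OntologyValidationError(ValueError):
    """Raised when a parsed ontology violates GO structural constraints."""


class UnknownTermError(KeyError):
    """Raised when a GO accession is not present in the graph."""


class OrphanTermError(ValueError):
    """Raised when a term is not connected to its namespace root by
    transitive edges and therefore has no well-defined level."""


@dataclass(frozen=True)
class Term:
    """A single GO term."""

    id: str
    name: str
    namespace: str  # one of CC / MF / BP
    obsolete: bool = False

    def __post_init__(self) -> None:
        if not GO_ID_PATTERN.match(self.id):
            raise OntologyValidationError(
                f"{self.id!r} does not match the GO accession pattern"
            )
        if self.namespace not in NAMESPACES:
            raise OntologyValidationError(
                f"{self.id}: namespace {self.namespace!r} is not one of {NAMESPACES}"
            )


@dataclass
class OntologyGraph:
    """Three-namespace GO DAG with typed edges and longest-path levels.

    ``edges`` holds (child, parent, relation) triples for *all* relation
    types; transitive traversal (parents, levels, ancestors) is restricted
    to is-a/part-of.  ``orphans`` are terms not connected to their
    namespace root by transitive edges: they keep a locally computed level
    but are never generalized.
    """

    terms: dict[str, Term]
    edges: set[tuple[str, str, str]]
    levels: dict[str, int] = field(default_factory=dict)
    roots: dict[str, str] = field(default_factory=dict)
    orphans: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self._parents: dict[str, frozenset[str]] = {t: frozenset() for t in self.terms}
        parent_sets: dict[str, set[str]] = {t: set() for t in self.terms}
        for child, parent, rel in self.edges:
            if rel in TRANSITIVE_RELATIONS:
                parent_sets[child].add(parent)
        self._parents = {t: frozenset(ps) for t, ps in parent_sets.items()}
        self._ancestors: dict[str, frozenset[str]] = {}
        self._validate()
        if not self.levels:
            self._compute_levels()

    # -- construction helpers ------------------------------------------------

    def _validate(self) -> None:
        for child, parent, rel in self.edges:
            if rel not in TRANSITIVE_RELATIONS:
                continue
            if child not in self.terms or parent not in self.terms:
                continue  # dangling references are dropped by parse_obo
            cns = self.terms[child].namespace
            pns = self.terms[parent].namespace
            if cns != pns:
                raise OntologyValidationError(
                    f"transitive edge {child} ({cns}) -> {parent} ({pns}) "
                    "crosses namespaces"
                )
        dag = nx.DiGraph(
            (c, p) for c, p, r in self.edges if r in TRANSITIVE_RELATIONS
        )
        if not nx.is_directed_acyclic_graph(dag):
            cycle = nx.find_cycle(dag)
            raise OntologyValidationError(f"cycle over transitive edges: {cycle}")

    def _compute_levels(self) -> None:
        # Longest path from a parentless term, computed in topological order
        # of the parent -> child orientation.
        down = nx.DiGraph()
        down.add_nodes_from(self.terms)
        for child, parent, rel in self.edges:
            if rel in TRANSITIVE_RELATIONS:
                down.add_edge(parent, child)
        levels: dict[str, int] = {}
        for node in nx.topological_sort(down):
            parents = self._parents[node]
            levels[node] = 1 + max((levels[p] for p in parents), default=0)
        self.levels = levels

        # Canonical namespace root: the parentless term with the most
        # transitive descendants (real GO has exactly one per namespace).
        by_ns_sources: dict[str, list[str]] = {ns: [] for ns in NAMESPACES}
        for t, term in self.terms.items():
            if not self._parents[t]:
                by_ns_sources[term.namespace].append(t)
        roots: dict[str, str] = {}
        for ns, sources in by_ns_sources.items():
            if not sources:
                continue
            n_desc = {s: len(nx.descendants(down, s)) for s in sources}
            roots[ns] = min(sources, key=lambda s: (-n_desc[s], s))
        self.roots = roots

        orphans = set()
        for t, term in self.terms.items():
            root = self.roots.get(term.namespace)
            if root is None or (t != root and root not in self._ancestor_set(t)):
                orphans.add(t)
        if orphans:
            logger.warning(
                "%d term(s) not connected to a namespace root via is_a/part_of; "
                "they will never be generalized", len(orphans)
            )
        self.orphans = frozenset(orphans)

    # -- queries -------------------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def namespace(self, term_id: str) -> str:
        try:
            return self.terms[term_id].namespace
        except KeyError:
            raise UnknownTermError(term_id) from None

    def find_parents(self, term_id: str) -> frozenset[str]:
        """Parents one is-a/part-of edge up; other relation types excluded."""
        try:
            return self._parents[term_id]
        except KeyError:
            raise UnknownTermError(term_id) from None

    def find_level(self, term_id: str) -> int:
        """1 + longest is-a/part-of path to the namespace root (root = 1)."""
        if term_id not in self.terms:
            raise UnknownTermError(term_id)
        if term_id in self.orphans:
            raise OrphanTermError(
                f"{term_id} is not connected to its namespace root via "
                "is_a/part_of; its level is undefined"
            )
        return self.levels[term_id]

    def level_or_fallback(self, term_id: str) -> int:
        """Level for connected terms; the locally computed fallback for
        orphans (used by the mining loop, which never generalizes them)."""
        if term_id not in self.terms:
            raise UnknownTermError(term_id)
        return self.levels[term_id]

    def _ancestor_set(self, term_id: str) -> frozenset[str]:
        cached = self._ancestors.get(term_id)
        if cached is not None:
            return cached
        # Iterative memoised DFS; the GO is deep enough that recursion is
        # best avoided.
        stack = [term_id]
        while stack:
            node = stack[-1]
            if node in self._ancestors:
                stack.pop()
                continue
            pending = [p for p in self._parents[node] if p not in self._ancestors]
            if pending:
                stack.extend(pending)
                continue
            anc: set[str] = set()
            for p in self._parents[node]:
                anc.add(p)
                anc |= self._ancestors[p]
            self._ancestors[node] = frozenset(anc)
            stack.pop()
        return self._ancestors[term_id]

    def is_ancestor(self, a: str, b: str) -> bool:
        """True iff ``a`` is a strict ancestor of ``b`` along transitive
        edges (irreflexive: ``is_ancestor(x, x)`` is False)."""
        if a not in self.terms:
            raise UnknownTermError(a)
        if b not in self.terms:
            raise UnknownTermError(b)
        return a in self._ancestor_set(b)

    def terms_at(self, level: int, namespace: str | None = None) -> list[str]:
        """All non-orphan term ids at a level, optionally per namespace."""
        return sorted(
            t
            for t, lv in self.levels.items()
            if lv == level
            and t not in self.orphans
            and (namespace is None or self.terms[t].namespace == namespace)
        )

    def leaves(self) -> list[str]:
        """Terms with no transitive children."""
        with_children = {p for _, p, r in self.edges if r in TRANSITIVE_RELATIONS}
        return sorted(t for t in self.terms if t not in with_children)


# ---------------------------------------------------------------------------
# OBO parsing
# ---------------------------------------------------------------------------


def _prevalidate(text: str) -> None:
    in_stanza = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("!", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            if not line.endswith("]"):
                raise OboParseError(f"line {lineno}: malformed stanza header {raw!r}")
            in_stanza = True
            continue
        if in_stanza and ":" not in line:
            raise OboParseError(f"line {lineno}: malformed tag line {raw!r}")


def parse_obo(source: str | TextIO) -> OntologyGraph:
    """Parse an OBO 1.2/1.4 document into an :class:`OntologyGraph`.

    Parameters
    ----------
    source
        Path to an .obo file, or a text stream containing OBO.

    Obsolete terms are dropped (with a logged count).  ``is_a`` tags and
    ``relationship: part_of`` tags become transitive edges; every other
    ``relationship`` type is recorded with its own relation label.
    ``intersection_of`` lines are ignored — they are logical definitions,
    not asserted edges.
    """
    if isinstance(source, str):
        with open(source, "rt", encoding="utf-8") as fh:
            text = fh.read()
    else:
        text = source.read()
    _prevalidate(text)
    try:
        graph = obonet.read_obo(io.StringIO(text), ignore_obsolete=False)
    except Exception as exc:  # pragma: no cover - obonet is lenient
        raise OboParseError(f"unreadable OBO document: {exc}") from exc

    terms: dict[str, Term] = {}
    n_obsolete = 0
    for node, data in graph.nodes(data=True):
        if not GO_ID_PATTERN.match(node):
            logger.warning("skipping non-GO identifier %r", node)
            continue
        if str(data.get("is_obsolete", "")).lower() == "true":
            n_obsolete += 1
            continue
        if not data:
            # Referenced as a parent but never defined by a [Term] stanza.
            logger.warning("term %s referenced but not defined; dropped", node)
            continue
        ns_raw = data.get("namespace")
        if ns_raw not in _NAMESPACE_CODES:
            raise OboParseError(f"term {node} has missing or unknown namespace {ns_raw!r}")
        terms[node] = Term(
            id=node, name=data.get("name", node), namespace=_NAMESPACE_CODES[ns_raw]
        )
    if n_obsolete:
        logger.info("dropped %d obsolete term(s)", n_obsolete)

    edges: set[tuple[str, str, str]] = set()
    for node, data in graph.nodes(data=True):
        if node not in terms:
            continue
        for parent in data.get("is_a", []):
            if parent in terms:
                edges.add((node, parent, "is_a"))
        for rel_line in data.get("relationship", []):
            parts = rel_line.split()
            if len(parts) < 2:
                raise OboParseError(f"term {node}: malformed relationship {rel_line!r}")
            rel, target = parts[0], parts[1]
            if target not in terms:
                continue
            if rel == "part_of":
                edges.add((node, target, "part_of"))
            else:
                edges.add((node, target, rel))

    return OntologyGraph(terms=terms, edges=edges)


# Module-level aliases matching the method surface --------------------------


def find_parents(g: OntologyGraph, term: str) -> frozenset[str]:
    return g.find_parents(term)


def find_level(g: OntologyGraph, term: str) -> int:
    return g.find_level(term)


def is_ancestor(g: OntologyGraph, a: str, b: str) -> bool:
    return g.is_ancestor(a, b)
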