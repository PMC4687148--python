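"""GO-style ontology DAGs and true-path annotation propagation.

An ontology is a directed acyclic graph of terms with child -> parent
``is_a`` (and optionally ``part_of``) edges, partitioned into namespaces
(biological_process, molecular_function, cellular_component).  The
true-path rule says that annotation of an object to a term implies
annotation to every ancestor of that term; propagated, ancestor-closed
annotation sets are the basis for enrichment counts and information
content.

OBO flat files are parsed with ``obonet``; obsolete terms are skipped.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import networkx as nx
import obonet

from .exceptions import UnknownTermError


@dataclass(frozen=True)
class Term:
    term_id: str
    name: str
    namespace: str


class OntologyGraph:
    """Terms plus child -> parent edges, with cached ancestor closure."""

    def __init__(
        self,
        terms: Iterable[Term],
        edges: Iterable[tuple[str, str]],
    ):
        self.terms: dict[str, Term] = {t.term_id: t for t in terms}
        self._parents: dict[str, set[str]] = {t: set() for t in self.terms}
        graph = nx.DiGraph()
        graph.add_nodes_from(self.terms)
        for child, parent in edges:
            if child not in self.terms or parent not in self.terms:
                raise UnknownTermError(f"edge ({child}, {parent}) references unknown term")
            if self.terms[child].namespace != self.terms[parent].namespace:
                raise UnknownTermError(
                    f"edge ({child}, {parent}) crosses namespaces"
                )
            self._parents[child].add(parent)
            graph.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(graph):
            raise ValueError("ontology graph contains a cycle")
        self._nx = graph
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def namespace(self, term_id: str) -> str:
        self._require(term_id)
        return self.terms[term_id].namespace

    def parents(self, term_id: str) -> frozenset[str]:
        self._require(term_id)
        return frozenset(self._parents[term_id])

    def ancestors(self, term_id: str, include_self: bool = False) -> frozenset[str]:
        """All terms reachable via parent edges (diamonds counted once)."""
        self._require(term_id)
        if term_id not in self._ancestor_cache:
            closure: set[str] = set()
            stack = list(self._parents[term_id])
            while stack:
                current = stack.pop()
                if current in closure:
                    continue
                closure.add(current)
                stack.extend(self._parents[current])
            self._ancestor_cache[term_id] = frozenset(closure)
        ancestors = self._ancestor_cache[term_id]
        return ancestors | {term_id} if include_self else ancestors

    def roots(self, namespace: Optional[str] = None) -> list[str]:
        """Terms with no parents, optionally restricted to a namespace."""
        return sorted(
            t for t, parents in self._parents.items()
            if not parents
            and (namespace is None or self.terms[t].namespace == namespace)
        )

    def namespaces(self) -> list[str]:
        return sorted({t.namespace for t in self.terms.values()})

    def terms_in_namespace(self, namespace: str) -> list[str]:
        return sorted(
            t for t, term in self.terms.items() if term.namespace == namespace
        )

    def _require(self, term_id: str) -> None:
        if term_id not in self.terms:
            raise UnknownTermError(f"unknown term {term_id!r}")

    @classmethod
    def from_obo(
        cls,
        path: Path | str,
        relationships: Iterable[str] = ("part_of",),
    ) -> "OntologyGraph":
        """Parse an OBO flat file (id, name, namespace, is_a, relationship).

        ``part_of`` edges are traversed like ``is_a`` by default; pass
        ``relationships=()`` to restrict propagation to ``is_a`` only.
        Obsolete terms are skipped by the parser.
        """
        allowed = {"is_a"} | set(relationships)
        graph = obonet.read_obo(path)
        terms = [
            Term(node, data.get("name", node), data.get("namespace", ""))
            for node, data in graph.nodes(data=True)
        ]
        edges = [
            (child, parent)
            for child, parent, key in graph.edges(keys=True)
            if key in allowed
        ]
        return cls(terms, edges)


@dataclass
class AnnotationCorpus:
    """Object -> term associations with true-path closure.

    ``direct`` holds the annotations as given; ``propagated`` the
    ancestor-closed sets; ``term_counts`` the number of annotated objects
    per term after propagation.
    """

    direct: dict[str, frozenset[str]]
    propagated: dict[str, frozenset[str]]
    term_counts: Counter = field(default_factory=Counter)

    def objects(self) -> list[str]:
        return sorted(self.direct)

    def objects_in_namespace(self, graph: OntologyGraph, namespace: str) -> list[str]:
        return sorted(
            obj for obj, terms in self.direct.items()
            if any(graph.namespace(t) == namespace for t in terms)
        )


def propagate(
    graph: OntologyGraph, direct_annotations: Mapping[str, Iterable[str]]
) -> AnnotationCorpus:
    """Apply the true-path rule to a direct annotation map.

    Each object's propagated set is the union of its direct terms and all
    their ancestors; a term reached through several paths (diamond) is
    counted once.  Annotation to a term absent from the graph is an error.
    """
    direct: dict[str, frozenset[str]] = {}
    propagated: dict[str, frozenset[str]] = {}
    counts: Counter = Counter()
    for obj, terms in direct_annotations.items():
        term_set = frozenset(terms)
        closed: set[str] = set()
        for term in term_set:
            closed |= graph.ancestors(term, include_self=True)
        direct[obj] = term_set
        propagated[obj] = frozenset(closed)
        counts.update(closed)
    return AnnotationCorpus(direct, propagated, counts)


def read_associations(path: Path | str) -> dict[str, set[str]]:
    """Read a 2-column association TSV (object, term) into a direct map."""
    from .table import read_table

    table = read_table(path)
    annotations: dict[str, set[str]] = {}
    for row in table.rows:
        annotations.setdefault(row[0], set()).add(row[1])
    return annotations


__all__ = [
    "Term",
    "OntologyGraph",
    "AnnotationCorpus",
    "propagate",
    "read_associations",
]
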