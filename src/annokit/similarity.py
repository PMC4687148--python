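"""Information-content semantic similarity between ontology terms and
functional similarity between annotated gene products.

The information content of a term t in an annotation corpus is

    IC(t) = -ln( count(t) / count(root) )

with counts taken after true-path propagation, per namespace; rarer terms
are more informative, the root carries none.  Term-pair similarity is
built on the most informative common ancestor (MICA):

    resnik(t1, t2) = IC(MICA)
    lin(t1, t2)    = 2 IC(MICA) / (IC(t1) + IC(t2))
    rel(t1, t2)    = lin * (1 - exp(-IC(MICA)))  =  lin * (1 - p(MICA))

Gene-level similarity combines the term-pair matrix over the two genes'
direct annotation sets, either by best-match average (BMA) or by the
maximum entry.  Direct sets feed the matrix while IC uses propagated
counts — the standard convention of this method family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .exceptions import CrossNamespaceError, UnannotatedObjectError, UnknownTermError
from .ontology import AnnotationCorpus, OntologyGraph

METHODS = ("resnik", "lin", "rel")
COMBINATIONS = ("bma", "max")


@dataclass
class ICTable:
    """Per-term information content for one namespace of a corpus."""

    namespace: str
    ic: dict[str, float]
    root_count: int

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.ic

    def __getitem__(self, term_id: str) -> float:
        try:
            return self.ic[term_id]
        except KeyError:
            raise UnknownTermError(
                f"term {term_id!r} has no IC (zero corpus count or wrong namespace)"
            ) from None


def build_ic(
    corpus: AnnotationCorpus, graph: OntologyGraph, namespace: str
) -> ICTable:
    """IC for every namespace term with a positive propagated count.

    The probability denominator is the root count — the number of corpus
    objects annotated anywhere in the namespace.
    """
    roots = graph.roots(namespace)
    root_count = max((corpus.term_counts.get(r, 0) for r in roots), default=0)
    if root_count == 0:
        raise UnannotatedObjectError(
            f"corpus has no annotated objects in namespace {namespace!r}"
        )
    ic = {}
    for term_id in graph.terms_in_namespace(namespace):
        count = corpus.term_counts.get(term_id, 0)
        if count >= 1:
            ic[term_id] = -math.log(count / root_count)
    return ICTable(namespace, ic, root_count)


def mica(
    t1: str, t2: str, ic: ICTable, graph: OntologyGraph
) -> tuple[Optional[str], float]:
    """Most informative common ancestor and its IC (0.0 if none has IC)."""
    if graph.namespace(t1) != graph.namespace(t2):
        raise CrossNamespaceError(f"{t1} and {t2} are in different namespaces")
    common = graph.ancestors(t1, include_self=True) & graph.ancestors(
        t2, include_self=True
    )
    best_term, best_ic = None, 0.0
    for term in sorted(common):  # sorted for deterministic tie-break
        if term in ic and ic[term] > best_ic:
            best_term, best_ic = term, ic[term]
        elif term in ic and best_term is None:
            best_term = term
    return best_term, best_ic


def term_similarity(
    t1: str, t2: str, ic: ICTable, graph: OntologyGraph, method: str = "lin"
) -> float:
    """Similarity of two same-namespace terms; symmetric in (t1, t2)."""
    if t1 not in ic or t2 not in ic:
        raise UnknownTermError(f"both terms need an IC value: {t1}, {t2}")
    _, ic_mica = mica(t1, t2, ic, graph)
    if method == "resnik":
        return ic_mica
    denom = ic[t1] + ic[t2]
    lin = (2.0 * ic_mica / denom) if denom > 0 else 0.0
    if method == "lin":
        return lin
    if method == "rel":
        return lin * (1.0 - math.exp(-ic_mica))
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def gene_similarity(
    obj_a: str,
    obj_b: str,
    corpus: AnnotationCorpus,
    ic: ICTable,
    graph: OntologyGraph,
    method: str = "lin",
    combination: str = "bma",
) -> float:
    """Functional similarity between two annotated objects.

    The term-pair similarity matrix S is computed over the direct
    annotation sets A x B (restricted to terms with IC in the table's
    namespace); ``bma`` averages the row-wise and column-wise best
    matches, ``max`` takes the best single pair.  An object with no
    usable terms raises :class:`UnannotatedObjectError`.
    """
    if combination not in COMBINATIONS:
        raise ValueError(f"unknown combination {combination!r}")
    terms_a = sorted(t for t in corpus.direct.get(obj_a, frozenset()) if t in ic)
    terms_b = sorted(t for t in corpus.direct.get(obj_b, frozenset()) if t in ic)
    if not terms_a or not terms_b:
        missing = obj_a if not terms_a else obj_b
        raise UnannotatedObjectError(
            f"object {missing!r} has no annotation with IC in namespace "
            f"{ic.namespace!r}"
        )
    matrix = [
        [term_similarity(ta, tb, ic, graph, method) for tb in terms_b]
        for ta in terms_a
    ]
    if combination == "max":
        return max(max(row) for row in matrix)
    row_best = [max(row) for row in matrix]
    col_best = [max(matrix[i][j] for i in range(len(terms_a)))
                for j in range(len(terms_b))]
    return 0.5 * (
        sum(row_best) / len(row_best) + sum(col_best) / len(col_best)
    )


__all__ = [
    "METHODS",
    "COMBINATIONS",
    "ICTable",
    "build_ic",
    "mica",
    "term_similarity",
    "gene_similarity",
]
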