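import pytest

from annokit.ontology import OntologyGraph, Term, propagate


@pytest.fixture
def diamond_graph():
    """Five-term DAG with a diamond: d -> c -> {a, b} -> root.

    Used by propagation and similarity tests; all terms share one
    namespace.
    """
    ns = "biological_process"
    terms = [
        Term("root", "root", ns),
        Term("a", "branch a", ns),
        Term("b", "branch b", ns),
        Term("c", "diamond child", ns),
        Term("d", "leaf", ns),
    ]
    edges = [
        ("a", "root"),
        ("b", "root"),
        ("c", "a"),
        ("c", "b"),
        ("d", "c"),
    ]
    return OntologyGraph(terms, edges)


@pytest.fixture
def diamond_corpus(diamond_graph):
    """Four objects annotated onto the diamond DAG (direct annotations)."""
    direct = {
        "g1": {"d"},
        "g2": {"c"},
        "g3": {"a"},
        "g4": {"b"},
    }
    return propagate(diamond_graph, direct)
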