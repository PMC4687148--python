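"""Ontology propagation and hypergeometric enrichment statistics."""

import random

import numpy as np
import pytest
from scipy.stats import fisher_exact

from annokit.enrichment import bh_adjust, hypergeom_pvalue, run_gse
from annokit.exceptions import EmptyStudyError, UnknownTermError
from annokit.ontology import OntologyGraph, Term, propagate


class TestPropagate:
    def test_true_path_closure(self, diamond_graph):
        corpus = propagate(diamond_graph, {"o": {"d"}})
        assert corpus.propagated["o"] == {"d", "c", "a", "b", "root"}

    def test_diamond_counted_once(self, diamond_graph):
        corpus = propagate(diamond_graph, {"o": {"c"}})
        assert corpus.term_counts["root"] == 1

    def test_root_count_equals_object_count(self, diamond_corpus):
        assert diamond_corpus.term_counts["root"] == 4

    def test_counts_monotone_rootward(self, diamond_graph, diamond_corpus):
        for term in diamond_graph.terms:
            for parent in diamond_graph.parents(term):
                assert (diamond_corpus.term_counts[parent]
                        >= diamond_corpus.term_counts[term])

    def test_unknown_term_rejected(self, diamond_graph):
        with pytest.raises(UnknownTermError):
            propagate(diamond_graph, {"o": {"nonexistent"}})

    def test_random_dag_counts_match_bruteforce(self):
        rng = random.Random(4)
        ns = "bp"
        n = 25
        terms = [Term(f"t{i}", f"t{i}", ns) for i in range(n)]
        edges = [
            (f"t{i}", f"t{rng.randrange(i)}")
            for i in range(1, n)
            for _ in range(rng.choice([1, 2]))
        ]
        edges = sorted(set(edges))
        graph = OntologyGraph(terms, edges)
        direct = {
            f"o{j}": {f"t{rng.randrange(n)}" for _ in range(rng.choice([1, 2, 3]))}
            for j in range(30)
        }
        corpus = propagate(graph, direct)

        def bf_ancestors(t):
            out = set()
            frontier = {t}
            while frontier:
                current = frontier.pop()
                for child, parent in edges:
                    if child == current and parent not in out:
                        out.add(parent)
                        frontier.add(parent)
            return out

        for term in graph.terms:
            expected = sum(
                1
                for terms_ in direct.values()
                if any(term == t or term in bf_ancestors(t) for t in terms_)
            )
            assert corpus.term_counts.get(term, 0) == expected


class TestHypergeomPvalue:
    def test_study_equals_background_forces_one(self):
        for mode in ("enrich", "deplete", "two_sided"):
            assert hypergeom_pvalue(5, 10, 5, 10, mode) == pytest.approx(1.0)

    def test_enrich_example(self):
        assert hypergeom_pvalue(4, 4, 5, 10, "enrich") == pytest.approx(
            5 / 210, abs=1e-12
        )

    def test_deplete_symmetry_example(self):
        assert hypergeom_pvalue(0, 4, 5, 10, "deplete") == pytest.approx(
            5 / 210, abs=1e-12
        )

    def test_tail_complement_identity(self):
        """P(X>=k) + P(X<=k) = 1 + P(X=k)."""
        from scipy.stats import hypergeom as hg

        for (k, n, K, N) in [(3, 8, 6, 20), (0, 5, 5, 12), (2, 4, 9, 11)]:
            up = hypergeom_pvalue(k, n, K, N, "enrich")
            down = hypergeom_pvalue(k, n, K, N, "deplete")
            point = hg.pmf(k, N, K, n)
            assert up + down == pytest.approx(1.0 + point, abs=1e-12)

    def test_two_sided_matches_fisher_exact(self):
        """Point-probability two-sided test equals the 2x2 Fisher exact
        p-value (independent scipy route)."""
        rng = random.Random(9)
        for _ in range(150):
            N = rng.randrange(2, 40)
            K = rng.randrange(0, N + 1)
            n = rng.randrange(0, N + 1)
            lo, hi = max(0, n + K - N), min(n, K)
            k = rng.randrange(lo, hi + 1)
            ours = hypergeom_pvalue(k, n, K, N, "two_sided")
            theirs = fisher_exact([[k, K - k], [n - k, N - K - n + k]])[1]
            assert ours == pytest.approx(theirs, abs=1e-9)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_pvalue(6, 5, 5, 10)
        with pytest.raises(ValueError):
            hypergeom_pvalue(0, 5, 11, 10)


def bh_reference(p):
    """Direct step-up definition: p_adj(i) = min_{j>=i} min(1, p(j) m / j)."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    best = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        best = min(best, p[i] * m / rank)
        adjusted[i] = best
    return adjusted


class TestBHAdjust:
    def test_worked_examples(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        assert bh_adjust([0.05, 0.5, 1.0]) == pytest.approx([0.15, 0.75, 1.0])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.321]) == pytest.approx([0.321])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_readjustment_never_shrinks(self):
        # BH is not idempotent in general (re-adjusting [0.5, 1.0] gives
        # [1.0, 1.0]); the correct one-sided law is that re-adjusting an
        # adjusted vector can only move values up.
        rng = np.random.default_rng(0)
        p = rng.uniform(size=20)
        once = bh_adjust(p)
        twice = bh_adjust(once)
        assert all(b >= a - 1e-15 for a, b in zip(once, twice))

    def test_permutation_equivariant(self):
        rng = np.random.default_rng(1)
        p = list(rng.uniform(size=15))
        adjusted = bh_adjust(p)
        perm = list(rng.permutation(15))
        assert bh_adjust([p[i] for i in perm]) == pytest.approx(
            [adjusted[i] for i in perm]
        )

    def test_matches_reference_on_random_vectors(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            p = list(rng.uniform(size=int(rng.integers(1, 60))))
            assert bh_adjust(p) == pytest.approx(bh_reference(p), abs=1e-12)


@pytest.fixture
def toy_gse(diamond_graph):
    """Three informative terms (a, b, c) over 8 objects."""
    direct = {
        "g1": {"c"}, "g2": {"c"}, "g3": {"a"}, "g4": {"a"},
        "g5": {"b"}, "g6": {"b"}, "g7": {"a"}, "g8": {"b"},
    }
    return propagate(diamond_graph, direct)


class TestRunGSE:
    def test_counts_match_hand_enumeration(self, diamond_graph, toy_gse):
        background = [f"g{i}" for i in range(1, 9)]
        study = ["g1", "g2", "g3"]
        outcome = run_gse(study, background, toy_gse, diamond_graph)
        by_term = {r.term_id: r for r in outcome.results}
        # propagated: c->{c,a,b,root}; a->{a,root}; b->{b,root}
        # K: a = 2(c-ann)+3(a-ann) = 5, b = 2+3 = 5, c = 2, root = 8
        # k over study {g1(c), g2(c), g3(a)}: a=3, b=2, c=2, root=3
        assert (by_term["a"].k, by_term["a"].K) == (3, 5)
        assert (by_term["b"].k, by_term["b"].K) == (2, 5)
        assert (by_term["c"].k, by_term["c"].K) == (2, 2)
        assert (by_term["root"].k, by_term["root"].K) == (3, 8)
        assert all(r.n == 3 and r.N == 8 for r in outcome.results)

    def test_extreme_enrichment_ranked_first(self, diamond_graph, toy_gse):
        background = [f"g{i}" for i in range(1, 9)]
        outcome = run_gse(["g1", "g2"], background, toy_gse, diamond_graph)
        assert outcome.results[0].term_id == "c"

    def test_unmappable_ids_reported_not_fatal(self, diamond_graph, toy_gse):
        background = [f"g{i}" for i in range(1, 9)] + ["ghost_bg"]
        outcome = run_gse(["g1", "ghost_bg"], background, toy_gse, diamond_graph)
        assert outcome.dropped_study == ["ghost_bg"]
        assert outcome.dropped_background == ["ghost_bg"]
        assert outcome.n == 1

    def test_study_equal_background_all_p_one(self, diamond_graph, toy_gse):
        background = [f"g{i}" for i in range(1, 9)]
        outcome = run_gse(background, background, toy_gse, diamond_graph)
        assert all(r.p_raw == pytest.approx(1.0) for r in outcome.results)

    def test_empty_study_is_error(self, diamond_graph, toy_gse):
        with pytest.raises(EmptyStudyError):
            run_gse(["ghost"], ["ghost"] + [f"g{i}" for i in range(1, 9)],
                    toy_gse, diamond_graph)

    def test_study_outside_background_rejected(self, diamond_graph, toy_gse):
        with pytest.raises(ValueError):
            run_gse(["g1"], ["g2", "g3"], toy_gse, diamond_graph)

    def test_p_adj_not_below_p_raw(self, diamond_graph, toy_gse):
        background = [f"g{i}" for i in range(1, 9)]
        outcome = run_gse(["g1", "g2", "g5"], background, toy_gse, diamond_graph)
        for r in outcome.results:
            assert r.p_adj >= r.p_raw - 1e-15
            assert 0.0 <= r.p_raw <= 1.0 and 0.0 <= r.p_adj <= 1.0
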