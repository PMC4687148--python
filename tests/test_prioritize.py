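"""Evidence scoring, rank aggregation and benchmark metric arithmetic."""

import random

import pytest

from annokit.exceptions import NoEvidenceError
from annokit.ontology import propagate
from annokit.prioritize import (
    EvidenceBundle,
    EvidenceProfile,
    RankedCandidate,
    aggregate,
    evaluate,
    prioritize,
    score_candidates,
)
from annokit.similarity import build_ic

NS = "biological_process"


def edges(*pairs):
    return {frozenset(p) for p in pairs}


class TestScoreCandidates:
    def test_ppi_counts_adjacent_training_genes(self):
        bundle = EvidenceBundle(
            interactions=edges(("c1", "t1"), ("c1", "t2"), ("c2", "t3"))
        )
        profiles = score_candidates(["c1", "c2", "c3"], ["t1", "t2", "t3"], bundle)
        by_gene = {p.gene: p for p in profiles}
        assert by_gene["c1"].ppi == 2
        assert by_gene["c2"].ppi == 1
        assert by_gene["c3"].ppi == 0

    def test_unannotated_candidate_flags_annotation_channels_off(
        self, diamond_graph
    ):
        direct = {"t1": {"c"}, "c1": {"d"}}
        corpus = propagate(diamond_graph, direct)
        ic = build_ic(corpus, diamond_graph, NS)
        bundle = EvidenceBundle(corpus=corpus, ic=ic, graph=diamond_graph)
        profiles = score_candidates(["c1", "c2"], ["t1"], bundle)
        by_gene = {p.gene: p for p in profiles}
        assert by_gene["c1"].available["funsim"] is True
        assert by_gene["c2"].available["funsim"] is False
        assert by_gene["c2"].available["go"] is False

    def test_training_genes_excluded_from_candidates(self):
        bundle = EvidenceBundle(interactions=edges(("c1", "t1")))
        profiles = score_candidates(["c1", "t1"], ["t1"], bundle)
        assert [p.gene for p in profiles] == ["c1"]

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError):
            score_candidates(["c1"], [], EvidenceBundle())

    def test_channels_match_bruteforce_on_random_bundle(self, diamond_graph):
        rng = random.Random(8)
        training = [f"t{i}" for i in range(4)]
        candidates = [f"c{i}" for i in range(10)]
        genes = training + candidates
        interactions = {
            frozenset(pair)
            for pair in (rng.sample(genes, 2) for _ in range(25))
        }
        complexes = {
            f"X{j}": frozenset(rng.sample(genes, rng.choice([2, 3, 4])))
            for j in range(5)
        }
        pathways = {
            f"P{j}": frozenset(rng.sample(genes, rng.choice([3, 5])))
            for j in range(4)
        }
        pool = ["a", "b", "c", "d"]
        direct = {g: set(rng.sample(pool, rng.choice([1, 2]))) for g in genes}
        corpus = propagate(diamond_graph, direct)
        ic = build_ic(corpus, diamond_graph, NS)
        bundle = EvidenceBundle(interactions, complexes, pathways,
                                corpus, ic, diamond_graph)
        profiles = score_candidates(candidates, training, bundle)
        for p in profiles:
            assert p.ppi == sum(
                1 for t in training if frozenset({p.gene, t}) in interactions
            )
            assert p.complex == len({
                t for members in complexes.values()
                if p.gene in members for t in training if t in members
            })
            assert p.pathway == len({
                t for members in pathways.values()
                if p.gene in members for t in training if t in members
            })
            def ns_terms(g):
                return corpus.propagated[g]
            expected_go = max(
                len(ns_terms(p.gene) & ns_terms(t)) / len(ns_terms(p.gene) | ns_terms(t))
                for t in training
            )
            assert p.go == pytest.approx(expected_go)
            assert 0.0 <= p.funsim <= 1.0


def profile(gene, **values):
    p = EvidenceProfile(gene=gene)
    for channel, value in values.items():
        setattr(p, channel, float(value))
        p.available[channel] = True
    return p


class TestAggregate:
    def test_single_channel_preserves_order(self):
        profiles = [profile(g, ppi=v) for g, v in
                    [("a", 5), ("b", 9), ("c", 1)]]
        ranked = aggregate(profiles, ["ppi"])
        assert [r.gene for r in ranked] == ["b", "a", "c"]
        assert [r.final_rank for r in ranked] == [1, 2, 3]

    def test_best_everywhere_is_rank_one(self):
        profiles = [
            profile("winner", ppi=9, go=0.9),
            profile("x", ppi=1, go=0.5),
            profile("y", ppi=2, go=0.1),
        ]
        ranked = aggregate(profiles, ["ppi", "go"])
        assert ranked[0].gene == "winner"

    def test_two_channel_arithmetic(self):
        """Ranks A(1,3), B(2,1), C(3,2) -> combined mean normalized ranks
        0.667 / 0.500 / 0.833 -> order B, A, C."""
        profiles = [
            profile("A", ppi=3, go=1),
            profile("B", ppi=2, go=3),
            profile("C", ppi=1, go=2),
        ]
        ranked = aggregate(profiles, ["ppi", "go"])
        by_gene = {r.gene: r for r in ranked}
        assert by_gene["A"].combined == pytest.approx(2 / 3, abs=1e-3)
        assert by_gene["B"].combined == pytest.approx(0.5, abs=1e-3)
        assert by_gene["C"].combined == pytest.approx(5 / 6, abs=1e-3)
        assert [r.gene for r in ranked] == ["B", "A", "C"]

    def test_unavailable_channel_imputed_neutral(self):
        p1 = profile("a", ppi=10)
        p2 = EvidenceProfile(gene="b")
        p2.available["ppi"] = False
        ranked = aggregate([p1, p2], ["ppi"])
        by_gene = {r.gene: r for r in ranked}
        assert by_gene["a"].normalized_ranks["ppi"] == pytest.approx(1.0)
        assert by_gene["b"].normalized_ranks["ppi"] == pytest.approx(0.5)

    def test_average_rank_ties_within_channel(self):
        profiles = [profile(g, ppi=v) for g, v in
                    [("a", 5), ("b", 5), ("c", 1)]]
        ranked = aggregate(profiles, ["ppi"])
        by_gene = {r.gene: r for r in ranked}
        assert by_gene["a"].normalized_ranks["ppi"] == pytest.approx(1.5 / 3)
        assert by_gene["b"].normalized_ranks["ppi"] == pytest.approx(1.5 / 3)

    def test_deterministic_gene_id_tie_break(self):
        profiles = [profile(g, ppi=1) for g in ("zeta", "alpha", "mid")]
        ranked = aggregate(profiles, ["ppi"])
        assert [r.gene for r in ranked] == ["alpha", "mid", "zeta"]

    def test_rank_ratio_in_percent(self):
        profiles = [profile(g, ppi=v) for g, v in
                    [("a", 3), ("b", 2), ("c", 1), ("d", 0)]]
        ranked = aggregate(profiles, ["ppi"])
        assert [r.rank_ratio for r in ranked] == [25.0, 50.0, 75.0, 100.0]

    def test_no_usable_evidence_rejected(self):
        p = EvidenceProfile(gene="a")
        with pytest.raises(NoEvidenceError):
            aggregate([p], ["ppi"])

    def test_score_monotonicity(self):
        """Raising one channel's raw score never worsens the final rank."""
        rng = random.Random(12)
        for _ in range(20):
            profiles = [
                profile(f"g{i}", ppi=rng.randrange(10), go=rng.random())
                for i in range(8)
            ]
            ranked = {r.gene: r.final_rank
                      for r in aggregate(profiles, ["ppi", "go"])}
            target = rng.choice(profiles)
            target.ppi += rng.randrange(1, 5)
            improved = {r.gene: r.final_rank
                        for r in aggregate(profiles, ["ppi", "go"])}
            assert improved[target.gene] <= ranked[target.gene]


def fake_ranking(ratios):
    n = len(ratios)
    return [
        RankedCandidate(gene=f"g{i}", combined=r / 100, final_rank=i + 1,
                        rank_ratio=r)
        for i, r in enumerate(ratios)
    ]


class TestEvaluate:
    def test_response_rate(self):
        cases = [("g0", fake_ranking([10.0]))] * 3 + [("gX", None)]
        assert evaluate(cases).response_rate == pytest.approx(0.75)

    def test_tpr_threshold_counting(self):
        cases = [
            ("g0", fake_ranking([ratio, 50.0]))
            for ratio in (1.0, 4.9, 5.1, 60.0)
        ]
        summary = evaluate(cases)
        assert summary.tpr5 == pytest.approx(0.5)
        assert summary.tpr10 == pytest.approx(0.75)
        assert summary.tpr30 == pytest.approx(0.75)

    def test_median_rank_ratio(self):
        cases = [("g0", fake_ranking([r])) for r in (10.0, 20.0, 80.0)]
        assert evaluate(cases).median_rank_ratio == pytest.approx(20.0)

    def test_tpr_ordering_law(self):
        rng = random.Random(17)
        cases = [("g0", fake_ranking([rng.uniform(0, 100)])) for _ in range(30)]
        s = evaluate(cases)
        assert s.tpr5 <= s.tpr10 <= s.tpr30

    def test_zero_cases_rejected(self):
        with pytest.raises(ValueError):
            evaluate([])


class TestPrioritizeEndToEnd:
    def test_planted_signal_wins(self, diamond_graph):
        training = ["t1", "t2"]
        bundle = EvidenceBundle(
            interactions=edges(("hit", "t1"), ("hit", "t2"), ("noise", "t1")),
            complexes={"X": frozenset({"hit", "t1", "t2"})},
        )
        ranked = prioritize(["hit", "noise", "cold"], training, bundle,
                            ["ppi", "complex"])
        assert ranked[0].gene == "hit"
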