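"""Rank-based candidate gene prioritization and benchmark evaluation.

Given a set of training genes already associated with a phenotype and a
set of candidate genes, each candidate is scored on up to five evidence
channels:

    ppi       number of training genes adjacent by a direct interaction
    complex   number of training genes sharing >= 1 protein complex
    pathway   number of training genes sharing >= 1 pathway
    go        best Jaccard overlap of propagated GO term sets vs training
    funsim    best functional (lin/BMA) similarity to any training gene

Within each channel candidates are ranked descending with average-rank
ties and the rank is normalized by the number of ranked candidates; a
candidate for which a channel is undefined receives the neutral value
0.5.  The combined score is the mean of normalized ranks over enabled
channels, and the final ranking is ascending in that score with a
lexicographic gene-id tie-break for determinism.  This is a rank-
aggregation rule in the MetaRanker family, documented as inspired-by,
not identical-to, any published tool.

The benchmark evaluator reports the standard comparison metrics: response
rate, true-positive rate of the hidden disease gene in the top 5/10/30 %
of candidates, and the median rank ratio (in percent).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .exceptions import NoEvidenceError, UnannotatedObjectError
from .ontology import AnnotationCorpus, OntologyGraph
from .similarity import ICTable, gene_similarity

CHANNELS = ("ppi", "complex", "pathway", "go", "funsim")


@dataclass
class EvidenceBundle:
    """Evidence sources shared by all candidates of one prioritization run."""

    interactions: set[frozenset[str]] = field(default_factory=set)
    complexes: dict[str, frozenset[str]] = field(default_factory=dict)
    pathways: dict[str, frozenset[str]] = field(default_factory=dict)
    corpus: Optional[AnnotationCorpus] = None
    ic: Optional[ICTable] = None
    graph: Optional[OntologyGraph] = None

    def neighbors(self, gene: str) -> set[str]:
        out: set[str] = set()
        for edge in self.interactions:
            if gene in edge:
                out |= edge - {gene}
        return out


@dataclass
class EvidenceProfile:
    gene: str
    ppi: float = 0.0
    complex: float = 0.0
    pathway: float = 0.0
    go: float = 0.0
    funsim: float = 0.0
    available: dict[str, bool] = field(default_factory=dict)

    def value(self, channel: str) -> float:
        return getattr(self, channel)


@dataclass
class RankedCandidate:
    gene: str
    combined: float
    final_rank: int
    rank_ratio: float  # 100 * final_rank / candidate count, in percent
    normalized_ranks: dict[str, float] = field(default_factory=dict)


@dataclass
class BenchmarkSummary:
    response_rate: float  # fraction of cases producing a ranking
    tpr5: float
    tpr10: float
    tpr30: float
    median_rank_ratio: float  # percent


def _jaccard(a: frozenset, b: frozenset) -> float:
    union = a | b
    return len(a & b) / len(union) if union else 0.0


def score_candidates(
    candidates: Sequence[str],
    training_genes: Sequence[str],
    bundle: EvidenceBundle,
) -> list[EvidenceProfile]:
    """Per-candidate evidence profile against the training set.

    Training genes are excluded from the candidate list (the benchmark
    protocol hides the disease gene from training).  Count channels are
    available whenever the bundle carries that evidence type; annotation
    channels are unavailable per-candidate when the candidate (or every
    training gene) lacks usable annotation.
    """
    training = [t for t in dict.fromkeys(training_genes)]
    if not training:
        raise ValueError("training set must be non-empty")
    candidates = [c for c in dict.fromkeys(candidates) if c not in set(training)]

    has_annotation = (
        bundle.corpus is not None and bundle.ic is not None and bundle.graph is not None
    )
    # Propagated sets restricted to the IC namespace for the overlap channel.
    def ns_terms(gene: str) -> frozenset[str]:
        assert bundle.corpus is not None and bundle.ic is not None
        return frozenset(
            t for t in bundle.corpus.propagated.get(gene, frozenset())
            if bundle.graph.namespace(t) == bundle.ic.namespace
        )

    profiles = []
    for gene in candidates:
        profile = EvidenceProfile(gene=gene)
        neighbors = bundle.neighbors(gene)
        profile.ppi = float(sum(1 for t in training if t in neighbors))
        profile.available["ppi"] = bool(bundle.interactions)
        shared_complex = {
            t
            for members in bundle.complexes.values()
            if gene in members
            for t in training
            if t in members
        }
        profile.complex = float(len(shared_complex))
        profile.available["complex"] = bool(bundle.complexes)
        shared_pathway = {
            t
            for members in bundle.pathways.values()
            if gene in members
            for t in training
            if t in members
        }
        profile.pathway = float(len(shared_pathway))
        profile.available["pathway"] = bool(bundle.pathways)

        profile.available["go"] = False
        profile.available["funsim"] = False
        if has_annotation:
            gene_terms = ns_terms(gene)
            if gene_terms:
                overlaps = [
                    _jaccard(gene_terms, ns_terms(t))
                    for t in training
                    if ns_terms(t)
                ]
                if overlaps:
                    profile.go = max(overlaps)
                    profile.available["go"] = True
            sims = []
            for t in training:
                try:
                    sims.append(
                        gene_similarity(
                            gene, t, bundle.corpus, bundle.ic, bundle.graph,
                            method="lin", combination="bma",
                        )
                    )
                except UnannotatedObjectError:
                    continue
            if sims:
                profile.funsim = max(sims)
                profile.available["funsim"] = True
        profiles.append(profile)
    return profiles


def aggregate(
    profiles: Sequence[EvidenceProfile],
    channels: Sequence[str] = CHANNELS,
) -> list[RankedCandidate]:
    """Combine channel scores into a final ranking.

    Per channel: candidates with an available value are ranked descending
    by raw score with average-rank ties, normalized by the count of
    ranked candidates; unavailable values are imputed with the neutral
    0.5.  Combined score = mean of normalized ranks over enabled
    channels; final order ascending by (combined, gene id); final ranks
    are the distinct integers 1..n.
    """
    channels = list(channels)
    unknown = set(channels) - set(CHANNELS)
    if unknown:
        raise ValueError(f"unknown channels: {sorted(unknown)}")
    if not profiles:
        raise NoEvidenceError("no candidates to rank")
    usable = [
        ch for ch in channels if any(p.available.get(ch, False) for p in profiles)
    ]
    if not usable:
        raise NoEvidenceError("no evidence channel has any available value")

    n = len(profiles)
    normalized: dict[str, np.ndarray] = {}
    for ch in channels:
        norm = np.full(n, 0.5)
        idx = [i for i, p in enumerate(profiles) if p.available.get(ch, False)]
        if idx:
            raw = np.array([profiles[i].value(ch) for i in idx])
            ranks = rankdata(-raw, method="average")
            norm[idx] = ranks / len(idx)
        normalized[ch] = norm

    combined = np.mean([normalized[ch] for ch in channels], axis=0)
    order = sorted(range(n), key=lambda i: (combined[i], profiles[i].gene))
    ranked = []
    for rank, i in enumerate(order, start=1):
        ranked.append(
            RankedCandidate(
                gene=profiles[i].gene,
                combined=float(combined[i]),
                final_rank=rank,
                rank_ratio=100.0 * rank / n,
                normalized_ranks={ch: float(normalized[ch][i]) for ch in channels},
            )
        )
    return ranked


def prioritize(
    candidates: Sequence[str],
    training_genes: Sequence[str],
    bundle: EvidenceBundle,
    channels: Sequence[str] = CHANNELS,
) -> list[RankedCandidate]:
    """score_candidates followed by aggregate."""
    return aggregate(score_candidates(candidates, training_genes, bundle), channels)


def evaluate(
    case_results: Sequence[tuple[str, Optional[Sequence[RankedCandidate]]]],
) -> BenchmarkSummary:
    """Benchmark metrics over (disease_gene, ranking | None) cases.

    A case with no ranking (None) counts against the response rate only;
    TPRs and the median are computed over responding cases.
    """
    if not case_results:
        raise ValueError("no benchmark cases")
    ratios = []
    for disease_gene, ranking in case_results:
        if ranking is None:
            continue
        by_gene = {r.gene: r for r in ranking}
        if disease_gene not in by_gene:
            raise ValueError(
                f"disease gene {disease_gene!r} missing from a responding ranking"
            )
        ratios.append(by_gene[disease_gene].rank_ratio)
    responding = len(ratios)
    total = len(case_results)
    if responding == 0:
        return BenchmarkSummary(0.0, 0.0, 0.0, 0.0, float("nan"))
    return BenchmarkSummary(
        response_rate=responding / total,
        tpr5=sum(r <= 5.0 for r in ratios) / responding,
        tpr10=sum(r <= 10.0 for r in ratios) / responding,
        tpr30=sum(r <= 30.0 for r in ratios) / responding,
        median_rank_ratio=float(statistics.median(ratios)),
    )


__all__ = [
    "CHANNELS",
    "EvidenceBundle",
    "EvidenceProfile",
    "RankedCandidate",
    "BenchmarkSummary",
    "score_candidates",
    "aggregate",
    "prioritize",
    "evaluate",
]
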