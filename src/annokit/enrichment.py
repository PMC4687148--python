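"""Gene set enrichment on GO terms: exact hypergeometric tests with
Benjamini-Hochberg correction.

For a study set of n objects drawn from a background of N, and a term
annotated (after true-path propagation) to K background objects of which
k fall in the study set, the null distribution of k is
Hypergeometric(N, K, n).  Over-representation is P(X >= k),
under-representation P(X <= k), and the two-sided test uses the
point-probability (minimum-likelihood) method: the sum of P(X = i) over
all i whose point probability does not exceed P(X = k) — the convention
of standard exact-test implementations.

Only terms with K >= 1 in the background are testable; that count is the
m entering the BH correction, per namespace.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .exceptions import EmptyStudyError
from .ontology import AnnotationCorpus, OntologyGraph

MODES = ("enrich", "deplete", "two_sided")

# Relative slack when comparing point probabilities in the two-sided test;
# guards against float noise splitting exact pmf ties.
_REL_TIE_TOL = 1e-7


def hypergeom_pvalue(k: int, n: int, K: int, N: int, mode: str = "enrich") -> float:
    """Exact tail probability for k study hits under Hypergeometric(N, K, n)."""
    _check_counts(k, n, K, N)
    if mode == "enrich":
        return float(min(1.0, hypergeom.sf(k - 1, N, K, n)))
    if mode == "deplete":
        return float(min(1.0, hypergeom.cdf(k, N, K, n)))
    if mode == "two_sided":
        lo = max(0, n + K - N)
        hi = min(n, K)
        support = np.arange(lo, hi + 1)
        pmf = hypergeom.pmf(support, N, K, n)
        p_k = float(hypergeom.pmf(k, N, K, n))
        total = float(pmf[pmf <= p_k * (1.0 + _REL_TIE_TOL)].sum())
        return min(1.0, total)
    raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")


def _check_counts(k: int, n: int, K: int, N: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: n={n}, K={K}, N={N}")
    if not (max(0, n + K - N) <= k <= min(n, K)):
        raise ValueError(
            f"k={k} outside support [{max(0, n + K - N)}, {min(n, K)}] "
            f"for n={n}, K={K}, N={N}"
        )


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    Equivalent to the direct definition: sort ascending and take
    p_adj(i) = min_{j >= i} min(1, p(j) * m / j).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in adjusted]


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    name: str
    k: int
    n: int
    K: int
    N: int
    p_raw: float
    p_adj: float
    mode: str
    significant: bool


@dataclass
class GSEOutcome:
    """Per-term results plus the mapping report of dropped identifiers."""

    results: list[EnrichmentResult]
    n: int
    N: int
    dropped_study: list[str]
    dropped_background: list[str]

    def significant(self) -> list[EnrichmentResult]:
        return [r for r in self.results if r.significant]


def term_membership_matrix(
    corpus: AnnotationCorpus,
    graph: OntologyGraph,
    background: Sequence[str],
    namespace: Optional[str] = None,
) -> tuple[np.ndarray, list[str]]:
    """Boolean (object x term) matrix of propagated annotation over the
    background, restricted to terms with at least one annotated object."""
    term_ids = sorted(
        {
            t
            for obj in background
            for t in corpus.propagated.get(obj, frozenset())
            if namespace is None or graph.namespace(t) == namespace
        }
    )
    col = {t: j for j, t in enumerate(term_ids)}
    matrix = np.zeros((len(background), len(term_ids)), dtype=bool)
    for i, obj in enumerate(background):
        for t in corpus.propagated.get(obj, frozenset()):
            j = col.get(t)
            if j is not None:
                matrix[i, j] = True
    return matrix, term_ids


def run_gse(
    study_ids: Iterable[str],
    background_ids: Iterable[str],
    corpus: AnnotationCorpus,
    graph: OntologyGraph,
    mode: str = "enrich",
    alpha: float = 0.05,
    namespace: Optional[str] = None,
) -> GSEOutcome:
    """Term enrichment of a study set against a background.

    Identifiers absent from the corpus are dropped from both sets and
    reported in the outcome (symbol loss across data versions is expected
    and must be surfaced, never silently discarded).  One test per term
    with K >= 1 in the background; results sorted by (p_adj, term_id) with
    p_adj <= alpha flagged significant.
    """
    study = list(dict.fromkeys(study_ids))
    background = list(dict.fromkeys(background_ids))
    missing_from_background = set(study) - set(background)
    if missing_from_background:
        raise ValueError(
            f"study ids not in background: {sorted(missing_from_background)[:5]} ..."
        )
    dropped_study = [s for s in study if s not in corpus.propagated]
    dropped_background = [b for b in background if b not in corpus.propagated]
    study = [s for s in study if s in corpus.propagated]
    background = [b for b in background if b in corpus.propagated]
    if not study:
        raise EmptyStudyError("study set empty after corpus intersection")

    matrix, term_ids = term_membership_matrix(corpus, graph, background, namespace)
    n, N = len(study), len(background)
    study_rows = np.array([background.index(s) for s in study])
    K_vec = matrix.sum(axis=0).astype(int)
    k_vec = matrix[study_rows].sum(axis=0).astype(int)

    p_raw = np.array(
        [
            hypergeom_pvalue(int(k), n, int(K), N, mode)
            for k, K in zip(k_vec, K_vec)
        ]
    )
    p_adj = np.array(bh_adjust(p_raw)) if len(p_raw) else np.array([])

    results = [
        EnrichmentResult(
            term_id=t,
            name=graph.terms[t].name if t in graph.terms else t,
            k=int(k),
            n=n,
            K=int(K),
            N=N,
            p_raw=float(pr),
            p_adj=float(pa),
            mode=mode,
            significant=bool(pa <= alpha),
        )
        for t, k, K, pr, pa in zip(term_ids, k_vec, K_vec, p_raw, p_adj)
    ]
    results.sort(key=lambda r: (r.p_adj, r.term_id))
    return GSEOutcome(results, n, N, dropped_study, dropped_background)


def null_rejection_rate(
    corpus: AnnotationCorpus,
    graph: OntologyGraph,
    background: Sequence[str],
    study_size: int,
    replicates: int,
    alpha: float = 0.05,
    mode: str = "enrich",
    namespace: Optional[str] = None,
    seed: int = 0,
) -> float:
    """Fraction of term tests with p_raw <= alpha when the study set is a
    uniform subsample of the background (type-I error measurement).

    Vectorized over replicates: the membership matrix is built once and
    each replicate only recounts study hits and recomputes tail
    probabilities.
    """
    rng = np.random.default_rng(seed)
    background = [b for b in background if b in corpus.propagated]
    matrix, _ = term_membership_matrix(corpus, graph, background, namespace)
    N = len(background)
    K_vec = matrix.sum(axis=0).astype(int)
    keep = K_vec >= 1
    matrix = matrix[:, keep]
    K_vec = K_vec[keep]
    rejections = 0
    tests = 0
    for _ in range(replicates):
        rows = rng.choice(N, size=study_size, replace=False)
        k_vec = matrix[rows].sum(axis=0).astype(int)
        if mode == "enrich":
            p = hypergeom.sf(k_vec - 1, N, K_vec, study_size)
        elif mode == "deplete":
            p = hypergeom.cdf(k_vec, N, K_vec, study_size)
        else:
            p = np.array(
                [
                    hypergeom_pvalue(int(k), study_size, int(K), N, "two_sided")
                    for k, K in zip(k_vec, K_vec)
                ]
            )
        rejections += int((p <= alpha).sum())
        tests += len(K_vec)
    return rejections / tests


__all__ = [
    "MODES",
    "hypergeom_pvalue",
    "bh_adjust",
    "EnrichmentResult",
    "GSEOutcome",
    "term_membership_matrix",
    "run_gse",
    "null_rejection_rate",
]
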