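"""Deterministic synthetic data generators for every input file type.

Real deployments of the toolkit read version-locked snapshots of external
resources (ontology releases, identifier mappings, ortholog tables,
interaction and pathway databases, haplotype-block maps).  This module
generates structurally equivalent synthetic versions of each file type as
pure functions of a :class:`FixtureSpec`, so every consuming module is
buildable and testable without downloads, and so tests can check row
counts and rankings against the generator's own recorded ground truth.

Each generator draws from its own pseudo-random stream keyed by
(seed, generator name), so adding a generator never perturbs the output
of the others; identical specs yield byte-identical files.

The generated data is shaped like the real thing but makes no claim to
statistical realism of GO topology, interactome degree distributions or
human LD structure.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .ontology import OntologyGraph, Term, propagate
from .prioritize import EvidenceBundle
from .registry import Registry
from .similarity import build_ic
from .table import AnnotationTable, write_table


@dataclass(frozen=True)
class FixtureSpec:
    """Sizes, rates and signal strength for all generators.

    ``theta`` is the probability that the planted disease gene of a
    benchmark case receives each unit of training-linked evidence;
    background candidates receive it with probability ``baseline``.
    At theta == baseline the planted gene is exchangeable with the
    background (the null).  ``annotation_rate`` is the Poisson mean of
    direct terms per gene (clipped to >= 1).
    """

    seed: int = 0
    n_terms: int = 50
    n_genes: int = 200
    edge_density: float = 0.05
    n_complexes: int = 20
    n_pathways: int = 20
    n_blocks: int = 26
    n_cases: int = 42
    n_candidates: int = 50
    n_training: int = 5
    theta: float = 0.8
    baseline: float = 0.1
    annotation_rate: float = 3.0
    namespace: str = "biological_process"


def _rng(spec: FixtureSpec, name: str, *extra: int) -> np.random.Generator:
    """Stream keyed by (seed, generator name[, indices])."""
    return np.random.default_rng(
        [spec.seed, zlib.crc32(name.encode("ascii")), *extra]
    )


def _term_id(i: int) -> str:
    return f"T:{i:07d}"


# ---------------------------------------------------------------------------
# ontology / corpus / networks


def gen_ontology(
    spec: FixtureSpec, out_path: Optional[Path | str] = None
) -> OntologyGraph:
    """Rooted random DAG: term 0 is the namespace root, each later term
    gets 1-2 parents drawn from earlier terms (acyclic by construction)."""
    if spec.n_terms < 3:
        raise ValueError("need at least 3 terms")
    rng = _rng(spec, "ontology")
    terms = [Term(_term_id(0), "synthetic root", spec.namespace)]
    edges: list[tuple[str, str]] = []
    for i in range(1, spec.n_terms):
        terms.append(Term(_term_id(i), f"synthetic term {i}", spec.namespace))
        n_parents = 1 if i == 1 else int(rng.integers(1, 3))
        parents = rng.choice(i, size=min(n_parents, i), replace=False)
        for p in sorted(int(x) for x in parents):
            edges.append((_term_id(i), _term_id(p)))
    if out_path is not None:
        lines = ["format-version: 1.2", "ontology: synthetic", ""]
        parent_map: dict[str, list[str]] = {}
        for child, parent in edges:
            parent_map.setdefault(child, []).append(parent)
        for term in terms:
            lines += [
                "[Term]",
                f"id: {term.term_id}",
                f"name: {term.name}",
                f"namespace: {term.namespace}",
            ]
            lines += [f"is_a: {p}" for p in parent_map.get(term.term_id, [])]
            lines.append("")
        Path(out_path).write_text("\n".join(lines), encoding="utf-8")
    return OntologyGraph(terms, edges)


def gene_ids(spec: FixtureSpec) -> list[str]:
    return [f"G{i:04d}" for i in range(spec.n_genes)]


def gen_corpus(
    spec: FixtureSpec,
    graph: OntologyGraph,
    out_path: Optional[Path | str] = None,
) -> dict[str, set[str]]:
    """Direct annotations: each gene draws max(1, Poisson(rate)) distinct
    non-root terms uniformly.  Returns the direct map; optionally writes
    the 2-column association TSV."""
    rng = _rng(spec, "corpus")
    non_root = [t for t in sorted(graph.terms) if graph.parents(t)]
    direct: dict[str, set[str]] = {}
    for gene in gene_ids(spec):
        k = max(1, int(rng.poisson(spec.annotation_rate)))
        k = min(k, len(non_root))
        picks = rng.choice(len(non_root), size=k, replace=False)
        direct[gene] = {non_root[int(i)] for i in picks}
    if out_path is not None:
        rows = [
            (gene, term)
            for gene in sorted(direct)
            for term in sorted(direct[gene])
        ]
        write_table(AnnotationTable(["object", "term"], rows), out_path)
    return direct


@dataclass
class Networks:
    interactions: set[frozenset[str]]
    complexes: dict[str, frozenset[str]]
    pathways: dict[str, frozenset[str]]


def gen_networks(
    spec: FixtureSpec, out_dir: Optional[Path | str] = None
) -> Networks:
    """Interaction edges at the stated density (no self-edges, no
    duplicates) plus complexes and pathways as random gene sets."""
    if spec.n_genes < 2:
        raise ValueError("need at least 2 genes")
    rng = _rng(spec, "networks")
    genes = gene_ids(spec)
    interactions: set[frozenset[str]] = set()
    for i in range(len(genes)):
        draws = rng.random(len(genes) - i - 1)
        for off, u in enumerate(draws):
            if u < spec.edge_density:
                interactions.add(frozenset({genes[i], genes[i + 1 + off]}))
    complexes = {}
    for c in range(spec.n_complexes):
        size = int(rng.integers(3, 9))
        members = rng.choice(len(genes), size=size, replace=False)
        complexes[f"CPX{c:04d}"] = frozenset(genes[int(i)] for i in members)
    pathways = {}
    for p in range(spec.n_pathways):
        size = int(rng.integers(5, 16))
        members = rng.choice(len(genes), size=size, replace=False)
        pathways[f"PWY{p:04d}"] = frozenset(genes[int(i)] for i in members)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        edge_rows = sorted(tuple(sorted(e)) for e in interactions)
        write_table(
            AnnotationTable(["gene_a", "gene_b"], edge_rows),
            out_dir / "interactions.tsv",
        )
        for fname, groups in (
            ("complexes.tsv", complexes),
            ("pathways.tsv", pathways),
        ):
            rows = [
                (name, gene)
                for name in sorted(groups)
                for gene in sorted(groups[name])
            ]
            write_table(AnnotationTable(["set_id", "gene"], rows), out_dir / fname)
    return Networks(interactions, complexes, pathways)


# ---------------------------------------------------------------------------
# genome fixture: loci -> blocks -> genes -> orthologs -> secondary ids


@dataclass
class GenomeFixture:
    """Files plus ground truth for the GWAS-to-ortholog pipeline shape."""

    registry: Registry
    loci_path: Path
    #: release id -> exact expected output row count of the full pipeline
    expected_rows: dict[str, int]
    #: organism-b genes whose secondary-id mapping differs between releases
    changed_fly_genes: set[str]
    paths: dict[str, Path] = field(default_factory=dict)


def gen_genome_fixture(spec: FixtureSpec, out_dir: Path | str) -> GenomeFixture:
    """Blocks, genes, loci and the mapping chain, registered in a two-
    release registry.

    Layout: non-overlapping haplotype blocks on one chromosome, each
    containing 1-3 genes and one tag SNP.  Loci are given in old-assembly
    coordinates (recoverable through an offset liftover map).  Mapping
    multiplicities (orthologs per gene, secondary ids per ortholog) are
    drawn from {1, 2, 3} and recorded, so the exact expected row count of
    the chained pipeline is Sigma over loci of Pi of multiplicities.
    Release 2 pins a later version of the secondary-id mapping in which a
    recorded subset of ortholog genes maps to different identifiers.
    """
    if spec.n_blocks < 1:
        raise ValueError("need at least 1 block")
    rng = _rng(spec, "genome")
    out_dir = Path(out_dir)
    data_dir = out_dir / "src"
    data_dir.mkdir(parents=True, exist_ok=True)

    blocks: list[tuple[str, int, int, str]] = []
    genes: list[tuple[str, str, int, int, str, str]] = []
    loci: list[str] = []
    snp_coords: list[tuple[str, str, int]] = []
    gene_block: dict[str, str] = {}
    genes_per_block: dict[str, list[str]] = {}

    chrom, old_chrom = "1", "chr1"
    offset = 1000  # new = old + offset, one interval spanning the chromosome
    cursor = 10_000
    gene_no = 0
    for b in range(spec.n_blocks):
        block_id = f"BLK{b:04d}"
        n_in_block = int(rng.integers(1, 4))
        start = cursor
        pos = start
        members = []
        for _ in range(n_in_block):
            gid = f"ENSG{gene_no:011d}"
            gene_no += 1
            g_start, g_end = pos, pos + 999
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append((gid, chrom, g_start, g_end, strand, "gene"))
            gene_block[gid] = block_id
            members.append(gid)
            pos = g_end + 501
        end = pos - 501
        blocks.append((chrom, start, end, block_id))
        genes_per_block[block_id] = members
        snp_id = f"rs{b + 1:06d}"
        loci.append(snp_id)
        snp_pos_new = int(rng.integers(start, end + 1))
        snp_coords.append((snp_id, old_chrom, snp_pos_new - offset))
        cursor = end + 2000

    write_table(AnnotationTable(["snp_id"], [(s,) for s in loci]),
                data_dir / "loci.tsv")
    write_table(
        AnnotationTable(
            ["snp_id", "old_chrom", "old_pos"],
            [(s, c, str(p)) for s, c, p in snp_coords],
        ),
        data_dir / "snp_coords.tsv",
    )
    write_table(
        AnnotationTable(
            ["chrom", "start", "end", "target_chrom", "offset"],
            [(old_chrom, "1", str(cursor), chrom, str(offset))],
        ),
        data_dir / "offset_map.tsv",
    )
    write_table(
        AnnotationTable(
            ["chrom", "start", "end", "block_id"],
            [(c, str(s), str(e), i) for c, s, e, i in blocks],
        ),
        data_dir / "blocks.tsv",
    )
    write_table(
        AnnotationTable(
            ["feature_id", "chrom", "start", "end", "strand", "kind"],
            [(g, c, str(s), str(e), st, k) for g, c, s, e, st, k in genes],
        ),
        data_dir / "genes.tsv",
    )

    human_genes = [g[0] for g in genes]
    write_table(
        AnnotationTable(
            ["gene_id", "symbol"],
            [(g, f"SYM{i:04d}") for i, g in enumerate(human_genes)],
        ),
        data_dir / "gene2symbol.tsv",
    )

    orth_mult: dict[str, int] = {}
    orth_rows: list[tuple[str, str, str]] = []
    fly_genes: list[str] = []
    fly_no = 0
    for g in human_genes:
        m = int(rng.integers(1, 4))
        orth_mult[g] = m
        cls = "one2one" if m == 1 else "one2many"
        for _ in range(m):
            fb = f"FBgn{fly_no:07d}"
            fly_no += 1
            fly_genes.append(fb)
            orth_rows.append((g, fb, cls))
    write_table(
        AnnotationTable(["human_gene", "fly_gene", "homology_class"], orth_rows),
        data_dir / "orthologs.tsv",
    )

    write_table(
        AnnotationTable(
            ["fly_gene", "cg_id"],
            [(fb, f"CG{i + 1:05d}") for i, fb in enumerate(fly_genes)],
        ),
        data_dir / "fly2cg.tsv",
    )

    vdrc_mult: dict[str, int] = {}
    vdrc_rows_a: list[tuple[str, str]] = []
    vdrc_no = 0
    for fb in fly_genes:
        m = int(rng.integers(1, 4))
        vdrc_mult[fb] = m
        for _ in range(m):
            vdrc_rows_a.append((fb, f"VDRC{vdrc_no:06d}"))
            vdrc_no += 1
    write_table(
        AnnotationTable(["fly_gene", "vdrc_id"], vdrc_rows_a),
        data_dir / "fly2vdrc_a.tsv",
    )

    # Later version of the secondary-id mapping: a recorded subset of
    # ortholog genes maps to fresh identifiers (multiplicity may change).
    changed_fly = {fb for fb in fly_genes if rng.random() < 0.3}
    if not changed_fly:
        changed_fly = {fly_genes[0]}
    vdrc_mult_b: dict[str, int] = dict(vdrc_mult)
    vdrc_rows_b: list[tuple[str, str]] = []
    by_fly_a: dict[str, list[str]] = {}
    for fb, v in vdrc_rows_a:
        by_fly_a.setdefault(fb, []).append(v)
    for fb in fly_genes:
        if fb in changed_fly:
            m = int(rng.integers(1, 4))
            vdrc_mult_b[fb] = m
            for _ in range(m):
                vdrc_rows_b.append((fb, f"VDRC{vdrc_no:06d}"))
                vdrc_no += 1
        else:
            vdrc_rows_b.extend((fb, v) for v in by_fly_a[fb])
    write_table(
        AnnotationTable(["fly_gene", "vdrc_id"], vdrc_rows_b),
        data_dir / "fly2vdrc_b.tsv",
    )

    registry = Registry(out_dir / "registry")
    registry.root.mkdir(parents=True, exist_ok=True)
    v_old, v_new = "2012-01-01", "2014-01-01"
    pins: dict[str, tuple[str, str, Path]] = {
        "loci": ("loci", v_old, data_dir / "loci.tsv"),
        "snp_coords": ("snp_coords", v_old, data_dir / "snp_coords.tsv"),
        "liftover": ("offset_map", v_old, data_dir / "offset_map.tsv"),
        "block_assign": ("blocks", v_old, data_dir / "blocks.tsv"),
        "block_genes": ("genes", v_old, data_dir / "genes.tsv"),
        "gene_symbol": ("gene2symbol", v_old, data_dir / "gene2symbol.tsv"),
        "ortholog": ("orthologs", v_old, data_dir / "orthologs.tsv"),
        "cg": ("fly2cg", v_old, data_dir / "fly2cg.tsv"),
    }
    for tool, (name, version, path) in pins.items():
        registry.add_file(name, version, path)
    registry.add_file("fly2vdrc", v_old, data_dir / "fly2vdrc_a.tsv")
    registry.add_file("fly2vdrc", v_new, data_dir / "fly2vdrc_b.tsv")
    for release in ("1", "2"):
        for tool, (name, version, _) in pins.items():
            registry.pin(release, tool, name, version)
    registry.pin("1", "vdrc", "fly2vdrc", v_old)
    registry.pin("2", "vdrc", "fly2vdrc", v_new)
    registry.save()

    expected = {"1": 0, "2": 0}
    for block_id in (b[3] for b in blocks):
        for g in genes_per_block[block_id]:
            g_flies = [fb for (hg, fb, _) in orth_rows if hg == g]
            expected["1"] += sum(vdrc_mult[fb] for fb in g_flies)
            expected["2"] += sum(vdrc_mult_b[fb] for fb in g_flies)

    paths = {name: path for _, (name, _, path) in pins.items()}
    paths["fly2vdrc_a"] = data_dir / "fly2vdrc_a.tsv"
    paths["fly2vdrc_b"] = data_dir / "fly2vdrc_b.tsv"
    return GenomeFixture(
        registry=registry,
        loci_path=data_dir / "loci.tsv",
        expected_rows=expected,
        changed_fly_genes=changed_fly,
        paths=paths,
    )


# ---------------------------------------------------------------------------
# planted-signal benchmark


@dataclass
class BenchmarkCase:
    case_id: str
    training: list[str]
    candidates: list[str]  # includes the planted gene
    planted: str
    bundle: EvidenceBundle


def gen_benchmark(
    spec: FixtureSpec, out_dir: Optional[Path | str] = None
) -> list[BenchmarkCase]:
    """Seeded benchmark cases with one planted disease gene each.

    Per case the training genes share a pool of ontology terms and
    complex/pathway/interaction affinity.  Every candidate is linked to
    each unit of training evidence (edge to a training gene, shared
    complex, shared pathway, pool term) independently with probability
    theta for the planted gene and ``baseline`` for the background, so
    theta == baseline is the exchangeable null.  Case streams are keyed
    by (seed, "benchmark", case index): changing n_cases never perturbs
    earlier cases.
    """
    if spec.n_candidates < 5:
        raise ValueError("need at least 5 candidates per case")
    graph = gen_ontology(replace(spec, n_terms=min(spec.n_terms, 40)))
    non_root = [t for t in sorted(graph.terms) if graph.parents(t)]
    cases = []
    for c in range(spec.n_cases):
        rng = _rng(spec, "benchmark", c)
        case_id = f"case{c:04d}"
        training = [f"TR{j}" for j in range(spec.n_training)]
        candidates = [f"C{j:03d}" for j in range(spec.n_candidates)]
        planted = candidates[int(rng.integers(spec.n_candidates))]

        pool_idx = rng.choice(len(non_root), size=min(6, len(non_root)),
                              replace=False)
        pool = [non_root[int(i)] for i in sorted(pool_idx)]
        non_pool = [t for t in non_root if t not in set(pool)]

        direct: dict[str, set[str]] = {}
        for t_gene in training:
            terms = {p for p in pool if rng.random() < 0.7}
            if not terms:
                terms = {pool[int(rng.integers(len(pool)))]}
            terms.add(non_pool[int(rng.integers(len(non_pool)))])
            direct[t_gene] = terms

        complexes: dict[str, frozenset[str]] = {}
        pathways: dict[str, frozenset[str]] = {}
        group_members: dict[str, set[str]] = {}
        for kind, store in (("CPX", complexes), ("PWY", pathways)):
            for g in range(3):
                members = {t for t in training if rng.random() < 0.7}
                if not members:
                    members = {training[int(rng.integers(len(training)))]}
                group_members[f"{kind}{g}"] = members

        interactions: set[frozenset[str]] = set()
        for cand in candidates:
            p = spec.theta if cand == planted else spec.baseline
            for t_gene in training:
                if rng.random() < p:
                    interactions.add(frozenset({cand, t_gene}))
            for g in range(3):
                if rng.random() < p:
                    group_members[f"CPX{g}"] = group_members[f"CPX{g}"] | {cand}
            for g in range(3):
                if rng.random() < p:
                    group_members[f"PWY{g}"] = group_members[f"PWY{g}"] | {cand}
            terms = {t for t in pool if rng.random() < p}
            terms.add(non_pool[int(rng.integers(len(non_pool)))])
            if rng.random() < 0.5:
                terms.add(non_pool[int(rng.integers(len(non_pool)))])
            direct[cand] = terms
        for g in range(3):
            complexes[f"CPX{g}"] = frozenset(group_members[f"CPX{g}"])
            pathways[f"PWY{g}"] = frozenset(group_members[f"PWY{g}"])

        corpus = propagate(graph, direct)
        ic = build_ic(corpus, graph, spec.namespace)
        bundle = EvidenceBundle(
            interactions=interactions,
            complexes=complexes,
            pathways=pathways,
            corpus=corpus,
            ic=ic,
            graph=graph,
        )
        cases.append(BenchmarkCase(case_id, training, candidates, planted, bundle))
    if out_dir is not None:
        write_benchmark(cases, out_dir)
    return cases


def write_benchmark(cases: Sequence[BenchmarkCase], out_dir: Path | str) -> None:
    """One subdirectory of plain TSVs per case."""
    out_dir = Path(out_dir)
    for case in cases:
        case_dir = out_dir / case.case_id
        case_dir.mkdir(parents=True, exist_ok=True)
        write_table(
            AnnotationTable(["gene"], [(g,) for g in case.training]),
            case_dir / "training.tsv",
        )
        write_table(
            AnnotationTable(["gene"], [(g,) for g in case.candidates]),
            case_dir / "candidates.tsv",
        )
        (case_dir / "disease_gene.txt").write_text(
            case.planted + "\n", encoding="utf-8"
        )
        bundle = case.bundle
        edge_rows = sorted(tuple(sorted(e)) for e in bundle.interactions)
        write_table(
            AnnotationTable(["gene_a", "gene_b"], edge_rows),
            case_dir / "interactions.tsv",
        )
        for fname, groups in (
            ("complexes.tsv", bundle.complexes),
            ("pathways.tsv", bundle.pathways),
        ):
            rows = [
                (name, gene)
                for name in sorted(groups)
                for gene in sorted(groups[name])
            ]
            write_table(
                AnnotationTable(["set_id", "gene"], rows), case_dir / fname
            )
        assert bundle.corpus is not None
        rows = [
            (obj, term)
            for obj in sorted(bundle.corpus.direct)
            for term in sorted(bundle.corpus.direct[obj])
        ]
        write_table(
            AnnotationTable(["object", "term"], rows),
            case_dir / "annotations.tsv",
        )


__all__ = [
    "FixtureSpec",
    "gen_ontology",
    "gene_ids",
    "gen_corpus",
    "Networks",
    "gen_networks",
    "GenomeFixture",
    "gen_genome_fixture",
    "BenchmarkCase",
    "gen_benchmark",
    "write_benchmark",
]
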