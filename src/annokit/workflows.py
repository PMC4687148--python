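"""Ready-made pipelines assembled from the annotation tools.

The flagship example is the GWAS-to-ortholog workflow: take tag SNPs from
an association study, lift their coordinates to the current assembly,
find the haplotype block containing each SNP, collect the genes in that
block, convert them to symbols, map them to model-organism orthologs and
finally to secondary identifiers usable for ordering knock-down lines.
Every step appends columns to the running table and expands rows on
multiple hits; all data files are resolved through a release manifest, so
the run is exactly reproducible under a fixed release.
"""

from __future__ import annotations

from typing import Optional

from .idmap import MappingTable, as_annotator
from .registry import Registry
from .table import AnnotationTable, annotate, read_table
from .variants import (
    OffsetMap,
    Variant,
    assign_block,
    lookup_annotation,
    overlap,
    read_blocks,
    read_features,
)
from .exceptions import NoBlockError


def run_gwas_ortholog_pipeline(
    registry: Registry,
    release_id: str | int,
    loci: Optional[AnnotationTable] = None,
) -> AnnotationTable:
    """SNP loci -> coordinates -> liftover -> block -> genes -> symbols ->
    orthologs -> secondary ids, all under one release manifest.

    ``loci`` overrides the pinned input table (a 1-column ``snp_id``
    TSV).  Output columns append, in order: old_chrom, old_pos, chrom,
    pos, block_id, block_start, block_end, gene_id, symbol, fly_gene,
    cg_id, vdrc_id.  Rows whose key is missing at some step are kept,
    padded with the missing token.
    """
    path = lambda tool: registry.resolve_path(tool, release_id)  # noqa: E731

    if loci is None:
        loci = read_table(path("loci"))
    table = loci

    coords_annotator, coord_cols = lookup_annotation(
        read_table(path("snp_coords")), "snp_id"
    )
    table = annotate(table, ["snp_id"], coords_annotator, coord_cols)

    offset_map = OffsetMap.from_tsv(path("liftover"))

    def lift(key: tuple[str, ...]) -> list[tuple[str, ...]]:
        chrom, pos = key
        if not pos.isdigit():
            return []
        mapped = offset_map.map_position(chrom, int(pos))
        return [] if mapped is None else [(mapped[0], str(mapped[1]))]

    table = annotate(table, ["old_chrom", "old_pos"], lift, ["chrom", "pos"])

    blocks = read_blocks(path("block_assign"))

    def block_hit(key: tuple[str, ...]) -> list[tuple[str, ...]]:
        chrom, pos = key
        if not pos.isdigit():
            return []
        try:
            block, _distance = assign_block(Variant(chrom, int(pos)), blocks)
        except NoBlockError:
            return []
        return [(block.block_id, str(block.start), str(block.end))]

    table = annotate(
        table, ["chrom", "pos"], block_hit,
        ["block_id", "block_start", "block_end"],
    )

    features = read_features(path("block_genes"))

    def block_genes(key: tuple[str, ...]) -> list[tuple[str, ...]]:
        chrom, start, end = key
        if not (start.isdigit() and end.isdigit()):
            return []
        hits = overlap(chrom, int(start), int(end), features)
        return [(f.feature_id,) for f in hits]

    table = annotate(
        table, ["chrom", "block_start", "block_end"], block_genes, ["gene_id"]
    )

    for tool, key_column, new_column, columns in (
        ("gene_symbol", "gene_id", "symbol", (0, 1)),
        ("ortholog", "gene_id", "fly_gene", (0, 1)),
        ("cg", "fly_gene", "cg_id", (0, 1)),
        ("vdrc", "fly_gene", "vdrc_id", (0, 1)),
    ):
        mapping = MappingTable.from_tsv(path(tool))
        table = annotate(table, [key_column], as_annotator(mapping), [new_column])
    return table


__all__ = ["run_gwas_ortholog_pipeline"]
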