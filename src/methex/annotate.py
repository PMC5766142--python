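"""Genomic-context annotation of DMRs.

Each DMR gets exactly one gene-context label, assigned by overlap with
precedence promoter > 5UTR > 3UTR > exon > intron > intergenic (the
promoter is ``promoter_bp`` upstream of the strand-aware transcription
start), and one CpG-island-context label from the gap to the nearest
island: 0 bp -> island, 1-3000 bp -> shore, >3000 bp -> distant. Distances
are measured between interval boundaries, not midpoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dmr_stats import nearest_gene
from .io_core import GeneModel, GenomicInterval

__all__ = ["DMRAnnotation", "annotate_dmr", "annotate_table", "genomic_distribution_summary"]

GENE_CONTEXTS = ("promoter", "5UTR", "3UTR", "exon", "intron", "intergenic")
ISLAND_CONTEXTS = ("island", "shore", "distant")
SHORE_MAX_BP = 3000
GENE_BODY_CONTEXTS = ("5UTR", "exon", "intron", "3UTR")


@dataclass(frozen=True)
class DMRAnnotation:
    gene_context: str
    island_context: str
    nearest_gene: str | None
    distance_bp: float
    length_bp: int


def _overlaps(iv: GenomicInterval, chrom: str, start: int, end: int) -> bool:
    return iv.chrom == chrom and iv.start < end and start < iv.end


def _gene_context_flags(iv: GenomicInterval, g: GeneModel, promoter_bp: int) -> set[str]:
    flags: set[str] = set()
    if g.chrom != iv.chrom:
        return flags
    # promoter: promoter_bp upstream of the strand-aware TSS
    if g.strand == "-":
        prom = (g.end, g.end + promoter_bp)
    else:
        prom = (max(0, g.start - promoter_bp), g.start)
    if prom[0] < prom[1] and _overlaps(iv, g.chrom, *prom):
        flags.add("promoter")
    if not _overlaps(iv, g.chrom, g.start, g.end):
        return flags
    exon_hit = utr5_hit = utr3_hit = False
    for s, e in zip(g.exon_starts, g.exon_ends):
        if not _overlaps(iv, g.chrom, s, e):
            continue
        # split the exon block into 5'UTR / CDS / 3'UTR pieces
        left = (s, min(e, g.cds_start))       # upstream-of-CDS piece in tx coords
        right = (max(s, g.cds_end), e)        # downstream-of-CDS piece
        cds = (max(s, g.cds_start), min(e, g.cds_end))
        if left[0] < left[1] and _overlaps(iv, g.chrom, *left):
            if g.strand == "-":
                utr3_hit = True
            else:
                utr5_hit = True
        if right[0] < right[1] and _overlaps(iv, g.chrom, *right):
            if g.strand == "-":
                utr5_hit = True
            else:
                utr3_hit = True
        if cds[0] < cds[1] and _overlaps(iv, g.chrom, *cds):
            exon_hit = True
    if utr5_hit:
        flags.add("5UTR")
    if utr3_hit:
        flags.add("3UTR")
    if exon_hit:
        flags.add("exon")
    # inside the gene body: intron if it touches an intron or no exonic piece
    if _spans_intron(iv, g) or not (utr5_hit or utr3_hit or exon_hit):
        flags.add("intron")
    return flags


def _spans_intron(iv: GenomicInterval, g: GeneModel) -> bool:
    for (e_prev, s_next) in zip(g.exon_ends[:-1], g.exon_starts[1:]):
        if e_prev < s_next and _overlaps(iv, g.chrom, e_prev, s_next):
            return True
    return False


def annotate_dmr(
    interval: GenomicInterval,
    genes: Sequence[GeneModel],
    islands: Sequence[GenomicInterval],
    promoter_bp: int = 2000,
) -> DMRAnnotation:
    """Annotate one DMR interval; see the module docstring for the rules."""
    flags: set[str] = set()
    for g in genes:
        flags |= _gene_context_flags(interval, g, promoter_bp)
    gene_context = "intergenic"
    for ctx in GENE_CONTEXTS[:-1]:
        if ctx in flags:
            gene_context = ctx
            break

    min_gap: float = np.inf
    for isl in islands:
        d = interval.distance_to(isl)
        if d is not None and d < min_gap:
            min_gap = d
    if min_gap == 0:
        island_context = "island"
    elif min_gap <= SHORE_MAX_BP:
        island_context = "shore"
    else:
        island_context = "distant"

    name, dist = nearest_gene(interval, genes)
    return DMRAnnotation(
        gene_context=gene_context,
        island_context=island_context,
        nearest_gene=name,
        distance_bp=dist,
        length_bp=interval.length,
    )


def annotate_table(
    table: pd.DataFrame,
    genes: Sequence[GeneModel],
    islands: Sequence[GenomicInterval],
    promoter_bp: int = 2000,
) -> pd.DataFrame:
    """Annotate every row of a DMR table (needs chrom/start/end columns)."""
    out = table.copy()
    anns = [
        annotate_dmr(GenomicInterval(r.chrom, int(r.start), int(r.end)), genes, islands, promoter_bp)
        for r in out.itertuples()
    ]
    out["gene_context"] = [a.gene_context for a in anns]
    out["island_context"] = [a.island_context for a in anns]
    out["nearest_gene"] = [a.nearest_gene for a in anns]
    out["gene_distance"] = [a.distance_bp for a in anns]
    out["length_bp"] = [a.length_bp for a in anns]
    return out


def genomic_distribution_summary(annotations: Sequence[DMRAnnotation]) -> pd.DataFrame:
    """Counts and percentages per gene-context and island-context category,
    plus the gene-body aggregate (5UTR + exon + intron + 3UTR)."""
    n = len(annotations)
    rows = []
    for ctx in GENE_CONTEXTS:
        c = sum(a.gene_context == ctx for a in annotations)
        rows.append(("gene", ctx, c, 100.0 * c / n if n else 0.0))
    body = sum(a.gene_context in GENE_BODY_CONTEXTS for a in annotations)
    rows.append(("gene", "gene_body", body, 100.0 * body / n if n else 0.0))
    for ctx in ISLAND_CONTEXTS:
        c = sum(a.island_context == ctx for a in annotations)
        rows.append(("island", ctx, c, 100.0 * c / n if n else 0.0))
    return pd.DataFrame(rows, columns=["axis", "category", "count", "percent"])
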