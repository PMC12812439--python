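"""Linking DMRs to genes and classifying DMR-associated DEGs.

A DMR is associated with a gene when it overlaps the gene body or a 2 kb
flanking window on either side (windows follow gene strand: "upstream" is
5' of the TSS, "downstream" 3' of the TES).  DMR-DEG counts are stratified
by methylation context, genomic region, methylation direction and
expression regulation; genes linked to more than one DMR are further
classified as unidirectional (all linked DMRs share a direction) or
bidirectional multi-DMR genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .dmr import Dmr
from .io import GeneModel, GenomicInterval

REGIONS = ("upstream", "gene_body", "downstream")
CONTEXTS = ("CG", "CHG", "CHH")
DIRECTIONS = ("hyper", "hypo")
REGULATIONS = ("up", "down")


def classify_deg(
    log2fc: float,
    fdr: float,
    fc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
) -> Literal["up", "down", "ns"]:
    """Differential-expression status with strict thresholds: 'up' iff
    FDR < 0.05 and log2FC > 1, 'down' iff FDR < 0.05 and log2FC < -1,
    otherwise 'ns' (a gene exactly at a boundary is not significant)."""
    if fdr < fdr_threshold:
        if log2fc > fc_threshold:
            return "up"
        if log2fc < -fc_threshold:
            return "down"
    return "ns"


def gene_windows(
    gene: GeneModel, flank_bp: int = 2000
) -> dict[str, GenomicInterval]:
    """The three analysis windows of a gene: upstream flank, gene body,
    downstream flank, oriented by gene strand and clipped at zero.
    Windows that collapse to zero width (a gene starting at the
    chromosome edge) are omitted."""
    iv = gene.interval
    before = (max(0, iv.start - flank_bp), iv.start)
    after = (iv.end, iv.end + flank_bp)
    if iv.strand == "-":
        names = {"downstream": before, "gene_body": (iv.start, iv.end),
                 "upstream": after}
    else:
        names = {"upstream": before, "gene_body": (iv.start, iv.end),
                 "downstream": after}
    return {
        region: GenomicInterval(iv.chrom, start, end, iv.strand)
        for region, (start, end) in names.items()
        if start < end
    }


@dataclass(frozen=True)
class DmrGeneLink:
    gene_id: str
    dmr_index: int  # position in the DMR list passed to the linker
    region: str
    context: str
    direction: str


def link_dmrs_to_genes(
    dmrs: Sequence[Dmr],
    genes: Sequence[GeneModel],
    flank_bp: int = 2000,
) -> list[DmrGeneLink]:
    """All (dmr, gene, window) pairs with at least 1 bp overlap.

    One DMR may link to several windows of one gene (e.g. straddling the
    TSS) and to several genes; each such pair is a separate link.
    """
    trees: dict[str, IntervalTree] = {}
    for dmr_index, dmr in enumerate(dmrs):
        iv = dmr.interval
        trees.setdefault(iv.chrom, IntervalTree()).addi(
            iv.start, iv.end, dmr_index
        )
    links: list[DmrGeneLink] = []
    for gene in genes:
        tree = trees.get(gene.interval.chrom)
        if tree is None:
            continue
        for region, window in gene_windows(gene, flank_bp).items():
            for hit in tree.overlap(window.start, window.end):
                dmr = dmrs[hit.data]
                links.append(
                    DmrGeneLink(
                        gene_id=gene.gene_id,
                        dmr_index=hit.data,
                        region=region,
                        context=dmr.context,
                        direction=dmr.direction,
                    )
                )
    links.sort(key=lambda l: (l.gene_id, l.dmr_index, REGIONS.index(l.region)))
    return links


def dmr_deg_counts(
    links: Sequence[DmrGeneLink],
    deg_status: Mapping[str, str],
) -> pd.DataFrame:
    """Count DMR-DEG links into the 36-cell table
    context x region x direction x regulation (tidy long format, all
    cells present).  Links to non-significant genes are excluded."""
    counts = {
        cell: 0
        for cell in product(CONTEXTS, REGIONS, DIRECTIONS, REGULATIONS)
    }
    for link in links:
        regulation = deg_status.get(link.gene_id, "ns")
        if regulation == "ns":
            continue
        counts[(link.context, link.region, link.direction, regulation)] += 1
    return pd.DataFrame(
        [
            {
                "context": c, "region": r, "direction": d,
                "regulation": g, "count": n,
            }
            for (c, r, d, g), n in counts.items()
        ]
    )


@dataclass(frozen=True)
class MultiDmrClass:
    gene_id: str
    n_dmrs: int
    klass: Literal["single", "unidirectional_multi", "bidirectional_multi"]


def multi_dmr_classes(
    links: Sequence[DmrGeneLink],
    deg_status: Mapping[str, str],
) -> list[MultiDmrClass]:
    """Classify each DMR-DEG gene by its distinct linked DMRs.

    A DMR appearing in two windows of one gene counts once (it is one
    DMR).  Genes with one DMR are 'single'; genes with several DMRs are
    'unidirectional_multi' when all share a direction and
    'bidirectional_multi' when both directions occur.
    """
    per_gene: dict[str, dict[int, str]] = {}
    for link in links:
        if deg_status.get(link.gene_id, "ns") == "ns":
            continue
        per_gene.setdefault(link.gene_id, {})[link.dmr_index] = link.direction
    out = []
    for gene_id in sorted(per_gene):
        directions = set(per_gene[gene_id].values())
        n = len(per_gene[gene_id])
        if n == 1:
            klass = "single"
        elif len(directions) == 1:
            klass = "unidirectional_multi"
        else:
            klass = "bidirectional_multi"
        out.append(MultiDmrClass(gene_id, n, klass))
    return out
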