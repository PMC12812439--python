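"""Tetraploid allele-dosage analysis within DMRs.

In an autotetraploid, each biallelic site carries 0-4 copies of the
alternative allele (the dosage).  Per DMR, the dosages of all contained
SNPs are summed for each cultivar; comparing the two sums classifies the
DMR as having lower, higher, or equal alternative-allele load in the
comparison cultivar relative to the reference.  Crossing that relation
with the DMR's methylation direction tests whether methylation
differences track allelic variation (the expected signature of
methylcytosine deamination is a *negative* association: hypomethylated
regions accumulate more alternative alleles).

The deamination subset restricts to C:T / T:C transitions and their
reverse complements G:A / A:G, the classes attributable to deamination of
(methyl)cytosine on either strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product
from typing import Mapping, Sequence

import pandas as pd

from .association import DIRECTIONS, REGIONS, DmrGeneLink
from .dmr import Dmr
from .io import GenomicInterval, SnpRecord

logger = logging.getLogger(__name__)

RELATIONS = ("cmp_lt_ref", "cmp_gt_ref", "equal")

DEAMINATION_PAIRS = frozenset(
    [("C", "T"), ("T", "C"), ("G", "A"), ("A", "G")]
)


@dataclass
class SnpFilterParams:
    """SNP quality filters: biallelic SNPs with dosage-based minor allele
    frequency above ``min_maf`` (both alleles), QUAL >= ``min_qual`` and
    every sample's read depth within ``[min_depth, max_depth]``
    (inclusive)."""

    min_maf: float = 0.1
    min_qual: float = 30.0
    min_depth: int = 10
    max_depth: int = 50
    biallelic_only: bool = True

    def __post_init__(self):
        if not (0 < self.min_maf < 0.5):
            raise ValueError("min_maf must be in (0, 0.5)")
        if self.min_depth > self.max_depth:
            raise ValueError("min_depth must be <= max_depth")


def alt_allele_frequency(record: SnpRecord) -> float | None:
    """Alternative-allele frequency from tetraploid dosages across all
    genotyped samples (``sum(dosage) / (4 * n_genotyped)``); None when no
    sample is genotyped."""
    dosages = [d for d in record.dosage.values() if d is not None]
    if not dosages:
        return None
    return sum(dosages) / (4 * len(dosages))


def filter_snps(
    records: Sequence[SnpRecord],
    params: SnpFilterParams | None = None,
) -> list[SnpRecord]:
    """Apply the SNP quality filters; records missing genotypes in every
    sample are dropped (their count is logged)."""
    if params is None:
        params = SnpFilterParams()
    kept: list[SnpRecord] = []
    n_all_missing = 0
    for rec in records:
        if params.biallelic_only and not rec.is_biallelic_snp:
            continue
        if not (rec.qual >= params.min_qual):  # NaN QUAL fails
            continue
        if any(
            not (params.min_depth <= d <= params.max_depth)
            for d in rec.depth.values()
        ):
            continue
        freq = alt_allele_frequency(rec)
        if freq is None:
            n_all_missing += 1
            continue
        if not (params.min_maf < freq < 1 - params.min_maf):
            continue
        kept.append(rec)
    if n_all_missing:
        logger.info(
            "filter_snps: dropped %d records with no genotyped sample",
            n_all_missing,
        )
    return kept


def snps_in_interval(
    snps: Sequence[SnpRecord], interval: GenomicInterval
) -> list[SnpRecord]:
    """SNPs whose 0-based point (pos - 1) lies within the half-open
    interval."""
    return [
        s
        for s in snps
        if s.chrom == interval.chrom
        and interval.start <= s.pos - 1 < interval.end
    ]


@dataclass
class DmrDosage:
    """Per-DMR summed alternative-allele dosages for the two cultivars."""

    dmr_index: int
    dosage_ref: int
    dosage_cmp: int
    n_snps: int

    @property
    def relation(self) -> str:
        if self.dosage_cmp < self.dosage_ref:
            return "cmp_lt_ref"
        if self.dosage_cmp > self.dosage_ref:
            return "cmp_gt_ref"
        return "equal"


def dmr_dosage(
    dmr: Dmr,
    snps: Sequence[SnpRecord],
    ref_samples: Sequence[str],
    cmp_samples: Sequence[str],
    dmr_index: int = 0,
) -> DmrDosage:
    """Sum per-cultivar dosages over SNPs contained in the DMR interval.

    Only SNPs inside the DMR itself are summed (not the gene window the
    DMR may sit in).  A SNP missing a genotype in any required sample is
    excluded from both sums.  A DMR with no usable SNPs is 'equal' (0=0).
    """
    contained = snps_in_interval(snps, dmr.interval)
    ref_sum = 0
    cmp_sum = 0
    n_used = 0
    for snp in contained:
        ref_d = [snp.dosage.get(s) for s in ref_samples]
        cmp_d = [snp.dosage.get(s) for s in cmp_samples]
        if any(d is None for d in ref_d + cmp_d):
            continue
        ref_sum += sum(ref_d)
        cmp_sum += sum(cmp_d)
        n_used += 1
    return DmrDosage(
        dmr_index=dmr_index, dosage_ref=ref_sum, dosage_cmp=cmp_sum,
        n_snps=n_used,
    )


def deamination_subset(snps: Sequence[SnpRecord]) -> list[SnpRecord]:
    """SNPs in the deamination transition classes C:T, T:C, G:A, A:G."""
    return [s for s in snps if (s.ref, s.alt) in DEAMINATION_PAIRS]


def dosage_association_summary(
    dmr_dosages: Sequence[DmrDosage],
    links: Sequence[DmrGeneLink],
    deg_status: Mapping[str, str],
    gene_set_mode: str = "deg_only",
) -> pd.DataFrame:
    """Count DMRs into region x direction x relation cells.

    A DMR linked to several genes or windows contributes one count per
    (gene, window) link in the selected gene set (``deg_only`` keeps links
    whose gene is up- or down-regulated; ``all_genes`` keeps every
    DMR-associated gene).  Tidy long output with all 18 cells present.
    """
    if gene_set_mode not in ("deg_only", "all_genes"):
        raise ValueError(f"unknown gene_set_mode {gene_set_mode!r}")
    by_index = {d.dmr_index: d for d in dmr_dosages}
    counts = {cell: 0 for cell in product(REGIONS, DIRECTIONS, RELATIONS)}
    for link in links:
        if gene_set_mode == "deg_only":
            if deg_status.get(link.gene_id, "ns") == "ns":
                continue
        dosage = by_index.get(link.dmr_index)
        if dosage is None:
            continue
        counts[(link.region, link.direction, dosage.relation)] += 1
    return pd.DataFrame(
        [
            {"region": r, "direction": d, "relation": rel, "count": n}
            for (r, d, rel), n in counts.items()
        ]
    )
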