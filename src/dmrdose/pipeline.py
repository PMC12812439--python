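"""End-to-end orchestration of the constitutive and induced analyses.

The core entry points work on in-memory objects so tests and scripts can
drive them directly:

* :func:`constitutive_analysis` — cultivar-vs-cultivar DMRs at baseline,
  DMR-gene links, DMR-DEG count tables, the multi-DMR taxonomy, and the
  dosage-association summaries (with a deamination-restricted variant);
* :func:`induced_analysis` — before-vs-after DMRs within one cultivar and
  their DEG links.

:func:`run_constitutive` / :func:`run_induced` wrap these behind a
declarative configuration (YAML-friendly dict) that names the input
files, and :func:`report` writes the tidy result tables plus a run
manifest (seed, configuration hash, package version) so identical
configurations yield byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .association import (
    DmrGeneLink,
    MultiDmrClass,
    dmr_deg_counts,
    link_dmrs_to_genes,
    multi_dmr_classes,
)
from .dmr import Dmr, DmrParams, call_dmrs, dmrs_to_bed, dmrs_to_frame
from .dosage import (
    DmrDosage,
    SnpFilterParams,
    deamination_subset,
    dmr_dosage,
    dosage_association_summary,
    filter_snps,
)
from .io import (
    GeneModel,
    SnpRecord,
    read_annotations,
    read_cx_report,
    read_de_table,
    read_vcf_tetraploid,
)

logger = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH")


# ---------------------------------------------------------------------------
# Summary arithmetic (count identities)
# ---------------------------------------------------------------------------

def deg_total(n_up: int, n_down: int) -> int:
    """Total DEG count from up- and down-regulated counts."""
    return int(n_up) + int(n_down)

def dmr_deg_percent(n_dmr_deg: int, n_deg: int) -> float:
    """Percentage of DEGs that are DMR-associated (0-100 scale)."""
    if n_deg == 0:
        return 0.0
    return 100.0 * n_dmr_deg / n_deg

def multi_dmr_partition(classes: Sequence[MultiDmrClass]) -> dict[str, int]:
    """Partition of DMR-DEG genes into single / unidirectional-multi /
    bidirectional-multi, plus the derived totals.  The partition identity
    single + unidirectional + bidirectional == total holds by
    construction."""
    counts = {"single": 0, "unidirectional_multi": 0, "bidirectional_multi": 0}
    for cls in classes:
        counts[cls.klass] += 1
    counts["multi"] = counts["unidirectional_multi"] + counts["bidirectional_multi"]
    counts["total"] = counts["single"] + counts["multi"]
    return counts


# ---------------------------------------------------------------------------
# In-memory analyses
# ---------------------------------------------------------------------------

@dataclass
class ConstitutiveResults:
    dmrs: dict[str, list[Dmr]]  # context -> DMR list
    all_dmrs: list[Dmr]  # flattened, the index space used by links
    links: list[DmrGeneLink]
    deg_status: dict[str, str]
    deg_counts: pd.DataFrame
    classes: list[MultiDmrClass]
    partition: dict[str, int]
    dosages: list[DmrDosage]
    summary_deg_only: pd.DataFrame
    summary_all_genes: pd.DataFrame
    summary_deam_deg_only: pd.DataFrame
    summary_deam_all_genes: pd.DataFrame


def call_all_contexts(
    ref_group: Sequence[pd.DataFrame],
    cmp_group: Sequence[pd.DataFrame],
    params: Mapping[str, DmrParams] | None = None,
) -> dict[str, list[Dmr]]:
    """DMRs per context between two replicate groups."""
    out: dict[str, list[Dmr]] = {}
    for context in CONTEXTS:
        p = (params or {}).get(context) or DmrParams.for_context(context)
        out[context] = call_dmrs(ref_group, cmp_group, context, p)
    return out


def constitutive_analysis(
    ref_group: Sequence[pd.DataFrame],
    cmp_group: Sequence[pd.DataFrame],
    genes: Sequence[GeneModel],
    de_table: pd.DataFrame,
    snps: Sequence[SnpRecord],
    ref_samples: Sequence[str],
    cmp_samples: Sequence[str],
    dmr_params: Mapping[str, DmrParams] | None = None,
    snp_params: SnpFilterParams | None = None,
    flank_bp: int = 2000,
) -> ConstitutiveResults:
    """Cultivar-vs-cultivar analysis at baseline: DMRs, DEG association,
    multi-DMR taxonomy and allele-dosage summaries."""
    dmrs_by_context = call_all_contexts(ref_group, cmp_group, dmr_params)
    all_dmrs = [d for context in CONTEXTS for d in dmrs_by_context[context]]
    links = link_dmrs_to_genes(all_dmrs, list(genes), flank_bp=flank_bp)
    deg_status = dict(zip(de_table["gene_id"], de_table["status"]))
    counts = dmr_deg_counts(links, deg_status)
    classes = multi_dmr_classes(links, deg_status)
    partition = multi_dmr_partition(classes)

    kept_snps = filter_snps(list(snps), snp_params)
    dosages = [
        dmr_dosage(dmr, kept_snps, ref_samples, cmp_samples, dmr_index=i)
        for i, dmr in enumerate(all_dmrs)
    ]
    deam_snps = deamination_subset(kept_snps)
    deam_dosages = [
        dmr_dosage(dmr, deam_snps, ref_samples, cmp_samples, dmr_index=i)
        for i, dmr in enumerate(all_dmrs)
    ]
    return ConstitutiveResults(
        dmrs=dmrs_by_context,
        all_dmrs=all_dmrs,
        links=links,
        deg_status=deg_status,
        deg_counts=counts,
        classes=classes,
        partition=partition,
        dosages=dosages,
        summary_deg_only=dosage_association_summary(
            dosages, links, deg_status, "deg_only"
        ),
        summary_all_genes=dosage_association_summary(
            dosages, links, deg_status, "all_genes"
        ),
        summary_deam_deg_only=dosage_association_summary(
            deam_dosages, links, deg_status, "deg_only"
        ),
        summary_deam_all_genes=dosage_association_summary(
            deam_dosages, links, deg_status, "all_genes"
        ),
    )


@dataclass
class InducedResults:
    cultivar: str
    dmrs: dict[str, list[Dmr]]
    all_dmrs: list[Dmr]
    links: list[DmrGeneLink]
    deg_counts: pd.DataFrame


def induced_analysis(
    before_group: Sequence[pd.DataFrame],
    after_group: Sequence[pd.DataFrame],
    genes: Sequence[GeneModel],
    de_table: pd.DataFrame,
    cultivar: str,
    dmr_params: Mapping[str, DmrParams] | None = None,
    flank_bp: int = 2000,
) -> InducedResults:
    """Before-vs-after analysis within one cultivar ('hyper' = more
    methylated after the stress)."""
    dmrs_by_context = call_all_contexts(before_group, after_group, dmr_params)
    all_dmrs = [d for context in CONTEXTS for d in dmrs_by_context[context]]
    links = link_dmrs_to_genes(all_dmrs, list(genes), flank_bp=flank_bp)
    deg_status = dict(zip(de_table["gene_id"], de_table["status"]))
    return InducedResults(
        cultivar=cultivar,
        dmrs=dmrs_by_context,
        all_dmrs=all_dmrs,
        links=links,
        deg_counts=dmr_deg_counts(links, deg_status),
    )


def dmr_count_table(dmrs_by_context: Mapping[str, list[Dmr]]) -> pd.DataFrame:
    """Hyper/hypo DMR counts per context (headline summary shape)."""
    rows = []
    for context in CONTEXTS:
        dmrs = dmrs_by_context.get(context, [])
        rows.append(
            {
                "context": context,
                "hyper": sum(1 for d in dmrs if d.direction == "hyper"),
                "hypo": sum(1 for d in dmrs if d.direction == "hypo"),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# File-driven pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Declarative run configuration.

    ``cx_paths`` maps cultivar -> time point -> list of replicate CX
    report paths.  ``vcf_sample_map`` maps cultivar label to the VCF
    sample names belonging to it (default: the label itself).
    """

    cx_paths: dict[str, dict[str, list[str]]]
    genes_path: str
    de_table_path: str
    vcf_path: str | None = None
    repeats_path: str | None = None
    ref_cultivar: str = "CA"
    cmp_cultivar: str = "AA"
    baseline_timepoint: str = "before"
    stress_timepoint: str = "after"
    vcf_sample_map: dict[str, list[str]] = field(default_factory=dict)
    dmr_overrides: dict[str, dict] = field(default_factory=dict)
    snp_overrides: dict = field(default_factory=dict)
    flank_bp: int = 2000
    outdir: str = "dmrdose_out"
    seed: int = 0

    def __post_init__(self):
        if self.ref_cultivar == self.cmp_cultivar:
            raise ValueError("cultivar labels must be distinct")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as handle:
            data = yaml.safe_load(handle)
        return cls(**data)

    def dmr_params(self) -> dict[str, DmrParams]:
        return {
            context: DmrParams.for_context(
                context, **self.dmr_overrides.get(context, {})
            )
            for context in CONTEXTS
        }

    def snp_params(self) -> SnpFilterParams:
        return SnpFilterParams(**self.snp_overrides)

    def samples_of(self, cultivar: str) -> list[str]:
        return self.vcf_sample_map.get(cultivar, [cultivar])

    def config_hash(self) -> str:
        blob = json.dumps(
            {k: v for k, v in self.__dict__.items()}, sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_group(config: PipelineConfig, cultivar: str, timepoint: str):
    try:
        paths = config.cx_paths[cultivar][timepoint]
    except KeyError:
        raise FileNotFoundError(
            f"no CX reports configured for {cultivar}/{timepoint}"
        ) from None
    missing = [p for p in paths if not os.path.exists(p)]
    if missing:
        raise FileNotFoundError(f"missing replicate files: {missing}")
    return [read_cx_report(p) for p in paths]


def run_constitutive(config: PipelineConfig) -> ConstitutiveResults:
    """File-driven cultivar-vs-cultivar analysis at the baseline
    time point."""
    ref_group = _load_group(config, config.ref_cultivar, config.baseline_timepoint)
    cmp_group = _load_group(config, config.cmp_cultivar, config.baseline_timepoint)
    genes = read_annotations(config.genes_path, kind="gene")
    de_table = read_de_table(config.de_table_path)
    snps = (
        read_vcf_tetraploid(config.vcf_path) if config.vcf_path else []
    )
    return constitutive_analysis(
        ref_group,
        cmp_group,
        genes,
        de_table,
        snps,
        ref_samples=config.samples_of(config.ref_cultivar),
        cmp_samples=config.samples_of(config.cmp_cultivar),
        dmr_params=config.dmr_params(),
        snp_params=config.snp_params(),
        flank_bp=config.flank_bp,
    )


def run_induced(config: PipelineConfig, cultivar: str) -> InducedResults:
    """File-driven before-vs-after analysis within one cultivar."""
    before = _load_group(config, cultivar, config.baseline_timepoint)
    after = _load_group(config, cultivar, config.stress_timepoint)
    genes = read_annotations(config.genes_path, kind="gene")
    de_table = read_de_table(config.de_table_path)
    return induced_analysis(
        before, after, genes, de_table, cultivar,
        dmr_params=config.dmr_params(), flank_bp=config.flank_bp,
    )


def report(
    results: ConstitutiveResults | InducedResults,
    outdir: str,
    config: PipelineConfig | None = None,
    prefix: str = "constitutive",
) -> dict[str, str]:
    """Write tidy TSV tables and a run manifest; returns written paths."""
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}

    def save(name: str, frame: pd.DataFrame):
        path = os.path.join(outdir, f"{prefix}_{name}.tsv")
        frame.to_csv(path, sep="\t", index=False)
        paths[name] = path

    save("dmr_counts", dmr_count_table(results.dmrs))
    save("dmrs", dmrs_to_frame(results.all_dmrs))
    bed_path = os.path.join(outdir, f"{prefix}_dmrs.bed")
    dmrs_to_bed(results.all_dmrs, bed_path)
    paths["dmrs_bed"] = bed_path
    save("dmr_deg_counts", results.deg_counts)
    links_frame = pd.DataFrame(
        [
            {
                "gene_id": l.gene_id, "dmr_index": l.dmr_index,
                "region": l.region, "context": l.context,
                "direction": l.direction,
            }
            for l in results.links
        ],
        columns=["gene_id", "dmr_index", "region", "context", "direction"],
    )
    save("links", links_frame)
    if isinstance(results, ConstitutiveResults):
        save("summary_deg_only", results.summary_deg_only)
        save("summary_all_genes", results.summary_all_genes)
        save("summary_deamination_deg_only", results.summary_deam_deg_only)
        save("summary_deamination_all_genes", results.summary_deam_all_genes)
        partition_frame = pd.DataFrame(
            [results.partition]
        )[["single", "unidirectional_multi", "bidirectional_multi", "multi", "total"]]
        save("multi_dmr_partition", partition_frame)
    manifest = {
        "tool": "dmrdose",
        "version": __version__,
        "prefix": prefix,
        "seed": config.seed if config else None,
        "config_hash": config.config_hash() if config else None,
        "tables": sorted(paths),
    }
    manifest_path = os.path.join(outdir, f"{prefix}_manifest.json")
    with open(manifest_path, "w") as handle:
        json.dump(manifest, handle, indent=1, sort_keys=True)
    paths["manifest"] = manifest_path
    return paths
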