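"""Readers and writers for the file formats the pipeline touches.

All genomic coordinates are converted to a single internal convention at
the I/O boundary: 0-based, half-open intervals (``start`` inclusive,
``end`` exclusive), as in BED.  Positions stored 1-based on disk (Bismark
cytosine reports, GFF3, VCF) are converted on read and back on write.

Bulk per-cytosine data is carried as a :class:`pandas.DataFrame` with the
columns in :data:`CX_COLUMNS`; ``pos`` in that frame keeps the on-disk
1-based coordinate so that a written report is byte-identical to its
source.  Small record collections (genes, repeats, SNPs) are lists of
dataclasses.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

VALID_CONTEXTS = ("CG", "CHG", "CHH")
VALID_STRANDS = ("+", "-")

#: Column order of a Bismark genome-wide cytosine report (CX dialect).
CX_COLUMNS = ["chrom", "pos", "strand", "meth", "unmeth", "context", "tri"]


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval, optionally stranded ('.' = unstranded)."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class CytosineRecord:
    """One cytosine of a genome-wide cytosine report (1-based position)."""

    chrom: str
    pos: int
    strand: str
    context: str
    tri: str
    meth: int
    unmeth: int

    def __post_init__(self):
        if self.context not in VALID_CONTEXTS:
            raise ValueError(f"bad context {self.context!r}")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")
        if self.meth < 0 or self.unmeth < 0:
            raise ValueError("negative read count")


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    interval: GenomicInterval


@dataclass(frozen=True)
class RepeatElement:
    repeat_id: str
    interval: GenomicInterval


@dataclass(frozen=True)
class SnpRecord:
    """A variant with per-sample tetraploid alternative-allele dosage.

    ``dosage`` maps sample name to the number of alternative-allele copies
    (0-4), or ``None`` for a missing genotype.  ``n_alts`` retains the
    number of ALT alleles in the source record so that multi-allelic sites
    can be rejected by :func:`dmrdose.dosage.filter_snps` rather than
    silently dropped at parse time.
    """

    chrom: str
    pos: int  # 1-based, as in the VCF
    ref: str
    alt: str
    qual: float
    depth: Mapping[str, int]
    dosage: Mapping[str, int | None]
    n_alts: int = 1

    @property
    def is_biallelic_snp(self) -> bool:
        return (
            self.n_alts == 1
            and len(self.ref) == 1
            and len(self.alt) == 1
            and self.ref in "ACGT"
            and self.alt in "ACGT"
            and self.ref != self.alt
        )


@dataclass(frozen=True)
class DegRecord:
    gene_id: str
    log2fc: float
    fdr: float
    status: Literal["up", "down", "ns"]


# ---------------------------------------------------------------------------
# Cytosine reports
# ---------------------------------------------------------------------------

def read_cx_report(path: str | os.PathLike) -> pd.DataFrame:
    """Read a Bismark genome-wide cytosine report.

    Returns a DataFrame with :data:`CX_COLUMNS`; row order is preserved.
    Rows whose context is outside {CG, CHG, CHH} are rejected with a
    :class:`FormatError` naming the offending line, as are rows with a
    wrong column count or negative counts.
    """
    if os.path.getsize(path) == 0:
        return pd.DataFrame(
            {
                "chrom": pd.Series(dtype=str),
                "pos": pd.Series(dtype=np.int64),
                "strand": pd.Series(dtype=str),
                "meth": pd.Series(dtype=np.int64),
                "unmeth": pd.Series(dtype=np.int64),
                "context": pd.Series(dtype=str),
                "tri": pd.Series(dtype=str),
            }
        )
    try:
        frame = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=CX_COLUMNS,
            dtype={
                "chrom": str,
                "pos": np.int64,
                "strand": str,
                "meth": np.int64,
                "unmeth": np.int64,
                "context": str,
                "tri": str,
            },
        )
    except (ValueError, pd.errors.ParserError):
        _raise_at_bad_cx_line(path)
        raise  # unreachable; keeps type-checkers honest
    if frame.isna().any().any():
        _raise_at_bad_cx_line(path)
    bad_ctx = ~frame["context"].isin(VALID_CONTEXTS)
    if bad_ctx.any():
        line = int(np.flatnonzero(bad_ctx.to_numpy())[0]) + 1
        raise FormatError(
            f"{path}: line {line}: context "
            f"{frame['context'].iloc[line - 1]!r} not in {VALID_CONTEXTS}"
        )
    if (frame["meth"] < 0).any() or (frame["unmeth"] < 0).any():
        bad = (frame["meth"] < 0) | (frame["unmeth"] < 0)
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise FormatError(f"{path}: line {line}: negative read count")
    bad_strand = ~frame["strand"].isin(VALID_STRANDS)
    if bad_strand.any():
        line = int(np.flatnonzero(bad_strand.to_numpy())[0]) + 1
        raise FormatError(f"{path}: line {line}: bad strand")
    return frame


def _raise_at_bad_cx_line(path) -> None:
    """Locate the first malformed line of a cytosine report and raise."""
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 7:
                raise FormatError(
                    f"{path}: line {lineno}: expected 7 tab-separated "
                    f"columns, found {len(fields)}"
                )
            for col in (3, 4):
                try:
                    value = int(fields[col])
                except ValueError:
                    raise FormatError(
                        f"{path}: line {lineno}: non-integer count "
                        f"{fields[col]!r}"
                    ) from None
                if value < 0:
                    raise FormatError(
                        f"{path}: line {lineno}: negative read count"
                    )
    raise FormatError(f"{path}: malformed cytosine report")


def write_cx_report(records: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write records in the 7-column CX dialect (round-trips exactly)."""
    frame = records[CX_COLUMNS] if len(records) else records
    if len(frame) == 0:
        open(path, "w").close()
        return
    frame.to_csv(path, sep="\t", header=False, index=False)


def cx_to_records(frame: pd.DataFrame) -> list[CytosineRecord]:
    """Materialise a cytosine frame as validated dataclass records."""
    return [
        CytosineRecord(
            chrom=row.chrom,
            pos=int(row.pos),
            strand=row.strand,
            context=row.context,
            tri=row.tri,
            meth=int(row.meth),
            unmeth=int(row.unmeth),
        )
        for row in frame.itertuples(index=False)
    ]


def records_to_cx(records: Iterable[CytosineRecord]) -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in records]
    if not rows:
        return pd.DataFrame(columns=CX_COLUMNS)
    frame = pd.DataFrame(rows)
    return frame[CX_COLUMNS]


# ---------------------------------------------------------------------------
# Annotations (GFF3 / BED)
# ---------------------------------------------------------------------------

_GFF_COLUMNS = [
    "chrom", "source", "type", "start", "end",
    "score", "strand", "phase", "attributes",
]


def read_annotations(
    path: str | os.PathLike,
    kind: Literal["gene", "repeat"] = "gene",
    fmt: str | None = None,
    feature_types: Sequence[str] | None = None,
) -> list[GeneModel] | list[RepeatElement]:
    """Read gene or repeat annotations from GFF3 (1-based inclusive) or
    BED (0-based half-open) into the internal 0-based half-open convention.

    ``fmt`` may be 'gff3' or 'bed'; by default it is inferred from the file
    extension.  For GFF3, only rows whose feature type is in
    ``feature_types`` are kept (default: ``gene`` for genes, any of
    ``repeat_region``/``match``/``transposable_element`` for repeats).
    """
    fmt = fmt or _infer_annotation_format(path)
    if fmt == "gff3":
        features = _read_gff3(path, kind, feature_types)
    elif fmt == "bed":
        features = _read_bed(path, kind)
    else:
        raise FormatError(f"unknown annotation format {fmt!r}")
    ids = [f.gene_id if kind == "gene" else f.repeat_id for f in features]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise FormatError(f"{path}: duplicate feature ids {dupes[:5]}")
    return features


def _infer_annotation_format(path) -> str:
    name = str(path).lower()
    if name.endswith((".gff", ".gff3")):
        return "gff3"
    if name.endswith(".bed"):
        return "bed"
    raise FormatError(f"cannot infer annotation format from {path!r}")


def _attr_id(attributes: str, fallback: str) -> str:
    for part in attributes.split(";"):
        key, _, value = part.strip().partition("=")
        if key in ("ID", "Name"):
            return value
    return fallback


def _read_gff3(path, kind, feature_types):
    if feature_types is None:
        feature_types = (
            ("gene",)
            if kind == "gene"
            else ("repeat_region", "match", "transposable_element", "repeat")
        )
    frame = pd.read_csv(
        path, sep="\t", header=None, names=_GFF_COLUMNS, comment="#",
        dtype={"chrom": str, "attributes": str},
    )
    frame = frame[frame["type"].isin(feature_types)]
    out = []
    for i, row in enumerate(frame.itertuples(index=False)):
        interval = GenomicInterval(
            chrom=row.chrom,
            start=int(row.start) - 1,  # GFF3 is 1-based inclusive
            end=int(row.end),
            strand=row.strand if row.strand in VALID_STRANDS else ".",
        )
        name = _attr_id(str(row.attributes), f"{kind}_{i}")
        out.append(
            GeneModel(name, interval) if kind == "gene"
            else RepeatElement(name, interval)
        )
    return out


def _read_bed(path, kind):
    frame = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"][:6],
        dtype={"chrom": str},
    )
    out = []
    for i, row in enumerate(frame.itertuples(index=False)):
        strand = getattr(row, "strand", ".")
        name = getattr(row, "name", None)
        if name is None or (isinstance(name, float) and np.isnan(name)):
            name = f"{kind}_{i}"
        interval = GenomicInterval(
            chrom=row.chrom,
            start=int(row.start),
            end=int(row.end),
            strand=strand if strand in VALID_STRANDS else ".",
        )
        out.append(
            GeneModel(str(name), interval) if kind == "gene"
            else RepeatElement(str(name), interval)
        )
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as handle:
        for iv in intervals:
            handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# VCF with tetraploid genotypes
# ---------------------------------------------------------------------------

def read_vcf_tetraploid(
    path: str | os.PathLike,
    sample_names: Sequence[str] | None = None,
) -> list[SnpRecord]:
    """Read a VCF carrying tetraploid GT fields (e.g. ``0/0/1/1``).

    Dosage is the count of alternative-allele indices in the genotype.
    Missing genotypes (``./././.``) are carried as dosage ``None`` rather
    than dropped; a genotype with arity other than four raises.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if sample_names is not None:
        missing = set(sample_names) - set(samples)
        if missing:
            raise FormatError(f"{path}: samples not in VCF: {sorted(missing)}")
        keep = [samples.index(s) for s in sample_names]
        names = list(sample_names)
    else:
        keep = list(range(len(samples)))
        names = samples
    records: list[SnpRecord] = []
    for var in vcf:
        depths_raw = var.format("DP")
        dosage: dict[str, int | None] = {}
        depth: dict[str, int] = {}
        for out_name, idx in zip(names, keep):
            gt = var.genotypes[idx][:-1]  # trailing element is phasing flag
            if all(allele == -1 for allele in gt):
                dosage[out_name] = None
            else:
                if len(gt) != 4:
                    raise FormatError(
                        f"{path}: {var.CHROM}:{var.POS} sample {out_name}: "
                        f"expected tetraploid genotype, got ploidy {len(gt)}"
                    )
                if any(allele == -1 for allele in gt):
                    dosage[out_name] = None  # partially missing: treat missing
                else:
                    dosage[out_name] = sum(1 for a in gt if a > 0)
            depth[out_name] = (
                int(depths_raw[idx][0]) if depths_raw is not None else 0
            )
        alts = var.ALT or []
        records.append(
            SnpRecord(
                chrom=var.CHROM,
                pos=var.POS,
                ref=var.REF,
                alt=alts[0] if alts else "",
                qual=float(var.QUAL) if var.QUAL is not None else float("nan"),
                depth=depth,
                dosage=dosage,
                n_alts=len(alts),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Differential-expression table
# ---------------------------------------------------------------------------

def read_de_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a DE results table (TSV or CSV) with columns
    gene_id, log2fc, fdr; the up/down/ns status column is recomputed from
    the thresholds (FDR < 0.05 and |log2FC| > 1, strict)."""
    from .association import classify_deg

    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    frame = pd.read_csv(path, sep=sep)
    required = {"gene_id", "log2fc", "fdr"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    frame = frame.copy()
    frame["status"] = [
        classify_deg(fc, fdr)
        for fc, fdr in zip(frame["log2fc"], frame["fdr"])
    ]
    return frame


def de_records(frame: pd.DataFrame) -> list[DegRecord]:
    return [
        DegRecord(row.gene_id, float(row.log2fc), float(row.fdr), row.status)
        for row in frame.itertuples(index=False)
    ]
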