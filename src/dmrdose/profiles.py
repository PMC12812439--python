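"""Weighted methylation levels, genome bins, and metagene profiles.

The methylation level of a set of cytosines is always the *weighted*
(read-count) level

    wml = sum(meth) / sum(meth + unmeth),

never a mean of per-site proportions, so deeply covered sites contribute
proportionally to their evidence.  A set with zero total reads has an
undefined level, reported as NaN.

Symmetric CG sites on opposite strands are deliberately not pooled: a
cytosine report lists both strands and each strand's cytosine enters the
sums as its own record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GeneModel, RepeatElement, VALID_CONTEXTS


def weighted_methylation_level(records: pd.DataFrame) -> float:
    """Coverage-weighted methylation level of a cytosine set (NaN if the
    set has no reads)."""
    total = int(records["meth"].sum() + records["unmeth"].sum())
    if total == 0:
        return float("nan")
    return float(records["meth"].sum()) / total


def bin_methylation(
    records: pd.DataFrame,
    bin_size: int = 200,
    context: str | None = None,
) -> pd.DataFrame:
    """Tile each chromosome into half-open ``[k*s, (k+1)*s)`` bins and
    compute the weighted methylation level per bin.

    Cytosines are assigned by their 0-based position (``pos - 1``).  Bins
    with no covered cytosine have ``wml`` NaN.  Returns one row per bin
    from 0 to the last occupied bin of each chromosome, with columns
    chrom, start, end, context, n_cytosines, total_reads, meth_reads, wml.
    """
    if bin_size < 1:
        raise ValueError(f"bin_size must be >= 1, got {bin_size}")
    if context is not None:
        records = records[records["context"] == context]
    out_frames = []
    for chrom, sub in records.groupby("chrom", sort=True):
        pos0 = sub["pos"].to_numpy() - 1
        idx = pos0 // bin_size
        n_bins = int(idx.max()) + 1 if len(idx) else 0
        meth = np.bincount(idx, weights=sub["meth"], minlength=n_bins)
        unmeth = np.bincount(idx, weights=sub["unmeth"], minlength=n_bins)
        ncyt = np.bincount(idx, minlength=n_bins)
        total = meth + unmeth
        with np.errstate(invalid="ignore", divide="ignore"):
            wml = np.where(total > 0, meth / np.where(total > 0, total, 1), np.nan)
        starts = np.arange(n_bins) * bin_size
        out_frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + bin_size,
                    "context": context if context is not None else "all",
                    "n_cytosines": ncyt.astype(int),
                    "total_reads": total.astype(int),
                    "meth_reads": meth.astype(int),
                    "wml": wml,
                }
            )
        )
    if not out_frames:
        return pd.DataFrame(
            columns=[
                "chrom", "start", "end", "context",
                "n_cytosines", "total_reads", "meth_reads", "wml",
            ]
        )
    return pd.concat(out_frames, ignore_index=True)


def chromosome_density(
    records: pd.DataFrame,
    window: int = 500_000,
    context: str | None = None,
) -> pd.DataFrame:
    """Chromosome-scale methylation density (large-window binning)."""
    return bin_methylation(records, bin_size=window, context=context)


@dataclass
class MetageneProfile:
    """Pooled methylation profile over flank / body / flank segments.

    Per-bin read counts are pooled across all features first and converted
    to weighted levels at the end, so the profile is a weighted level of
    the pooled cytosines, not a mean of per-feature profiles.
    """

    context: str
    upstream: np.ndarray
    body: np.ndarray
    downstream: np.ndarray
    flank_bp: int = 2000
    n_features: int = 0

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([self.upstream, self.body, self.downstream])


def metagene_profile(
    records: pd.DataFrame,
    features: list[GeneModel] | list[RepeatElement],
    flank_bp: int = 2000,
    n_flank_bins: int = 100,
    n_body_bins: int = 100,
    context: str | None = None,
) -> MetageneProfile:
    """Metagene methylation profile around a feature set.

    For each feature the upstream flank (5' of the feature) is split into
    ``n_flank_bins`` equal bins, the body is rescaled to ``n_body_bins``
    by proportional assignment (``floor(rel_pos * n_body_bins)``), and the
    downstream flank likewise.  Minus-strand features are reversed so bin 0
    is always 5'; unstranded features are treated as plus-strand.
    """
    if not features:
        raise ValueError("features must be non-empty")
    if context is not None:
        records = records[records["context"] == context]
    n_total = n_flank_bins * 2 + n_body_bins
    meth = np.zeros(n_total)
    total = np.zeros(n_total)

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, sub in records.groupby("chrom"):
        order = np.argsort(sub["pos"].to_numpy(), kind="stable")
        pos0 = sub["pos"].to_numpy()[order] - 1
        by_chrom[chrom] = (
            pos0,
            sub["meth"].to_numpy()[order].astype(float),
            (sub["meth"].to_numpy() + sub["unmeth"].to_numpy())[order].astype(float),
        )

    for feature in features:
        iv = feature.interval
        if iv.chrom not in by_chrom:
            continue
        pos0, m, t = by_chrom[iv.chrom]
        lo = np.searchsorted(pos0, iv.start - flank_bp, side="left")
        hi = np.searchsorted(pos0, iv.end + flank_bp, side="left")
        sel = slice(lo, hi)
        p, mm, tt = pos0[sel], m[sel], t[sel]
        bins = np.empty(len(p), dtype=np.int64)
        body_len = iv.end - iv.start
        up = p < iv.start
        down = p >= iv.end
        body = ~(up | down)
        # flank bins: equal width flank_bp / n_flank_bins
        bins[up] = ((p[up] - (iv.start - flank_bp)) * n_flank_bins) // flank_bp
        bins[body] = n_flank_bins + (
            (p[body] - iv.start) * n_body_bins
        ) // body_len
        bins[down] = (
            n_flank_bins
            + n_body_bins
            + ((p[down] - iv.end) * n_flank_bins) // flank_bp
        )
        if iv.strand == "-":
            bins = n_total - 1 - bins
        np.add.at(meth, bins, mm)
        np.add.at(total, bins, tt)

    with np.errstate(invalid="ignore", divide="ignore"):
        wml = np.where(total > 0, meth / np.where(total > 0, total, 1), np.nan)
    return MetageneProfile(
        context=context if context is not None else "all",
        upstream=wml[:n_flank_bins],
        body=wml[n_flank_bins : n_flank_bins + n_body_bins],
        downstream=wml[n_flank_bins + n_body_bins :],
        flank_bp=flank_bp,
        n_features=len(features),
    )


def methylation_distribution(
    bins: pd.DataFrame,
    n_hist_bins: int = 50,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Histogram of defined per-bin weighted levels.

    Returns ``(counts, edges, n_undefined)``; undefined bins (no reads)
    are excluded from the histogram and reported separately.
    """
    wml = bins["wml"].to_numpy(dtype=float)
    defined = wml[~np.isnan(wml)]
    counts, edges = np.histogram(defined, bins=n_hist_bins, range=(0.0, 1.0))
    return counts, edges, int(np.isnan(wml).sum())
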