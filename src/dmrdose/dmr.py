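"""Context-specific differentially methylated region (DMR) calling.

Two groups of bisulfite samples (e.g. two cultivars, or one cultivar
before and after a stress) are compared per cytosine context with the
noise-filter strategy:

1.  replicate counts are pooled per position and strand;
2.  methylated and total counts are smoothed along the chromosome with a
    truncated Gaussian kernel, giving a noise-filtered methylation
    proportion at every cytosine;
3.  maximal runs of cytosines whose smoothed proportion difference
    exceeds the context's minimum difference become candidate regions;
4.  each candidate is tested with a two-sided Fisher's exact test on the
    pooled 2x2 count table, and p-values are Benjamini-Hochberg adjusted
    across all candidates of the context;
5.  candidates are filtered on FDR, span, mean coverage per cytosine,
    pooled proportion difference and cytosine count;
6.  surviving same-direction regions closer than the merge gap are fused
    and their statistics recomputed from the pooled counts.

Context-specific defaults follow common plant WGBS practice: minimum span
50/50/25 bp and minimum proportion difference 0.40/0.30/0.10 for
CG/CHG/CHH, FDR < 0.05, mean coverage >= 8 reads per cytosine, and a
200 bp merge gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .io import GenomicInterval

DEFAULT_MIN_SIZE_BP = {"CG": 50, "CHG": 50, "CHH": 25}
DEFAULT_MIN_PROP_DIFF = {"CG": 0.40, "CHG": 0.30, "CHH": 0.10}


@dataclass
class DmrParams:
    """Thresholds and kernel settings for one context's DMR call.

    ``kernel_window_bp`` is the full width of the Gaussian smoothing
    window; the kernel's standard deviation is ``kernel_window_bp / 6`` so
    that the 3-sigma truncation coincides with the half-window.  The
    default window of 50 bp keeps the kernel half-support (25 bp) at the
    smallest minimum DMR span, so a minimum-size CHH region at its
    detection threshold is not diluted below that threshold by mass
    borrowed from its unchanged flanks.
    """

    context: str = "CG"
    min_size_bp: int = 50
    min_prop_diff: float = 0.40
    min_coverage_per_cytosine: float = 8.0
    fdr_threshold: float = 0.05
    kernel_window_bp: float = 50.0
    min_cytosines: int = 4
    merge_gap_bp: int = 200

    def __post_init__(self):
        if self.context not in DEFAULT_MIN_SIZE_BP:
            raise ValueError(f"unknown context {self.context!r}")
        if not (0 < self.fdr_threshold < 1):
            raise ValueError("fdr_threshold must be in (0, 1)")
        if min(
            self.min_size_bp,
            self.min_prop_diff,
            self.min_coverage_per_cytosine,
            self.kernel_window_bp,
        ) <= 0:
            raise ValueError("thresholds must be positive")

    @property
    def bandwidth_bp(self) -> float:
        """Gaussian sigma implied by the kernel window."""
        return self.kernel_window_bp / 6.0

    @classmethod
    def for_context(cls, context: str, **overrides) -> "DmrParams":
        """Context-specific defaults (span 50/50/25 bp and difference
        0.40/0.30/0.10 for CG/CHG/CHH)."""
        base = dict(
            context=context,
            min_size_bp=DEFAULT_MIN_SIZE_BP[context],
            min_prop_diff=DEFAULT_MIN_PROP_DIFF[context],
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class Dmr:
    """A differentially methylated interval with its pooled statistics.

    ``direction`` is 'hyper' when the comparison group is more methylated
    than the reference group over the region, 'hypo' otherwise;
    ``prop_diff`` is the pooled comparison-minus-reference proportion
    difference.  Pooled counts are retained so that merged regions can be
    re-tested.
    """

    interval: GenomicInterval
    context: str
    direction: str  # 'hyper' | 'hypo'
    n_cytosines: int
    mean_coverage: float
    prop_diff: float
    p_value: float
    q_value: float
    meth_ref: int = 0
    unmeth_ref: int = 0
    meth_cmp: int = 0
    unmeth_cmp: int = 0

    @property
    def table(self) -> list[list[int]]:
        return [[self.meth_cmp, self.unmeth_cmp],
                [self.meth_ref, self.unmeth_ref]]


# ---------------------------------------------------------------------------
# Stage 1: replicate pooling
# ---------------------------------------------------------------------------

def pool_replicates(tracks: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Sum methylated/unmethylated counts across replicate cytosine
    frames per (chrom, pos, strand).

    All replicates must agree on the context annotated at a position;
    conflicting annotations raise ``ValueError``.
    """
    if not tracks:
        raise ValueError("no replicate tracks given")
    merged = pd.concat(tracks, ignore_index=True)
    grouped = merged.groupby(["chrom", "pos", "strand"], sort=True)
    contexts = grouped["context"].nunique()
    if (contexts > 1).any():
        bad = contexts[contexts > 1].index[0]
        raise ValueError(
            f"conflicting context annotations at {bad[0]}:{bad[1]} ({bad[2]})"
        )
    pooled = grouped.agg(
        meth=("meth", "sum"),
        unmeth=("unmeth", "sum"),
        context=("context", "first"),
        tri=("tri", "first"),
    ).reset_index()
    return pooled[["chrom", "pos", "strand", "meth", "unmeth", "context", "tri"]]


# ---------------------------------------------------------------------------
# Stage 2: kernel smoothing
# ---------------------------------------------------------------------------

def smooth_proportions(
    positions: np.ndarray,
    meth: np.ndarray,
    total: np.ndarray,
    bandwidth_bp: float,
) -> np.ndarray:
    """Gaussian-kernel smoothed methylation proportion at each cytosine.

    At position x the estimate is
    ``sum_i K((x - x_i)/h) * meth_i / sum_i K((x - x_i)/h) * total_i``
    with a Gaussian kernel of standard deviation ``bandwidth_bp``
    truncated at three sigma; positions with zero smoothed total are NaN.
    ``positions`` must be strictly increasing integers.

    Implemented by scattering counts on a dense per-bp grid and running a
    C-level Gaussian filter over it, which is algebraically identical to
    the per-pair kernel sum (kernel normalisation cancels in the ratio).
    """
    positions = np.asarray(positions, dtype=np.int64)
    if len(positions) == 0:
        return np.empty(0)
    offset, num_grid, den_grid = _smooth_grids(
        positions, meth, total, bandwidth_bp
    )
    shifted = positions - offset
    return _safe_ratio(num_grid[shifted], den_grid[shifted])


def _smooth_grids(positions, meth, total, bandwidth_bp):
    """Kernel-weighted count sums on the dense per-bp grid spanning the
    positions; returns (grid offset, smoothed meth, smoothed total)."""
    if bandwidth_bp <= 0:
        raise ValueError(f"bandwidth_bp must be positive, got {bandwidth_bp}")
    if np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing")
    offset = int(positions[0])
    shifted = positions - offset
    length = int(shifted[-1]) + 1
    meth_grid = np.bincount(shifted, weights=meth, minlength=length)
    total_grid = np.bincount(shifted, weights=total, minlength=length)
    meth_smooth = gaussian_filter1d(
        meth_grid, bandwidth_bp, truncate=3.0, mode="constant"
    )
    total_smooth = gaussian_filter1d(
        total_grid, bandwidth_bp, truncate=3.0, mode="constant"
    )
    return offset, meth_smooth, total_smooth


def _safe_ratio(num, den):
    out = np.full(len(num), np.nan)
    # guard against float dust from the filter on all-zero neighbourhoods
    ok = den > 1e-12
    out[ok] = num[ok] / den[ok]
    return out


# ---------------------------------------------------------------------------
# Stage 3: candidate discovery
# ---------------------------------------------------------------------------

def candidate_regions(
    positions: np.ndarray,
    smoothed_ref: np.ndarray,
    smoothed_cmp: np.ndarray,
    min_prop_diff: float,
) -> list[tuple[int, int, int]]:
    """Maximal runs of consecutive cytosines whose smoothed difference
    (cmp - ref) is >= +threshold (hyper, sign +1) or <= -threshold (hypo,
    sign -1).

    Returns ``(first_index, last_index, sign)`` tuples over ``positions``;
    the genomic interval of a run spans ``positions[first]`` to
    ``positions[last] + 1`` (half-open).  NaNs break runs.
    """
    diff = np.asarray(smoothed_cmp, dtype=float) - np.asarray(
        smoothed_ref, dtype=float
    )
    state = np.zeros(len(diff), dtype=np.int8)
    with np.errstate(invalid="ignore"):
        state[diff >= min_prop_diff] = 1
        state[diff <= -min_prop_diff] = -1
    if len(state) == 0:
        return []
    boundaries = np.flatnonzero(np.diff(state)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [len(state)]])
    return [
        (int(s), int(e) - 1, int(state[s]))
        for s, e in zip(starts, ends)
        if state[s] != 0
    ]


# ---------------------------------------------------------------------------
# Stage 4: testing and FDR
# ---------------------------------------------------------------------------

def test_region(
    meth_cmp: int, unmeth_cmp: int, meth_ref: int, unmeth_ref: int
) -> float:
    """Two-sided Fisher's exact test on the pooled region count table
    ``[[meth_cmp, unmeth_cmp], [meth_ref, unmeth_ref]]`` (p = 1 for an
    all-zero table)."""
    table = [[meth_cmp, unmeth_cmp], [meth_ref, unmeth_ref]]
    if sum(map(sum, table)) == 0:
        return 1.0
    return float(fisher_exact(table, alternative="two-sided")[1])


def adjust_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return np.empty(0)
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Stages 5-6: filtering and merging
# ---------------------------------------------------------------------------

def filter_dmrs(candidates: Iterable[Dmr], params: DmrParams) -> list[Dmr]:
    """Keep candidates with q below the FDR threshold, span at least the
    context's minimum size, mean coverage per cytosine (both groups
    pooled) at least the minimum, absolute pooled proportion difference at
    least the context threshold (inclusive), and enough cytosines."""
    kept = []
    for dmr in candidates:
        if dmr.q_value >= params.fdr_threshold:
            continue
        if len(dmr.interval) < params.min_size_bp:
            continue
        if dmr.mean_coverage < params.min_coverage_per_cytosine:
            continue
        if abs(dmr.prop_diff) < params.min_prop_diff - 1e-12:
            continue
        if dmr.n_cytosines < params.min_cytosines:
            continue
        kept.append(dmr)
    return kept


def merge_dmrs(dmrs: Sequence[Dmr], merge_gap_bp: int = 200) -> list[Dmr]:
    """Fuse same-chromosome, same-context, same-direction DMRs whose gap
    is below ``merge_gap_bp``; counts are pooled, the Fisher test is
    recomputed on the pooled table and q-values re-adjusted across the
    merged set."""
    ordered = sorted(
        dmrs, key=lambda d: (d.interval.chrom, d.interval.start, d.interval.end)
    )
    merged: list[Dmr] = []
    for dmr in ordered:
        if merged:
            prev = merged[-1]
            same = (
                prev.interval.chrom == dmr.interval.chrom
                and prev.context == dmr.context
                and prev.direction == dmr.direction
            )
            if same and dmr.interval.start - prev.interval.end < merge_gap_bp:
                merged[-1] = _fuse(prev, dmr)
                continue
        merged.append(replace(dmr))
    if merged:
        q = adjust_fdr([d.p_value for d in merged])
        for dmr, qv in zip(merged, q):
            dmr.q_value = float(qv)
    return merged


def _fuse(a: Dmr, b: Dmr) -> Dmr:
    meth_ref = a.meth_ref + b.meth_ref
    unmeth_ref = a.unmeth_ref + b.unmeth_ref
    meth_cmp = a.meth_cmp + b.meth_cmp
    unmeth_cmp = a.unmeth_cmp + b.unmeth_cmp
    n_cyt = a.n_cytosines + b.n_cytosines
    total = meth_ref + unmeth_ref + meth_cmp + unmeth_cmp
    ref_total = meth_ref + unmeth_ref
    cmp_total = meth_cmp + unmeth_cmp
    prop_diff = (meth_cmp / cmp_total if cmp_total else 0.0) - (
        meth_ref / ref_total if ref_total else 0.0
    )
    interval = GenomicInterval(
        a.interval.chrom,
        min(a.interval.start, b.interval.start),
        max(a.interval.end, b.interval.end),
        ".",
    )
    return Dmr(
        interval=interval,
        context=a.context,
        direction=a.direction,
        n_cytosines=n_cyt,
        mean_coverage=total / (n_cyt * 2) if n_cyt else 0.0,
        prop_diff=prop_diff,
        p_value=test_region(meth_cmp, unmeth_cmp, meth_ref, unmeth_ref),
        q_value=float("nan"),  # re-adjusted by merge_dmrs
        meth_ref=meth_ref,
        unmeth_ref=unmeth_ref,
        meth_cmp=meth_cmp,
        unmeth_cmp=unmeth_cmp,
    )


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------

def call_dmrs(
    group_ref: Sequence[pd.DataFrame],
    group_cmp: Sequence[pd.DataFrame],
    context: str,
    params: DmrParams | None = None,
) -> list[Dmr]:
    """Call DMRs of one context between a reference and a comparison
    group of replicate cytosine frames.

    Pipeline: pool replicates -> smooth proportions -> candidate runs ->
    Fisher test per candidate -> BH across all candidates of the context
    -> threshold filters -> gap merging.  Deterministic given inputs.
    """
    if params is None:
        params = DmrParams.for_context(context)
    if params.context != context:
        raise ValueError("params.context does not match context argument")
    # restrict to the context up front: pooling is the hot path
    pooled_ref = pool_replicates(
        [f[f["context"] == context] for f in group_ref]
    )
    pooled_cmp = pool_replicates(
        [f[f["context"] == context] for f in group_cmp]
    )

    candidates: list[Dmr] = []
    chroms = sorted(
        set(pooled_ref["chrom"]).union(pooled_cmp["chrom"])
    )
    for chrom in chroms:
        ref = pooled_ref[pooled_ref["chrom"] == chrom]
        cmp_ = pooled_cmp[pooled_cmp["chrom"] == chrom]
        candidates.extend(
            _chrom_candidates(chrom, ref, cmp_, context, params)
        )
    if not candidates:
        return []
    q = adjust_fdr([d.p_value for d in candidates])
    for dmr, qv in zip(candidates, q):
        dmr.q_value = float(qv)
    kept = filter_dmrs(candidates, params)
    return merge_dmrs(kept, params.merge_gap_bp)


def _chrom_candidates(chrom, ref, cmp_, context, params) -> list[Dmr]:
    """Candidate regions with pooled statistics on one chromosome.

    The smoothed proportion curves of both groups are evaluated on the
    dense per-bp grid spanning the covered cytosines, and candidates are
    maximal bp runs where the curve difference stays beyond the
    threshold.  A candidate's span is therefore the extent of the
    signal on the curve, not the (sparser) first-to-last cytosine
    distance, matching the size semantics of the noise-filter method.
    Runs without at least one covered cytosine in each group are dropped.
    """
    # union of cytosine positions seen in either group; per-strand records
    # at distinct positions stay distinct, same-position counts are summed
    ref_counts = _position_counts(ref)
    cmp_counts = _position_counts(cmp_)
    positions = np.union1d(
        ref_counts.index.to_numpy(), cmp_counts.index.to_numpy()
    )
    if len(positions) == 0:
        return []
    ref_m, ref_t = _aligned(ref_counts, positions)
    cmp_m, cmp_t = _aligned(cmp_counts, positions)
    offset, ref_num, ref_den = _smooth_grids(
        positions, ref_m, ref_t, params.bandwidth_bp
    )
    _, cmp_num, cmp_den = _smooth_grids(
        positions, cmp_m, cmp_t, params.bandwidth_bp
    )
    curve_ref = _safe_ratio(ref_num, ref_den)
    curve_cmp = _safe_ratio(cmp_num, cmp_den)
    grid = np.arange(offset, offset + len(curve_ref))
    runs = candidate_regions(grid, curve_ref, curve_cmp, params.min_prop_diff)
    out = []
    for first, last, sign in runs:
        start = offset + first
        end = offset + last + 1  # half-open
        lo = int(np.searchsorted(positions, start, side="left"))
        hi = int(np.searchsorted(positions, end, side="left"))
        if hi <= lo:
            continue
        sl = slice(lo, hi)
        meth_ref = int(ref_m[sl].sum())
        total_ref = int(ref_t[sl].sum())
        meth_cmp = int(cmp_m[sl].sum())
        total_cmp = int(cmp_t[sl].sum())
        if total_ref == 0 or total_cmp == 0:
            continue
        n_cyt = hi - lo
        prop_diff = meth_cmp / total_cmp - meth_ref / total_ref
        out.append(
            Dmr(
                interval=GenomicInterval(chrom, start, end, "."),
                context=context,
                direction="hyper" if sign > 0 else "hypo",
                n_cytosines=n_cyt,
                mean_coverage=(total_ref + total_cmp) / (n_cyt * 2),
                prop_diff=prop_diff,
                p_value=test_region(
                    meth_cmp, total_cmp - meth_cmp, meth_ref, total_ref - meth_ref
                ),
                q_value=float("nan"),
                meth_ref=meth_ref,
                unmeth_ref=total_ref - meth_ref,
                meth_cmp=meth_cmp,
                unmeth_cmp=total_cmp - meth_cmp,
            )
        )
    return out


def _position_counts(frame: pd.DataFrame) -> pd.DataFrame:
    """Counts summed per 0-based position (strands at distinct positions)."""
    if len(frame) == 0:
        return pd.DataFrame(
            {"meth": pd.Series(dtype=float), "total": pd.Series(dtype=float)}
        )
    pos0 = frame["pos"] - 1
    grouped = frame.assign(pos0=pos0).groupby("pos0")
    out = grouped.agg(meth=("meth", "sum"))
    out["total"] = grouped["meth"].sum() + grouped["unmeth"].sum()
    return out


def _aligned(counts: pd.DataFrame, positions: np.ndarray):
    meth = np.zeros(len(positions))
    total = np.zeros(len(positions))
    if len(counts):
        idx = np.searchsorted(positions, counts.index.to_numpy())
        meth[idx] = counts["meth"].to_numpy()
        total[idx] = counts["total"].to_numpy()
    return meth, total


def dmrs_to_frame(dmrs: Sequence[Dmr]) -> pd.DataFrame:
    """Tabular view of a DMR list (one row per DMR, full statistics)."""
    return pd.DataFrame(
        [
            {
                "chrom": d.interval.chrom,
                "start": d.interval.start,
                "end": d.interval.end,
                "context": d.context,
                "direction": d.direction,
                "n_cytosines": d.n_cytosines,
                "mean_coverage": d.mean_coverage,
                "prop_diff": d.prop_diff,
                "p_value": d.p_value,
                "q_value": d.q_value,
            }
            for d in dmrs
        ],
        columns=[
            "chrom", "start", "end", "context", "direction", "n_cytosines",
            "mean_coverage", "prop_diff", "p_value", "q_value",
        ],
    )


def dmrs_to_bed(dmrs: Sequence[Dmr], path) -> None:
    """Write DMRs as BED6+ (name = context:direction, score = -log10 q)."""
    with open(path, "w") as handle:
        for d in dmrs:
            score = -np.log10(d.q_value) if d.q_value > 0 else 999.0
            handle.write(
                f"{d.interval.chrom}\t{d.interval.start}\t{d.interval.end}\t"
                f"{d.context}:{d.direction}\t{score:.3f}\t.\n"
            )
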