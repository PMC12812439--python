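"""DMR calling stages against independent oracles: replicate pooling,
kernel smoothing, candidate runs, Fisher testing, BH adjustment,
filtering, merging, and the full chain on data with planted truth."""

import math

import numpy as np
import pandas as pd
import pytest

from dmrdose.dmr import (
    Dmr,
    DmrParams,
    adjust_fdr,
    call_dmrs,
    candidate_regions,
    filter_dmrs,
    merge_dmrs,
    pool_replicates,
    smooth_proportions,
    test_region as region_p_value,
)
from dmrdose.io import GenomicInterval

from conftest import make_cx


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def fisher_two_sided_exact(a, b, c, d):
    """Full hypergeometric enumeration with integer arithmetic: sum the
    probabilities of all tables (fixed margins) no more likely than the
    observed one."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    observed = math.comb(r1, a) * math.comb(r2, c1 - a)
    num = 0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        weight = math.comb(r1, k) * math.comb(r2, c1 - k)
        if weight <= observed:
            num += weight
    return num / math.comb(n, c1)


def bh_step_up(p):
    """Independent Benjamini-Hochberg: sort, scale by m/rank, cumulative
    minimum from the largest p down, clip at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def smooth_double_loop(positions, meth, total, h):
    radius = int(3 * h + 0.5)
    out = np.full(len(positions), np.nan)
    for j, x in enumerate(positions):
        num = den = 0.0
        for i, xi in enumerate(positions):
            d = x - xi
            if abs(d) <= radius:
                w = math.exp(-(d * d) / (2 * h * h))
                num += w * meth[i]
                den += w * total[i]
        if den > 1e-12:
            out[j] = num / den
    return out


def scan_runs(state):
    """Exhaustive maximal-run scanner over a -1/0/+1 state sequence."""
    runs = []
    i = 0
    while i < len(state):
        if state[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < len(state) and state[j + 1] == state[i]:
            j += 1
        runs.append((i, j, int(state[i])))
        i = j + 1
    return runs


# ---------------------------------------------------------------------------
# Replicate pooling
# ---------------------------------------------------------------------------

def test_pooling_single_replicate_is_identity():
    rep = make_cx([("chr1", 5, "+", 1, 2, "CG"), ("chr1", 9, "-", 0, 4, "CHH")])
    pooled = pool_replicates([rep])
    pd.testing.assert_frame_equal(pooled, rep)


def test_pooling_sums_counts_per_position():
    rep1 = make_cx([("chr1", 5, "+", 1, 1, "CG")])
    rep2 = make_cx([("chr1", 5, "+", 2, 0, "CG")])
    pooled = pool_replicates([rep1, rep2])
    assert (pooled["meth"].iloc[0], pooled["unmeth"].iloc[0]) == (3, 1)


def test_pooling_matches_brute_force_sum():
    rng = np.random.default_rng(7)
    reps = []
    positions = sorted(rng.choice(np.arange(1, 500), 40, replace=False))
    for _ in range(3):
        keep = rng.random(40) < 0.8
        reps.append(
            make_cx(
                [
                    ("chr1", int(p), "+", int(rng.integers(10)), int(rng.integers(10)), "CHG")
                    for p, k in zip(positions, keep)
                    if k
                ]
            )
        )
    pooled = pool_replicates(reps)
    for row in pooled.itertuples(index=False):
        manual_m = sum(
            int(r.loc[r["pos"] == row.pos, "meth"].sum()) for r in reps
        )
        manual_u = sum(
            int(r.loc[r["pos"] == row.pos, "unmeth"].sum()) for r in reps
        )
        assert (row.meth, row.unmeth) == (manual_m, manual_u)


def test_pooling_rejects_conflicting_contexts():
    rep1 = make_cx([("chr1", 5, "+", 1, 1, "CG")])
    rep2 = make_cx([("chr1", 5, "+", 1, 1, "CHH")])
    with pytest.raises(ValueError, match="context"):
        pool_replicates([rep1, rep2])


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------

def test_smoothing_single_cytosine_kernel_cancels():
    out = smooth_proportions(np.array([100]), np.array([4.0]), np.array([8.0]), 10.0)
    assert out[0] == pytest.approx(0.5)


def test_smoothing_equidistant_neighbours_pool_equally():
    # midpoint evaluated via a zero-coverage cytosine between two sites
    positions = np.array([0, 10, 20])
    meth = np.array([4.0, 0.0, 8.0])
    total = np.array([8.0, 0.0, 8.0])
    out = smooth_proportions(positions, meth, total, 50.0)
    assert out[1] == pytest.approx(12 / 16, abs=1e-9)


def test_smoothing_matches_double_loop_oracle():
    rng = np.random.default_rng(8)
    for trial in range(10):
        positions = np.sort(rng.choice(np.arange(2_000), 30, replace=False))
        total = rng.poisson(20, 30).astype(float)
        meth = rng.binomial(total.astype(int), rng.random(30)).astype(float)
        h = float(rng.uniform(3, 40))
        ours = smooth_proportions(positions, meth, total, h)
        oracle = smooth_double_loop(positions, meth, total, h)
        np.testing.assert_allclose(ours, oracle, atol=1e-10)


def test_smoothing_rejects_bad_inputs():
    with pytest.raises(ValueError, match="bandwidth"):
        smooth_proportions(np.array([1]), np.array([1.0]), np.array([1.0]), 0.0)
    with pytest.raises(ValueError, match="increasing"):
        smooth_proportions(
            np.array([5, 5]), np.array([1.0, 1.0]), np.array([1.0, 1.0]), 10.0
        )


def test_smoothing_undefined_without_coverage():
    positions = np.array([0, 1000])
    out = smooth_proportions(
        positions, np.array([0.0, 3.0]), np.array([0.0, 6.0]), 5.0
    )
    assert np.isnan(out[0]) and out[1] == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# Candidate regions
# ---------------------------------------------------------------------------

def test_no_candidates_for_equal_tracks():
    ref = np.full(20, 0.4)
    assert candidate_regions(np.arange(20), ref, ref.copy(), 0.1) == []


def test_single_hyper_run():
    ref = np.zeros(5)
    cmp_ = np.full(5, 0.5)
    runs = candidate_regions(np.arange(5), ref, cmp_, 0.4)
    assert runs == [(0, 4, 1)]


def test_candidate_runs_match_exhaustive_scanner():
    rng = np.random.default_rng(9)
    for _ in range(20):
        n = int(rng.integers(1, 80))
        ref = rng.random(n)
        cmp_ = rng.random(n)
        ref[rng.random(n) < 0.1] = np.nan  # undefined positions break runs
        threshold = float(rng.uniform(0.05, 0.5))
        diff = cmp_ - ref
        state = np.zeros(n, dtype=int)
        with np.errstate(invalid="ignore"):
            state[diff >= threshold] = 1
            state[diff <= -threshold] = -1
        assert candidate_regions(np.arange(n), ref, cmp_, threshold) == scan_runs(state)


# ---------------------------------------------------------------------------
# Fisher test and FDR
# ---------------------------------------------------------------------------

def test_fisher_diagonal_table_value():
    # frozen from the hypergeometric enumeration oracle: 2 / C(20, 10)
    assert region_p_value(10, 0, 0, 10) == pytest.approx(2 / 184756, rel=1e-9)
    assert region_p_value(10, 0, 0, 10) == pytest.approx(1.0825e-5, rel=1e-3)


def test_fisher_identical_margins_give_unity():
    assert region_p_value(5, 5, 5, 5) == 1.0


def test_fisher_all_zero_table_convention():
    assert region_p_value(0, 0, 0, 0) == 1.0


def test_fisher_matches_enumeration_oracle():
    rng = np.random.default_rng(10)
    for _ in range(100):
        a, b, c, d = (int(x) for x in rng.integers(0, 21, size=4))
        ours = region_p_value(a, b, c, d)
        oracle = fisher_two_sided_exact(a, b, c, d)
        assert abs(ours - oracle) < 1e-10


def test_bh_single_p_is_identity():
    assert adjust_fdr([0.037])[0] == pytest.approx(0.037)


def test_bh_hand_computation():
    np.testing.assert_allclose(
        adjust_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
    )


def test_bh_matches_independent_step_up():
    rng = np.random.default_rng(11)
    for _ in range(100):
        p = rng.random(int(rng.integers(1, 40)))
        np.testing.assert_allclose(adjust_fdr(p), bh_step_up(p), atol=1e-12)


# ---------------------------------------------------------------------------
# Filtering and merging
# ---------------------------------------------------------------------------

def build_dmr(start=0, end=100, context="CG", direction="hyper",
              n_cytosines=10, mean_coverage=20.0, prop_diff=0.5,
              p_value=1e-6, q_value=1e-4, chrom="chr1",
              meth_ref=10, unmeth_ref=90, meth_cmp=60, unmeth_cmp=40):
    return Dmr(
        interval=GenomicInterval(chrom, start, end, "."),
        context=context, direction=direction, n_cytosines=n_cytosines,
        mean_coverage=mean_coverage, prop_diff=prop_diff,
        p_value=p_value, q_value=q_value, meth_ref=meth_ref,
        unmeth_ref=unmeth_ref, meth_cmp=meth_cmp, unmeth_cmp=unmeth_cmp,
    )


def test_short_cg_region_removed():
    params = DmrParams.for_context("CG")
    assert filter_dmrs([build_dmr(end=30)], params) == []
    assert len(filter_dmrs([build_dmr(end=50)], params)) == 1


def test_low_coverage_region_removed():
    params = DmrParams.for_context("CG")
    assert filter_dmrs([build_dmr(mean_coverage=7.9)], params) == []
    assert len(filter_dmrs([build_dmr(mean_coverage=8.0)], params)) == 1


def test_threshold_tie_is_retained():
    params = DmrParams.for_context("CG")
    assert len(filter_dmrs([build_dmr(prop_diff=0.40)], params)) == 1
    assert filter_dmrs([build_dmr(prop_diff=0.39)], params) == []


def test_filter_matches_predicate_oracle():
    rng = np.random.default_rng(12)
    params = DmrParams.for_context("CHG")
    candidates = [
        build_dmr(
            start=0,
            end=int(rng.integers(10, 120)),
            context="CHG",
            n_cytosines=int(rng.integers(1, 12)),
            mean_coverage=float(rng.uniform(2, 20)),
            prop_diff=float(rng.uniform(-0.6, 0.6)),
            q_value=float(rng.uniform(0, 0.2)),
        )
        for _ in range(200)
    ]
    kept = filter_dmrs(candidates, params)
    expected = [
        d
        for d in candidates
        if d.q_value < 0.05
        and len(d.interval) >= 50
        and d.mean_coverage >= 8
        and abs(d.prop_diff) >= 0.30 - 1e-12
        and d.n_cytosines >= params.min_cytosines
    ]
    assert kept == expected


def test_merge_gap_boundary():
    a = build_dmr(start=0, end=100)
    b = build_dmr(start=299, end=400)  # gap 199 -> merge
    merged = merge_dmrs([a, b], merge_gap_bp=200)
    assert len(merged) == 1
    assert (merged[0].interval.start, merged[0].interval.end) == (0, 400)
    c = build_dmr(start=300, end=400)  # gap 200 -> no merge
    assert len(merge_dmrs([a, c], merge_gap_bp=200)) == 2


def test_opposite_directions_never_merge():
    a = build_dmr(start=0, end=100, direction="hyper")
    b = build_dmr(start=120, end=220, direction="hypo", prop_diff=-0.5)
    assert len(merge_dmrs([a, b], merge_gap_bp=200)) == 2


def test_merged_statistics_recomputed_from_pooled_counts():
    a = build_dmr(start=0, end=100, meth_ref=5, unmeth_ref=45, meth_cmp=30,
                  unmeth_cmp=20, n_cytosines=6)
    b = build_dmr(start=150, end=260, meth_ref=10, unmeth_ref=40, meth_cmp=40,
                  unmeth_cmp=10, n_cytosines=8)
    (merged,) = merge_dmrs([a, b], merge_gap_bp=200)
    assert merged.n_cytosines == 14
    assert (merged.meth_ref, merged.unmeth_ref) == (15, 85)
    assert merged.prop_diff == pytest.approx(70 / 100 - 15 / 100)
    assert merged.p_value == pytest.approx(region_p_value(70, 30, 15, 85))
    assert merged.q_value == pytest.approx(merged.p_value)  # single region BH
    assert merged.mean_coverage == pytest.approx(200 / (14 * 2))


def test_merge_matches_fixpoint_oracle():
    rng = np.random.default_rng(13)
    for _ in range(20):
        dmrs = []
        cursor = 0
        for _ in range(int(rng.integers(1, 12))):
            cursor += int(rng.integers(1, 400))
            length = int(rng.integers(30, 150))
            dmrs.append(
                build_dmr(
                    start=cursor,
                    end=cursor + length,
                    direction="hyper" if rng.random() < 0.5 else "hypo",
                )
            )
            cursor += length
        merged = merge_dmrs(dmrs, merge_gap_bp=200)
        # oracle: repeatedly fuse any adjacent eligible pair until stable
        intervals = [
            (d.interval.start, d.interval.end, d.direction) for d in dmrs
        ]
        changed = True
        while changed:
            changed = False
            for i in range(len(intervals) - 1):
                s1, e1, d1 = intervals[i]
                s2, e2, d2 = intervals[i + 1]
                if d1 == d2 and s2 - e1 < 200:
                    intervals[i : i + 2] = [(s1, max(e1, e2), d1)]
                    changed = True
                    break
        assert [
            (d.interval.start, d.interval.end, d.direction) for d in merged
        ] == intervals


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------

def make_group(rng, positions, levels, depth, n_reps, chrom="chr1"):
    reps = []
    for _ in range(n_reps):
        depths = rng.poisson(depth, len(positions))
        meth = rng.binomial(depths, levels)
        reps.append(
            make_cx(
                [
                    (chrom, int(p) + 1, "+", int(m), int(d - m), "CG")
                    for p, m, d in zip(positions, meth, depths)
                ]
            )
        )
    return reps


def test_identical_groups_yield_no_dmrs():
    rng = np.random.default_rng(14)
    positions = np.sort(rng.choice(np.arange(10_000), 300, replace=False))
    levels = rng.uniform(0.2, 0.8, len(positions))
    group = make_group(rng, positions, levels, 30, 3)
    assert call_dmrs(group, group, "CG") == []


def test_planted_block_recovered_and_antisymmetric():
    """A 60 bp planted block at +0.6 difference yields exactly one hyper
    DMR overlapping the block; swapping group roles flips its direction
    but not its interval."""
    rng = np.random.default_rng(15)
    positions = np.sort(rng.choice(np.arange(10_000), 400, replace=False))
    base = np.full(len(positions), 0.15)
    block = (positions >= 5_000) & (positions < 5_060)
    assert block.sum() >= 4
    cmp_levels = np.where(block, 0.75, base)
    ref_group = make_group(rng, positions, base, 30, 3)
    cmp_group = make_group(rng, positions, cmp_levels, 30, 3)
    dmrs = call_dmrs(ref_group, cmp_group, "CG")
    assert len(dmrs) == 1
    (dmr,) = dmrs
    assert dmr.direction == "hyper"
    assert dmr.interval.start < 5_060 and dmr.interval.end > 5_000
    swapped = call_dmrs(cmp_group, ref_group, "CG")
    assert [(d.interval, d.context) for d in swapped] == [
        (d.interval, d.context) for d in dmrs
    ]
    assert [d.direction for d in swapped] == ["hypo"]
    assert swapped[0].prop_diff == pytest.approx(-dmr.prop_diff)


def test_chh_threshold_admits_small_differences_cg_does_not():
    """A 10-15% difference clears the CHH threshold but not the CG one:
    the context-specific parameterisation orders detection floors."""
    rng = np.random.default_rng(16)
    positions = np.sort(rng.choice(np.arange(4_000), 300, replace=False))
    block = (positions >= 2_000) & (positions < 2_050)
    base = np.full(len(positions), 0.05)
    cmp_levels = np.where(block, 0.20, base)

    def group_with_context(context, levels):
        reps = []
        for _ in range(3):
            depths = rng.poisson(40, len(positions))
            meth = rng.binomial(depths, levels)
            reps.append(
                make_cx(
                    [
                        ("chr1", int(p) + 1, "+", int(m), int(d - m), context)
                        for p, m, d in zip(positions, meth, depths)
                    ]
                )
            )
        return reps

    chh_dmrs = call_dmrs(
        group_with_context("CHH", base), group_with_context("CHH", cmp_levels), "CHH"
    )
    cg_dmrs = call_dmrs(
        group_with_context("CG", base), group_with_context("CG", cmp_levels), "CG"
    )
    assert len(chh_dmrs) >= 1
    assert cg_dmrs == []


def test_params_context_mismatch_rejected():
    with pytest.raises(ValueError, match="context"):
        call_dmrs([], [], "CG", DmrParams.for_context("CHH"))


def test_dmr_params_validation():
    with pytest.raises(ValueError):
        DmrParams(context="XX")
    with pytest.raises(ValueError):
        DmrParams(fdr_threshold=1.5)
    with pytest.raises(ValueError):
        DmrParams(min_size_bp=0)
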