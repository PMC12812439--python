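"""Seed-reproducible synthetic datasets with planted truth.

The generator emulates a small multi-chromosome plant genome observed by
whole-genome bisulfite sequencing in two tetraploid cultivars at two time
points (before / after a heat stress), plus matched gene/repeat
annotations, a differential-expression table, and a tetraploid VCF:

* methylation truth is piecewise-constant over 200 bp blocks, with
  context-specific baseline bands (CG bimodal and high, CHG broad, CHH
  near zero) so the three contexts reproduce the canonical ordering of
  plant methylation levels;
* planted *constitutive* DMRs differ between the cultivars at both time
  points and are placed inside gene windows so they produce DMR-gene
  links; planted *induced* DMRs differ only after stress in one cultivar
  and are CHH-biased, mirroring the stress-responsive context;
* observed counts are Binomial(depth, level) with per-cytosine Poisson
  depth, independent across samples; symmetric CG strand pairs are two
  independent records sharing a true level;
* SNPs inside planted constitutive DMRs carry a configurable *negative*
  methylation-dosage coupling: with probability ``dosage_coupling_prob``
  the cultivar hypomethylated in a region receives the larger
  alternative-allele dosage sum there.

Everything downstream of the generator can therefore be scored against
:class:`SimulationTruth` exactly.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dmr import DEFAULT_MIN_PROP_DIFF, DEFAULT_MIN_SIZE_BP, Dmr
from .io import (
    GeneModel,
    GenomicInterval,
    RepeatElement,
    write_cx_report,
)

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SimulationConfig:
    """Study conditions of a synthetic dataset.

    Defaults describe the reference scenario: a 1 Mb diploid-genome
    stand-in (2 x 500 kb), mean depth 30, three replicates per cultivar
    and time point, planted DMR effects at 1.5x the context's calling
    threshold with spans twice the context's minimum size, and a strong
    (0.8) negative methylation-dosage coupling.
    """

    n_chromosomes: int = 2
    chrom_length_bp: int = 500_000
    n_genes: int = 120
    n_repeats: int = 60
    gene_length_bp: tuple[int, int] = (1_000, 3_000)
    repeat_length_bp: tuple[int, int] = (200, 1_000)
    read_depth_mean: float = 30.0
    n_replicates: int = 3
    block_bp: int = 200
    # context baseline bands (low, high); CG additionally has a low mode
    cg_band: tuple[float, float] = (0.60, 0.95)
    cg_low_band: tuple[float, float] = (0.02, 0.10)
    cg_low_mode_prob: float = 0.3
    chg_band: tuple[float, float] = (0.02, 0.80)
    chh_band: tuple[float, float] = (0.01, 0.17)
    n_constitutive_dmrs: int = 24
    n_induced_dmrs: int = 12
    induced_context_probs: dict = field(
        default_factory=lambda: {"CG": 0.1, "CHG": 0.2, "CHH": 0.7}
    )
    induced_hyper_prob: float = 0.75
    induced_cmp_cultivar_prob: float = 0.8
    effect_multiplier: float = 1.5  # x context min_prop_diff
    length_multiplier: int = 2  # x context min_size_bp
    deg_fraction: float = 0.3
    dosage_coupling_prob: float = 0.8
    snps_per_dmr: int = 3
    n_background_snps: int = 200
    ref_cultivar: str = "CA"
    cmp_cultivar: str = "AA"
    timepoints: tuple[str, str] = ("before", "after")
    rng_seed: int = 0

    def __post_init__(self):
        if self.chrom_length_bp < 10_000:
            raise ValueError("chrom_length_bp must be >= 10 kb")
        for p in (
            self.deg_fraction, self.dosage_coupling_prob,
            self.cg_low_mode_prob, self.induced_hyper_prob,
            self.induced_cmp_cultivar_prob,
        ):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class PlantedDmr:
    interval: GenomicInterval
    context: str
    direction: str  # 'hyper' | 'hypo' (comparison relative to reference)
    effect: float
    kind: str  # 'constitutive' | 'induced'
    cultivar: str | None = None  # induced only: the cultivar that changes
    gene_id: str | None = None  # constitutive only: the gene it was placed by
    region: str | None = None


@dataclass
class SimulationTruth:
    """Everything a downstream stage's output can be scored against."""

    planted_dmrs: list[PlantedDmr] = field(default_factory=list)
    deg_status: dict[str, str] = field(default_factory=dict)
    snp_dosages: dict[tuple[str, int], dict[str, int]] = field(
        default_factory=dict
    )
    coupling_winner: dict[int, str | None] = field(default_factory=dict)
    # index into planted_dmrs -> cultivar with the larger dosage sum

    def constitutive(self) -> list[PlantedDmr]:
        return [d for d in self.planted_dmrs if d.kind == "constitutive"]

    def induced(self, cultivar: str | None = None) -> list[PlantedDmr]:
        return [
            d
            for d in self.planted_dmrs
            if d.kind == "induced"
            and (cultivar is None or d.cultivar == cultivar)
        ]


# ---------------------------------------------------------------------------
# Genome and annotations
# ---------------------------------------------------------------------------

def generate_genome(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[str, str], list[GeneModel], list[RepeatElement]]:
    """Random genome with non-overlapping genes in the chromosome arms
    and repeats concentrated in the middle ("pericentromeric") third."""
    sequences: dict[str, str] = {}
    genes: list[GeneModel] = []
    repeats: list[RepeatElement] = []
    bases = np.frombuffer(b"ACGT", dtype="S1")
    length = config.chrom_length_bp
    genes_per_chrom = _split_evenly(config.n_genes, config.n_chromosomes)
    reps_per_chrom = _split_evenly(config.n_repeats, config.n_chromosomes)
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        seq = rng.choice(bases, size=length)
        sequences[chrom] = seq.tobytes().decode()
        peri = (length // 3, 2 * length // 3)
        arm_windows = [(0, peri[0]), (peri[1], length)]
        gene_ivs = _pack_intervals(
            rng, arm_windows, genes_per_chrom[c], config.gene_length_bp,
            what="genes",
        )
        for iv_start, iv_end in gene_ivs:
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    f"gene_{chrom}_{len(genes):04d}",
                    GenomicInterval(chrom, iv_start, iv_end, strand),
                )
            )
        rep_ivs = _pack_intervals(
            rng, [peri], reps_per_chrom[c], config.repeat_length_bp,
            what="repeats",
        )
        for iv_start, iv_end in rep_ivs:
            repeats.append(
                RepeatElement(
                    f"rep_{chrom}_{len(repeats):04d}",
                    GenomicInterval(chrom, iv_start, iv_end, "."),
                )
            )
    return sequences, genes, repeats


def _split_evenly(n: int, k: int) -> list[int]:
    base = n // k
    out = [base] * k
    for i in range(n - base * k):
        out[i] += 1
    return out


def _pack_intervals(rng, windows, n, length_range, what, max_tries=10_000):
    """Place n non-overlapping intervals inside the given windows."""
    placed: list[tuple[int, int]] = []
    tries = 0
    while len(placed) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n} non-overlapping {what}; "
                "reduce the count or lengths"
            )
        win = windows[rng.integers(len(windows))]
        size = int(rng.integers(length_range[0], length_range[1] + 1))
        if win[1] - win[0] <= size:
            continue
        start = int(rng.integers(win[0], win[1] - size))
        end = start + size
        if any(start < e and s < end for s, e in placed):
            continue
        placed.append((start, end))
    return sorted(placed)


# ---------------------------------------------------------------------------
# Truth planting
# ---------------------------------------------------------------------------

def plant_truth(
    config: SimulationConfig,
    genes: list[GeneModel],
    rng: np.random.Generator,
) -> SimulationTruth:
    """Plant constitutive DMRs inside gene windows, induced DMRs in the
    pericentromeric third, and DEG statuses."""
    truth = SimulationTruth()
    occupied: dict[str, list[tuple[int, int]]] = {}
    contexts = ["CG", "CHG", "CHH"]
    # constitutive: cycle contexts so the mix is even; alternate direction
    gene_order = list(rng.permutation(len(genes)))
    gi = 0
    for i in range(config.n_constitutive_dmrs):
        context = contexts[i % 3]
        effect = config.effect_multiplier * DEFAULT_MIN_PROP_DIFF[context]
        size = config.length_multiplier * DEFAULT_MIN_SIZE_BP[context]
        direction = "hyper" if rng.random() < 0.5 else "hypo"
        placed = None
        while placed is None:
            if gi >= len(gene_order):
                raise RuntimeError(
                    "not enough genes to host the planted DMRs"
                )
            gene = genes[gene_order[gi]]
            gi += 1
            region = ("upstream", "gene_body", "downstream")[
                int(rng.integers(3))
            ]
            placed = _place_in_gene_window(
                gene, region, size, occupied, config, rng
            )
        interval, region = placed
        truth.planted_dmrs.append(
            PlantedDmr(
                interval=interval, context=context, direction=direction,
                effect=effect, kind="constitutive",
                gene_id=gene.gene_id, region=region,
            )
        )
    # induced: pericentromeric third, CHH-biased, mostly hypermethylated
    # after stress, mostly in the comparison cultivar
    ctx_names = list(config.induced_context_probs)
    ctx_probs = np.array([config.induced_context_probs[c] for c in ctx_names])
    ctx_probs = ctx_probs / ctx_probs.sum()
    length = config.chrom_length_bp
    for _ in range(config.n_induced_dmrs):
        context = ctx_names[int(rng.choice(len(ctx_names), p=ctx_probs))]
        effect = config.effect_multiplier * DEFAULT_MIN_PROP_DIFF[context]
        size = config.length_multiplier * DEFAULT_MIN_SIZE_BP[context]
        direction = "hyper" if rng.random() < config.induced_hyper_prob else "hypo"
        cultivar = (
            config.cmp_cultivar
            if rng.random() < config.induced_cmp_cultivar_prob
            else config.ref_cultivar
        )
        for _ in range(1000):
            chrom = f"chr{int(rng.integers(config.n_chromosomes)) + 1}"
            start = int(rng.integers(length // 3, 2 * length // 3 - size))
            if _is_free(occupied.get(chrom, []), start, start + size):
                _occupy(occupied, chrom, start, start + size)
                truth.planted_dmrs.append(
                    PlantedDmr(
                        interval=GenomicInterval(chrom, start, start + size, "."),
                        context=context, direction=direction, effect=effect,
                        kind="induced", cultivar=cultivar,
                    )
                )
                break
        else:
            raise RuntimeError("could not place induced DMR")
    # DEG statuses: independent of DMR placement and direction, so a
    # direction x regulation coupling is never planted
    for gene in genes:
        u = rng.random()
        if u < config.deg_fraction / 2:
            truth.deg_status[gene.gene_id] = "up"
        elif u < config.deg_fraction:
            truth.deg_status[gene.gene_id] = "down"
        else:
            truth.deg_status[gene.gene_id] = "ns"
    return truth


# planted regions keep clear of each other by a margin wider than the
# merge gap plus the kernel support, so recovered regions never fuse
_SEPARATION_BP = 400


def _is_free(placed, start, end):
    return all(
        start - _SEPARATION_BP >= e or end + _SEPARATION_BP <= s
        for s, e in placed
    )


def _occupy(occupied, chrom, start, end):
    occupied.setdefault(chrom, []).append((start, end))


def _place_in_gene_window(gene, region, size, occupied, config, rng):
    from .association import gene_windows

    windows = gene_windows(gene, flank_bp=2000)
    window = windows.get(region)
    if window is None or len(window) <= size:
        return None
    for _ in range(20):
        start = int(rng.integers(window.start, window.end - size))
        end = start + size
        if end > config.chrom_length_bp - 10:
            continue
        if _is_free(occupied.get(window.chrom, []), start, end):
            _occupy(occupied, window.chrom, start, end)
            return GenomicInterval(window.chrom, start, end, "."), region
    return None


# ---------------------------------------------------------------------------
# Methylome simulation
# ---------------------------------------------------------------------------

def _cytosine_sites(seq: str):
    """Cytosine positions (0-based), strands, contexts and trinucleotides
    on both strands of a sequence."""
    arr = np.frombuffer(seq.encode(), dtype="S1")
    n = len(arr)
    is_c = arr == b"C"
    is_g = arr == b"G"
    # plus strand: C at i, context from i+1, i+2 (skip last two bases)
    plus = np.flatnonzero(is_c[: n - 2])
    plus_cg = is_g[plus + 1]
    plus_chg = ~plus_cg & is_g[plus + 2]
    # minus strand: G at i read as C on the reverse strand, context from
    # i-1, i-2 (skip first two bases)
    minus = np.flatnonzero(is_g)
    minus = minus[minus >= 2]
    minus_cg = is_c[minus - 1]
    minus_chg = ~minus_cg & is_c[minus - 2]

    def ctx_labels(cg, chg):
        out = np.full(len(cg), "CHH", dtype=object)
        out[chg] = "CHG"
        out[cg] = "CG"
        return out

    pos = np.concatenate([plus, minus])
    strand = np.concatenate(
        [np.full(len(plus), "+", dtype=object),
         np.full(len(minus), "-", dtype=object)]
    )
    context = np.concatenate(
        [ctx_labels(plus_cg, plus_chg), ctx_labels(minus_cg, minus_chg)]
    )
    order = np.argsort(pos, kind="stable")
    pos, strand, context = pos[order], strand[order], context[order]
    # trinucleotides, vectorised: 5' -> 3' on the cytosine's own strand
    u8 = np.frombuffer(seq.encode(), dtype=np.uint8)
    comp = np.zeros(256, dtype=np.uint8)
    for a, b in COMPLEMENT.items():
        comp[ord(a)] = ord(b)
    tri_plus = np.empty((len(plus), 3), dtype=np.uint8)
    for k in range(3):
        tri_plus[:, k] = u8[plus + k]
    tri_minus = np.empty((len(minus), 3), dtype=np.uint8)
    for k in range(3):
        tri_minus[:, k] = comp[u8[minus - k]]
    tri_all = np.concatenate([tri_plus, tri_minus])[order]
    tri = tri_all.reshape(-1).view("S3").astype("U3").astype(object)
    return pos.astype(np.int64), strand, context, tri


def _block_levels(config, n_blocks, context, rng):
    if context == "CG":
        low = rng.uniform(*config.cg_low_band, size=n_blocks)
        high = rng.uniform(*config.cg_band, size=n_blocks)
        pick_low = rng.random(n_blocks) < config.cg_low_mode_prob
        return np.where(pick_low, low, high)
    if context == "CHG":
        return rng.uniform(*config.chg_band, size=n_blocks)
    return rng.uniform(*config.chh_band, size=n_blocks)


def _band_high(config, context):
    return {
        "CG": config.cg_band[1],
        "CHG": config.chg_band[1],
        "CHH": config.chh_band[1],
    }[context]


def _band_low(config, context):
    return {
        "CG": config.cg_low_band[0],
        "CHG": config.chg_band[0],
        "CHH": config.chh_band[0],
    }[context]


def simulate_methylome(
    config: SimulationConfig,
    truth: SimulationTruth,
    sequences: dict[str, str],
    rng: np.random.Generator,
) -> dict[tuple[str, str, int], pd.DataFrame]:
    """Observed cytosine reports per (cultivar, time point, replicate).

    True levels are piecewise-constant per 200 bp block and context;
    planted DMRs override the block level with a baseline that leaves room
    for the effect (the region hosting a hypomethylated-in-comparison DMR
    is given a high enough baseline that subtracting the effect never
    clips at zero).
    """
    cultivars = (config.ref_cultivar, config.cmp_cultivar)
    out: dict[tuple[str, str, int], pd.DataFrame] = {}
    chrom_frames: dict[tuple[str, str, int], list[pd.DataFrame]] = {
        (cv, tp, rep): []
        for cv in cultivars
        for tp in config.timepoints
        for rep in range(config.n_replicates)
    }
    for chrom in sorted(sequences):
        seq = sequences[chrom]
        pos, strand, context, tri = _cytosine_sites(seq)
        n_sites = len(pos)
        block = pos // config.block_bp
        n_blocks = int(block.max()) + 1 if n_sites else 0
        base = np.empty(n_sites)
        for ctx in ("CG", "CHG", "CHH"):
            mask = context == ctx
            base[mask] = _block_levels(config, n_blocks, ctx, rng)[block[mask]]
        delta_const = np.zeros(n_sites)
        delta_induced = {cv: np.zeros(n_sites) for cv in cultivars}
        for idx, planted in enumerate(truth.planted_dmrs):
            iv = planted.interval
            if iv.chrom != chrom:
                continue
            mask = (
                (pos >= iv.start) & (pos < iv.end) & (context == planted.context)
            )
            sign = 1.0 if planted.direction == "hyper" else -1.0
            e = planted.effect
            # baseline leaving room for the signed effect in [0, 1]
            if sign > 0:
                lo = _band_low(config, planted.context)
                hi = max(lo, min(_band_high(config, planted.context), 1 - e - 0.02))
            else:
                lo = min(e + 0.02, 0.95)
                hi = max(_band_high(config, planted.context), lo)
            base[mask] = rng.uniform(lo, hi, size=int(mask.sum()))
            if planted.kind == "constitutive":
                delta_const[mask] += sign * e
            else:
                delta_induced[planted.cultivar][mask] += sign * e
        for cv in cultivars:
            for tp in config.timepoints:
                level = base.copy()
                if cv == config.cmp_cultivar:
                    level = level + delta_const
                # induced effects appear only at the post-stress time point
                if len(config.timepoints) > 1 and tp == config.timepoints[1]:
                    level = level + delta_induced[cv]
                np.clip(level, 0.0, 1.0, out=level)
                for rep in range(config.n_replicates):
                    depth = rng.poisson(config.read_depth_mean, n_sites)
                    meth = rng.binomial(depth, level)
                    chrom_frames[(cv, tp, rep)].append(
                        pd.DataFrame(
                            {
                                "chrom": chrom,
                                "pos": pos + 1,  # CX reports are 1-based
                                "strand": strand,
                                "meth": meth,
                                "unmeth": depth - meth,
                                "context": context,
                                "tri": tri,
                            }
                        )
                    )
    for key, frames in chrom_frames.items():
        out[key] = pd.concat(frames, ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# Variant simulation
# ---------------------------------------------------------------------------

def simulate_variants(
    config: SimulationConfig,
    truth: SimulationTruth,
    sequences: dict[str, str],
    rng: np.random.Generator,
) -> list[dict]:
    """SNPs with tetraploid genotypes for the two cultivars.

    Inside each planted constitutive DMR the per-SNP dosages of the
    "winner" cultivar (chosen with probability ``dosage_coupling_prob`` to
    be the hypomethylated one) strictly exceed the loser's, so the dosage
    sums are ordered before sampling noise.  SNPs inside planted DMRs
    always pass the quality filters; background SNPs include records the
    filters must reject (low QUAL, out-of-range depth, zero frequency,
    missing and multi-allelic genotypes).

    Returns VCF-shaped dicts (chrom, pos, ref, alt(s), qual, per-sample
    depth and dosage) and fills ``truth.snp_dosages`` and
    ``truth.coupling_winner``.
    """
    ref_cv, cmp_cv = config.ref_cultivar, config.cmp_cultivar
    records: list[dict] = []
    occupied: set[tuple[str, int]] = set()

    def add_record(chrom, pos0, dosages, qual, depths, multi=False):
        ref_base = sequences[chrom][pos0]
        alt = _draw_alt(ref_base, rng)
        rec = {
            "chrom": chrom,
            "pos": pos0 + 1,
            "ref": ref_base,
            "alts": [alt] if not multi else [alt, _draw_alt(ref_base, rng, exclude=alt)],
            "qual": round(float(qual), 1),
            "depth": depths,
            "dosage": dosages,
        }
        records.append(rec)
        if not multi and all(d is not None for d in dosages.values()):
            truth.snp_dosages[(chrom, pos0 + 1)] = dict(dosages)
        return rec

    for idx, planted in enumerate(truth.planted_dmrs):
        if planted.kind != "constitutive":
            continue
        iv = planted.interval
        hypo_cultivar = cmp_cv if planted.direction == "hypo" else ref_cv
        other = ref_cv if hypo_cultivar == cmp_cv else cmp_cv
        winner = hypo_cultivar if rng.random() < config.dosage_coupling_prob else other
        truth.coupling_winner[idx] = winner
        loser = ref_cv if winner == cmp_cv else cmp_cv
        n_snps = min(config.snps_per_dmr, len(iv))
        positions = sorted(
            int(p) for p in rng.choice(
                np.arange(iv.start, iv.end), size=n_snps, replace=False
            )
        )
        for pos0 in positions:
            if (iv.chrom, pos0) in occupied:
                continue
            occupied.add((iv.chrom, pos0))
            d_loser = int(rng.integers(0, 4))
            d_winner = int(rng.integers(d_loser + 1, 5))
            dosages = {winner: d_winner, loser: d_loser}
            depths = {
                ref_cv: int(rng.integers(15, 46)),
                cmp_cv: int(rng.integers(15, 46)),
            }
            add_record(iv.chrom, pos0, dosages, rng.uniform(40, 80), depths)

    # background SNPs scattered outside planted regions
    planted_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for planted in truth.planted_dmrs:
        planted_by_chrom.setdefault(planted.interval.chrom, []).append(
            (planted.interval.start, planted.interval.end)
        )
    chroms = sorted(sequences)
    n_placed = 0
    while n_placed < config.n_background_snps:
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos0 = int(rng.integers(0, len(sequences[chrom])))
        if (chrom, pos0) in occupied:
            continue
        if any(s <= pos0 < e for s, e in planted_by_chrom.get(chrom, [])):
            continue
        occupied.add((chrom, pos0))
        n_placed += 1
        u = rng.random()
        if u < 0.05:  # missing genotype in one cultivar
            dosages = {ref_cv: None, cmp_cv: int(rng.integers(0, 5))}
        elif u < 0.10:  # monomorphic (MAF filter must drop)
            d = 0 if rng.random() < 0.5 else 4
            dosages = {ref_cv: d, cmp_cv: d}
        else:
            dosages = {
                ref_cv: int(rng.integers(0, 5)),
                cmp_cv: int(rng.integers(0, 5)),
            }
        qual = rng.uniform(10, 80)  # a tail below the QUAL threshold
        depths = {
            ref_cv: int(rng.integers(5, 61)),  # tails outside [10, 50]
            cmp_cv: int(rng.integers(5, 61)),
        }
        add_record(
            chrom, pos0, dosages, qual, depths,
            multi=rng.random() < 0.02,
        )
    records.sort(key=lambda r: (r["chrom"], r["pos"]))
    return records


def _draw_alt(ref_base: str, rng: np.random.Generator, exclude=None) -> str:
    """Alternative allele; deamination-class transitions dominate."""
    transition = {"C": "T", "T": "C", "G": "A", "A": "G"}[ref_base]
    if exclude != transition and rng.random() < 0.8:
        return transition
    choices = [b for b in "ACGT" if b != ref_base and b != exclude]
    return choices[int(rng.integers(len(choices)))]


def dosage_to_gt(dosage: int | None) -> str:
    if dosage is None:
        return "./././."
    return "/".join(["0"] * (4 - dosage) + ["1"] * dosage)


def write_vcf(
    records: list[dict],
    path: str | os.PathLike,
    samples: tuple[str, str],
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write simulated variants as a VCF v4.2 with tetraploid GT fields."""
    with open(path, "w") as handle:
        handle.write("##fileformat=VCFv4.2\n")
        handle.write("##source=dmrdose-simulate\n")
        for chrom, length in (contig_lengths or {}).items():
            handle.write(f"##contig=<ID={chrom},length={length}>\n")
        handle.write(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        )
        handle.write(
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
        )
        handle.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for rec in records:
            fields = [
                rec["chrom"],
                str(rec["pos"]),
                ".",
                rec["ref"],
                ",".join(rec["alts"]),
                f"{rec['qual']:.1f}",
                ".",
                ".",
                "GT:DP",
            ]
            for sample in samples:
                gt = dosage_to_gt(rec["dosage"].get(sample))
                fields.append(f"{gt}:{rec['depth'][sample]}")
            handle.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# DE table simulation
# ---------------------------------------------------------------------------

def simulate_de_table(
    config: SimulationConfig,
    truth: SimulationTruth,
    genes: list[GeneModel],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """DE results table consistent with the planted DEG statuses.

    Planted DEGs get |log2FC| > 1 and FDR < 0.05 by construction;
    non-DEGs include rows exactly at the thresholds (log2FC = 1.0,
    FDR = 0.05) to exercise the strict inequalities downstream.
    """
    rows = []
    boundary_cases = [(1.0, 0.001), (2.0, 0.05), (-1.0, 0.001)]
    n_boundary = 0
    for gene in genes:
        status = truth.deg_status[gene.gene_id]
        if status == "up":
            fc = float(rng.uniform(1.5, 4.0))
            fdr = float(10 ** rng.uniform(-6, -2))
        elif status == "down":
            fc = -float(rng.uniform(1.5, 4.0))
            fdr = float(10 ** rng.uniform(-6, -2))
        elif n_boundary < len(boundary_cases):
            fc, fdr = boundary_cases[n_boundary]
            n_boundary += 1
        else:
            fc = float(rng.uniform(-0.9, 0.9))
            fdr = float(rng.uniform(0.05, 1.0))
        rows.append({"gene_id": gene.gene_id, "log2fc": fc, "fdr": fdr})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    config: SimulationConfig
    sequences: dict[str, str]
    genes: list[GeneModel]
    repeats: list[RepeatElement]
    methylomes: dict[tuple[str, str, int], pd.DataFrame]
    variants: list[dict]
    de_table: pd.DataFrame
    truth: SimulationTruth

    def group(self, cultivar: str, timepoint: str) -> list[pd.DataFrame]:
        """Replicate cytosine frames of one cultivar at one time point."""
        return [
            frame
            for (cv, tp, _rep), frame in sorted(self.methylomes.items())
            if cv == cultivar and tp == timepoint
        ]


def simulate_dataset(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Generate a complete in-memory dataset with planted truth."""
    if config is None:
        config = SimulationConfig()
    rng = np.random.default_rng(config.rng_seed)
    sequences, genes, repeats = generate_genome(config, rng)
    truth = plant_truth(config, genes, rng)
    methylomes = simulate_methylome(config, truth, sequences, rng)
    variants = simulate_variants(config, truth, sequences, rng)
    de_table = simulate_de_table(config, truth, genes, rng)
    return SimulatedDataset(
        config=config, sequences=sequences, genes=genes, repeats=repeats,
        methylomes=methylomes, variants=variants, de_table=de_table,
        truth=truth,
    )


def write_dataset(dataset: SimulatedDataset, outdir: str | os.PathLike) -> dict:
    """Write a dataset to disk in the formats the readers consume.

    Returns a manifest of written paths.  The truth file is JSON and is
    consumed only by tests and scoring code, never by the pipeline.
    """
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    manifest: dict = {"cx": {}}
    for (cv, tp, rep), frame in sorted(dataset.methylomes.items()):
        path = os.path.join(outdir, f"{cv}_{tp}_rep{rep + 1}.CX_report.txt")
        write_cx_report(frame, path)
        manifest["cx"][f"{cv}/{tp}/{rep + 1}"] = path
    genes_path = os.path.join(outdir, "genes.gff3")
    with open(genes_path, "w") as handle:
        handle.write("##gff-version 3\n")
        for gene in dataset.genes:
            iv = gene.interval
            handle.write(
                f"{iv.chrom}\tdmrdose\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={gene.gene_id}\n"
            )
    repeats_path = os.path.join(outdir, "repeats.bed")
    with open(repeats_path, "w") as handle:
        for rep in dataset.repeats:
            iv = rep.interval
            handle.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rep.repeat_id}\t0\t.\n"
            )
    vcf_path = os.path.join(outdir, "variants.vcf")
    write_vcf(
        dataset.variants,
        vcf_path,
        samples=(dataset.config.cmp_cultivar, dataset.config.ref_cultivar),
        contig_lengths={c: len(s) for c, s in dataset.sequences.items()},
    )
    de_path = os.path.join(outdir, "de_table.tsv")
    dataset.de_table.to_csv(de_path, sep="\t", index=False)
    truth_path = os.path.join(outdir, "truth.json")
    with open(truth_path, "w") as handle:
        json.dump(_truth_to_json(dataset.truth), handle, indent=1)
    manifest.update(
        genes=genes_path, repeats=repeats_path, vcf=vcf_path,
        de_table=de_path, truth=truth_path,
    )
    return manifest


def _truth_to_json(truth: SimulationTruth) -> dict:
    return {
        "planted_dmrs": [
            {
                **dataclasses.asdict(d.interval),
                "context": d.context,
                "direction": d.direction,
                "effect": d.effect,
                "kind": d.kind,
                "cultivar": d.cultivar,
                "gene_id": d.gene_id,
                "region": d.region,
            }
            for d in truth.planted_dmrs
        ],
        "deg_status": truth.deg_status,
        "snp_dosages": [
            {"chrom": chrom, "pos": pos, "dosage": dosage}
            for (chrom, pos), dosage in sorted(truth.snp_dosages.items())
        ],
        "coupling_winner": {
            str(k): v for k, v in truth.coupling_winner.items()
        },
    }


# ---------------------------------------------------------------------------
# Truth scoring
# ---------------------------------------------------------------------------

def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """min(overlap/|a|, overlap/|b|); 0 when disjoint or on different
    chromosomes."""
    if a.chrom != b.chrom:
        return 0.0
    overlap = min(a.end, b.end) - max(a.start, b.start)
    if overlap <= 0:
        return 0.0
    return min(overlap / len(a), overlap / len(b))


def dmr_recovery(
    called: list[Dmr],
    planted: list[PlantedDmr],
    min_reciprocal: float = 0.5,
    require_direction: bool = True,
) -> tuple[int, int]:
    """(recovered, total) planted DMRs matched by a called DMR of the
    same context at the reciprocal-overlap threshold."""
    recovered = 0
    for p in planted:
        for c in called:
            if c.context != p.context:
                continue
            if require_direction and c.direction != p.direction:
                continue
            if reciprocal_overlap(c.interval, p.interval) >= min_reciprocal:
                recovered += 1
                break
    return recovered, len(planted)
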