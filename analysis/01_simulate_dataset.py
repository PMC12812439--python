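"""Generate the reference synthetic dataset and write it to disk.

Two tetraploid cultivars (AA = comparison, CA = reference) observed by
WGBS at two time points (before/after heat stress, 3 replicates each) on
a 1 Mb two-chromosome genome, with planted constitutive DMRs inside gene
windows, CHH-biased induced DMRs, planted DEGs, and SNPs carrying a
negative methylation-dosage coupling.  The bulky cytosine reports go to
scratch/dataset/ (regenerable from the seed); a compact description of
the planted truth goes to results/.
"""

import os
import sys

import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), ".."))

from dmrdose.simulate import SimulationConfig, simulate_dataset, write_dataset

SEED = 0
OUT = os.path.join(os.path.dirname(__file__), "..", "results")
SCRATCH = os.path.join(os.path.dirname(__file__), "..", "scratch", "dataset")


def main():
    config = SimulationConfig(rng_seed=SEED)
    dataset = simulate_dataset(config)
    manifest = write_dataset(dataset, SCRATCH)
    os.makedirs(OUT, exist_ok=True)

    planted = pd.DataFrame(
        [
            {
                "chrom": p.interval.chrom,
                "start": p.interval.start,
                "end": p.interval.end,
                "context": p.context,
                "direction": p.direction,
                "effect": p.effect,
                "kind": p.kind,
                "cultivar": p.cultivar or "",
                "gene_id": p.gene_id or "",
                "region": p.region or "",
            }
            for p in dataset.truth.planted_dmrs
        ]
    )
    planted.to_csv(os.path.join(OUT, "01_planted_dmrs.tsv"), sep="\t", index=False)

    n_sites = len(next(iter(dataset.methylomes.values())))
    print(f"dataset written under {SCRATCH} ({len(manifest['cx'])} CX files)")
    print(f"cytosine sites per sample: {n_sites}")
    print(
        f"planted: {len(dataset.truth.constitutive())} constitutive and "
        f"{len(dataset.truth.induced())} induced DMRs, "
        f"{sum(s != 'ns' for s in dataset.truth.deg_status.values())} DEGs, "
        f"{len(dataset.variants)} variants"
    )
    print(planted.groupby(["kind", "context"]).size().to_string())


if __name__ == "__main__":
    main()
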