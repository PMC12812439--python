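"""Global methylation landscape of the simulated cultivars.

Computes 200 bp-bin weighted methylation distributions per context
(expected: bimodal/high CG, broad CHG, near-zero CHH), 500 kb chromosome
density tracks, and metagene profiles over gene bodies and repeats with
2 kb flanks.  Writes tidy tables under results/.
"""

import os
import sys

import numpy as np
import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), ".."))

from dmrdose.profiles import (
    bin_methylation,
    chromosome_density,
    metagene_profile,
    methylation_distribution,
)
from dmrdose.simulate import SimulationConfig, simulate_dataset

SEED = 0
OUT = os.path.join(os.path.dirname(__file__), "..", "results")
CONTEXTS = ("CG", "CHG", "CHH")


def main():
    config = SimulationConfig(rng_seed=SEED, timepoints=("before",))
    dataset = simulate_dataset(config)
    frame = pd.concat(dataset.group(config.ref_cultivar, "before"))
    os.makedirs(OUT, exist_ok=True)

    rows = []
    for context in CONTEXTS:
        bins = bin_methylation(frame, bin_size=200, context=context)
        counts, edges, n_undef = methylation_distribution(bins, n_hist_bins=20)
        median = float(np.nanmedian(bins["wml"]))
        rows.append({"context": context, "median_wml": round(median, 4),
                     "undefined_bins": n_undef})
        pd.DataFrame(
            {"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts}
        ).assign(context=context).to_csv(
            os.path.join(OUT, f"02_distribution_{context}.tsv"),
            sep="\t", index=False,
        )
        density = chromosome_density(frame, window=500_000, context=context)
        density.to_csv(
            os.path.join(OUT, f"02_density_{context}.tsv"), sep="\t", index=False
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(os.path.join(OUT, "02_context_medians.tsv"), sep="\t", index=False)
    print("median 200 bp-bin weighted methylation per context:")
    print(summary.to_string(index=False))

    profile_rows = []
    for features, label in ((dataset.genes, "genes"), (dataset.repeats, "repeats")):
        for context in CONTEXTS:
            profile = metagene_profile(
                frame, features, flank_bp=2000,
                n_flank_bins=20, n_body_bins=20, context=context,
            )
            for segment, values in (
                ("upstream", profile.upstream),
                ("body", profile.body),
                ("downstream", profile.downstream),
            ):
                for i, v in enumerate(values):
                    profile_rows.append(
                        {"features": label, "context": context,
                         "segment": segment, "bin": i, "wml": v}
                    )
    profiles = pd.DataFrame(profile_rows)
    profiles.to_csv(os.path.join(OUT, "02_metagene_profiles.tsv"),
                    sep="\t", index=False)
    body_means = (
        profiles[profiles["segment"] == "body"]
        .groupby(["features", "context"])["wml"].mean().round(3)
    )
    print("\nmean body-segment methylation (metagene):")
    print(body_means.to_string())


if __name__ == "__main__":
    main()
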