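import numpy as np
import pandas as pd
import pytest

from dmrdose.simulate import SimulationConfig, simulate_dataset


def make_cx(rows):
    """Cytosine frame from (chrom, pos, strand, meth, unmeth, context, tri)
    tuples; tri may be omitted."""
    full = [r if len(r) == 7 else (*r, r[5] + "N") for r in rows]
    return pd.DataFrame(
        full, columns=["chrom", "pos", "strand", "meth", "unmeth", "context", "tri"]
    )


def random_cx(rng, n, chrom="chr1", context=None, max_pos=10_000):
    pos = np.sort(rng.choice(np.arange(1, max_pos), size=n, replace=False))
    contexts = (
        rng.choice(["CG", "CHG", "CHH"], size=n)
        if context is None
        else np.full(n, context)
    )
    meth = rng.integers(0, 30, size=n)
    unmeth = rng.integers(0, 30, size=n)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "strand": rng.choice(["+", "-"], size=n),
            "meth": meth,
            "unmeth": unmeth,
            "context": contexts,
            "tri": [c + "NN" for c in contexts],
        }
    )


@pytest.fixture(scope="session")
def small_config():
    """A deliberately small synthetic scenario for fast unit tests."""
    return SimulationConfig(
        n_chromosomes=1,
        chrom_length_bp=100_000,
        n_genes=15,
        n_repeats=8,
        n_constitutive_dmrs=6,
        n_induced_dmrs=3,
        n_background_snps=40,
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def default_dataset():
    """The reference scenario (1 Mb, depth 30, 3 replicates)."""
    return simulate_dataset(SimulationConfig(rng_seed=0))
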