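import numpy as np
import pandas as pd
import pytest

import lakescan as lk


@pytest.fixture(scope="session")
def demo_sim():
    """One mid-sized radiation shared by read-only tests: 4 lakes x
    (Balchen, Albeli) x 3 fish, 2 chromosomes, 100 SNPs per 50 kb window."""
    cfg = lk.SimConfig(seed=101, n_chromosomes=2, snps_per_chromosome=5000)
    g, meta, truth = lk.simulate_radiation(cfg)
    return cfg, g, meta, truth


@pytest.fixture(scope="session")
def demo_groups(demo_sim):
    cfg, g, meta, truth = demo_sim
    groups = {
        sp: meta.loc[meta["species"] == sp, "sample"].tolist()
        for sp in cfg.species
    }
    groups["outgroup"] = meta.loc[
        meta["species"] == "outgroup", "sample"
    ].tolist()
    return groups


@pytest.fixture()
def toy_matrix():
    """2 samples x 3 SNPs with hand-set dosages."""
    loci = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr2"],
            "pos": [100, 250, 40],
            "ref": ["A", "C", "G"],
            "alt": ["T", "G", "A"],
        }
    )
    dosages = np.array([[0, 1, 2], [2, 0, 1]], dtype=np.int8)
    return lk.GenotypeMatrix(dosages, loci, ["fish_a", "fish_b"])
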