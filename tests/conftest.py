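import numpy as np
import pytest

import epiblup as eb
from epiblup.simulate import (
    SimulationConfig,
    simulate_effects,
    simulate_genotypes,
    simulate_phenotypes,
)


@pytest.fixture
def toy_genotypes():
    """3 individuals x 2 SNPs, both loci at p = 0.5."""
    return eb.GenotypeMatrix([[2, 0], [1, 1], [0, 2]], ["a", "b", "c"], ["s1", "s2"])


def small_simulation(seed, n=120, m=200, inbreeding=None, records=(2, 2), **targets):
    """One small data set with all simulation artifacts, for unit tests."""
    cfg = SimulationConfig(
        n_individuals=n, m_snps=m,
        records_min=records[0], records_max=records[1],
        inbreeding=inbreeding, n_pairs=300, seed=seed, n_groups=8, **targets,
    )
    rng = np.random.default_rng(seed)
    geno, F = simulate_genotypes(cfg, rng)
    truth = simulate_effects(geno, cfg, rng, f_latent=F)
    records_ = simulate_phenotypes(geno, truth, cfg, rng)
    return cfg, geno, F, truth, records_


@pytest.fixture(scope="session")
def small_dataset():
    cfg, geno, F, truth, records = small_simulation(42)
    freqs = eb.allele_frequencies(geno)
    f = eb.genomic_inbreeding(geno)
    grms = eb.build_grms(geno, freqs)
    return {
        "cfg": cfg, "genotypes": geno, "F": F, "truth": truth,
        "records": records, "freqs": freqs, "f": f, "grms": grms,
    }
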