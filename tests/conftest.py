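import numpy as np
import pandas as pd
import pytest

from regionscan import phenotype_prep, synthetic_data as sd


@pytest.fixture(scope="session")
def small_cohort():
    """Deterministic cohort with families, one regional QTL, missingness."""
    cfg = sd.SimulationConfig(
        n_samples=300, n_families=40, sibship_size=3,
        n_chromosomes=2, snps_per_chromosome=200,
        qtl_spec=[sd.QTLSpec(1, 50, 150, 0.08, n_causal=5)],
        h2_poly=0.4, missing_rate=0.01, n_hwe_violators=0, seed=11,
    )
    return sd.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def unrelated_genotypes():
    """Unrelated individuals, no LD, no missingness: clean HWE reference."""
    cfg = sd.SimulationConfig(
        n_samples=400, n_families=0, sibship_size=0,
        n_chromosomes=1, snps_per_chromosome=500,
        ld_decay=0.0, missing_rate=0.0, n_hwe_violators=0, seed=5,
    )
    return sd.simulate_genotypes(cfg)


def aligned_phenotype(cohort) -> np.ndarray:
    """Adjusted + rank-transformed phenotype in genotype sample order."""
    ph = phenotype_prep.prepare_phenotype(cohort.trait_table())
    return (
        pd.Series(ph.values, index=ph.sample_ids)
        .loc[cohort.genotypes.samples]
        .to_numpy()
    )
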