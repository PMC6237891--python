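import numpy as np
import pytest

import codonlife as cl

PLANTED_SEED = 11
WOBBLE_DELTA = 0.5


@pytest.fixture(scope="session")
def planted_config():
    """Paper-scale study conditions: n=2000 proteins, a wobble-class effect on
    every codon percentage, half-explainable responses, ~0.69 inter-dataset r."""
    return cl.SyntheticConfig(
        n_proteins=2000,
        length_range=(50, 300),
        seed=PLANTED_SEED,
        effect_map=cl.wobble_effect_map(WOBBLE_DELTA),
        target_r2=0.5,
        replicate_r=0.69,
    )


@pytest.fixture(scope="session")
def planted_cohort(planted_config):
    """Cohort with one target_r2 response and eight replicate datasets."""
    cohort = cl.generate_cds_cohort(planted_config)
    cl.plant_response(cohort, planted_config, "lifetime")
    cl.plant_replicates(cohort, planted_config, [f"ds{i}" for i in range(8)])
    cl.generate_structures(cohort, seed=PLANTED_SEED)
    return cohort


@pytest.fixture(scope="session")
def planted_features(planted_cohort):
    return cl.assemble_feature_matrix(planted_cohort.records, tier="composition")


@pytest.fixture(scope="session")
def small_cohort():
    """Quick 200-protein cohort for structural checks."""
    config = cl.SyntheticConfig(n_proteins=200, length_range=(30, 120), seed=5,
                                effect_map={"aa_A": 1.0, "aa_D": -1.0},
                                target_r2=0.8)
    cohort = cl.generate_cds_cohort(config)
    cl.plant_response(cohort, config, "lifetime")
    cl.generate_structures(cohort, seed=5)
    return cohort


@pytest.fixture
def rng():
    return np.random.default_rng(0)
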