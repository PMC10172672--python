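import numpy as np
import pytest

from metaomix.synthetic_cohort import CohortConfig, generate_cohort


def small_config(**overrides) -> CohortConfig:
    """Down-sized cohort for fast unit tests (same structure as the default)."""
    base = dict(
        n_patients=6,
        n_controls=6,
        n_genes=400,
        n_liver_markers=30,
        n_mirnas=100,
        n_probes=600,
        n_de_genes=60,
        n_dm_probes=60,
        n_bias_probes=50,
        n_de_mirnas=10,
        n_cnv_genes=30,
        n_deg_cnv_overlap=10,
        n_deg_meth_overlap=8,
        n_deg_mirna_overlap=6,
        n_somatic_variants=200,
        seed=11,
    )
    base.update(overrides)
    return CohortConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config())


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
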