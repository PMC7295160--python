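import numpy as np
import pytest

from devqtl import pipeline, simgen


@pytest.fixture(scope="session")
def cohort():
    """Default 176-sample developmental cohort (112 prenatal, 4 transitional,
    60 postnatal)."""
    return simgen.simulate_samples(seed=11)


@pytest.fixture(scope="session")
def small_study():
    """Small null study (no planted eQTLs) shared across read-only tests."""
    return pipeline.build_study(n_genes=80, n_variants=600, seed=5, n_hidden=2)


@pytest.fixture(scope="session")
def planted_study():
    """Study with prenatal-predominant planted effects (beta_pre=0.8,
    beta_post=0) on common variants, shared across read-only tests."""
    study = pipeline.build_study(
        n_genes=120, n_variants=1500, seed=17, n_hidden=2,
        n_planted=30, beta_pre=0.8, beta_post=0.0, planted_min_maf=0.2,
    )
    pipeline.scan_all_cuts(study)
    return study


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
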