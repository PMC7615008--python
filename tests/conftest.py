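import numpy as np
import pytest

from mvpgs import (
    GeneratorTruth,
    default_study_config,
    simulate_study,
    standardize_for_analysis,
)


@pytest.fixture(scope="session")
def truth():
    return GeneratorTruth()


@pytest.fixture(scope="session")
def small_study(truth):
    """Four-cohort study at ~2% of the published sizes (fast, full layout)."""
    cfg = default_study_config(seed=42, scale=0.02, n_pcs=2)
    return simulate_study(cfg, truth)


@pytest.fixture(scope="session")
def small_std(small_study):
    return [standardize_for_analysis(ds) for ds in small_study]


@pytest.fixture
def rng():
    return np.random.default_rng(20539)
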