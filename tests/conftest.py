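import numpy as np
import pytest

from reef_regimes import GeneratorConfig, generate_profiles
from reef_regimes.harmonization import transform
from reef_regimes.regimes import assign_regimes, select_model


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def small_config():
    """Reduced-size generator config for fast unit tests."""
    return GeneratorConfig(n_sites=300, seed=11)


@pytest.fixture(scope="session")
def study_dataset():
    """Full-scale synthetic dataset at the study's sample size (n = 1027)."""
    config = GeneratorConfig(seed=1)
    profiles, truth = generate_profiles(config)
    return config, profiles, truth


@pytest.fixture(scope="session")
def study_fit(study_dataset):
    """BIC-selected mixture fit on the full-scale synthetic dataset.

    Session-scoped: the regime-recovery checks all share this single fit."""
    config, profiles, truth = study_dataset
    X, state = transform(profiles)
    model, table = select_model(X)
    assignments = assign_regimes(model, X)
    return {
        "config": config,
        "profiles": profiles,
        "truth": truth,
        "X": X,
        "state": state,
        "model": model,
        "bic_table": table,
        "assignments": assignments,
    }
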