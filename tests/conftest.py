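import numpy as np
import pytest

from gliofuse import (Cohort, FeatureCohortConfig, PhantomConfig,
                      generate_feature_cohort, generate_phantom_subject)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250901)


@pytest.fixture(scope="session")
def phantom_subject():
    """One full-size phantom: 4 modality volumes + tumor mask."""
    cfg = PhantomConfig(seed=11)
    volumes, mask = generate_phantom_subject(cfg)
    return cfg, volumes, mask


@pytest.fixture(scope="session")
def signal_cohort_small():
    """Small cohort with signal only in the T1wCE branch (fast model tests)."""
    cfg = FeatureCohortConfig(n_subjects=120, n_features=40,
                              effect_size=(0, 0, 0, 2.0, 0),
                              informative_fraction=0.25, seed=5)
    return generate_feature_cohort(cfg)


def make_random_cohort(rng, n=12, f=7, labeled=True, name="c"):
    y = rng.integers(0, 2, n) if labeled else None
    return Cohort([f"s{i:03d}" for i in range(n)],
                  rng.standard_normal((n, 5, f)), y, name, "stub")
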