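import dataclasses

import numpy as np
import pytest

from msi_ith import (
    PreprocessParams,
    SimulationConfig,
    preprocess_pipeline,
    simulate_dataset,
    simulate_two_arm_study,
)
from msi_ith.pipeline import (
    analyze_study,
    study_analysis_params,
    two_arm_study_conditions,
)


def tiny_config(**overrides) -> SimulationConfig:
    """A fast, fully featured simulation configuration for unit tests."""
    base = dict(
        mz_min=700.0,
        mz_max=900.0,
        n_channels=1500,
        n_peaks=20,
        roi_shape=(12, 12),
        n_clusters_per_roi=3,
        noise_sd=0.02,
        seed=11,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def tiny_dataset():
    cfg = tiny_config()
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def tiny_preprocessed(tiny_dataset):
    ds, _ = tiny_dataset
    return preprocess_pipeline(
        [ds], PreprocessParams(baseline_window=101, gmm_tol=1e-6)
    )


@pytest.fixture(scope="session")
def two_arm_report():
    """Full pooled pipeline on the standing two-arm study conditions.

    Shared across the heterogeneity-recovery checks; this is the most
    expensive fixture in the suite (roughly half a minute).
    """
    high, low = two_arm_study_conditions(seed=1)
    bundle = simulate_two_arm_study(high, low)
    prep, seg = study_analysis_params()
    report = analyze_study(
        bundle, preprocess_params=prep, divik_params=seg, max_pairs=2000, seed=1
    )
    return bundle, report


def separable_abundances(
    n_per_cluster=120, n_features=18, n_clusters=3, noise=0.02, seed=5
):
    """Noisy pixels around well-separated cluster profiles (pairwise
    profile correlations far below 0.3), plus planted labels."""
    rng = np.random.default_rng(seed)
    while True:
        profiles = rng.lognormal(0.0, 1.0, size=(n_clusters, n_features))
        c = np.corrcoef(profiles)
        if np.all(np.abs(c[np.triu_indices(n_clusters, 1)]) < 0.3):
            break
    labels = np.repeat(np.arange(n_clusters), n_per_cluster)
    values = profiles[labels] * (1 + rng.normal(0, noise, (len(labels), n_features)))
    return np.clip(values, 0, None), labels, profiles
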