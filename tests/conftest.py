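"""Shared fixtures: synthetic studies at two scales and their feature tables.

The full-scale study (2000 variants, generator defaults) feeds the
model-level statistical checks; the small study keeps structural tests fast.
Hypothesis runs derandomized so the suite is reproducible.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from structvep import pipeline, synthfix

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_study() -> synthfix.SyntheticStudy:
    cfg = synthfix.SyntheticConfig(
        seed=101, n_proteins=6, length_range=(60, 90), n_variants=300,
        msa_depth=25, sasa_points=120,
    )
    return synthfix.generate_study(cfg)


@pytest.fixture(scope="session")
def small_features(small_study):
    X, y, meta = pipeline.extract_study_features(small_study, schema="FULL")
    return X, y, meta


@pytest.fixture(scope="session")
def default_study() -> synthfix.SyntheticStudy:
    """Full-scale synthetic cohort at the generator's default conditions."""
    return synthfix.generate_study(synthfix.SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def default_features(default_study):
    X, y, meta = pipeline.extract_study_features(default_study, schema="FULL")
    return X, y, meta


@pytest.fixture(scope="session")
def binormal_scores():
    """Scores with a known population AUROC of 0.8 (binormal model)."""
    rng = np.random.default_rng(42)
    n = 600
    y = np.r_[np.ones(n // 2), np.zeros(n // 2)].astype(int)
    mu = synthfix.binormal_separation(0.8)
    s = rng.normal(0.0, 1.0, n) + mu * y
    return y, s
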