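"""Shared fixtures: synthetic cohorts (expensive, session-scoped) and cheap
Gaussian feature cohorts for classifier-level tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import breathauth as ba
from breathauth.features import SIGNATURE_FEATURES, FeatureMatrix
from breathauth.pipeline import extract_cohort_features


def make_gaussian_cohort(n_users: int, n_trials: int = 6,
                         segs_per_trial: int = 8, sep: float = 4.0,
                         seed: int = 0, n_features: int = 10,
                         ) -> dict[str, FeatureMatrix]:
    """Feature cohort with Gaussian per-user clusters, mean spacing ``sep``
    standard deviations along every axis — a fast stand-in for the full
    signal pipeline when only the classifier stages are under test."""
    rng = np.random.default_rng(seed)
    names = list(SIGNATURE_FEATURES[:n_features])
    out = {}
    for u in range(n_users):
        user = f"user{u:03d}"
        mu = np.full(n_features, sep * u, dtype=float)
        rows, labels = [], []
        for t in range(n_trials):
            trial_shift = rng.normal(0, 0.3, n_features)  # trial-level drift
            for s in range(segs_per_trial):
                rows.append(mu + trial_shift + rng.normal(0, 1, n_features))
                labels.append((user, f"trial{t:02d}", s))
        index = pd.MultiIndex.from_tuples(
            labels, names=["user_id", "trial_id", "segment_index"])
        out[user] = FeatureMatrix(pd.DataFrame(rows, index=index,
                                               columns=names))
    return out


@pytest.fixture(scope="session")
def gaussian_cohort3():
    return make_gaussian_cohort(3, seed=11)


@pytest.fixture(scope="session")
def gaussian_cohort5():
    return make_gaussian_cohort(5, seed=12)


@pytest.fixture(scope="session")
def cohort5_features():
    """Full-pipeline features of a well-separated 5-user synthetic cohort
    (10 trials each), the nominal study design."""
    profiles = ba.generate_profiles(5, separation=1.0, master_seed=42)
    signals = [ba.generate_trial(p, k) for p in profiles for k in range(10)]
    features, rejections = extract_cohort_features(signals)
    return features, rejections


@pytest.fixture(scope="session")
def cohort5_sep0_features():
    """Features of a 5-user cohort whose users are statistically identical
    (separation 0) — the exchangeable null of the identification problem."""
    profiles = ba.generate_profiles(5, separation=0.0, master_seed=42)
    signals = [ba.generate_trial(p, k) for p in profiles for k in range(10)]
    features, _ = extract_cohort_features(signals)
    return features
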