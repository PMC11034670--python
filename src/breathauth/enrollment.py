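"""Enrollment: the library of pairwise random-forest classifiers.

The multiclass identity problem is decomposed by class binarization: for n
enrolled users one binary random forest is trained per unordered user pair,
C(n, 2) models in total; enrolling an additional user adds exactly n models
and leaves the existing ones untouched. The library also stores each user's
training and held-out test features, split at the recording level (whole
trials go to one side, never straddling the split) so that the 19 segments
of one exhalation cannot leak information across the split.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .features import FeatureMatrix

__all__ = [
    "EnrollmentLibrary",
    "split_user",
    "library_size",
    "enroll",
    "add_user",
    "save_library",
    "load_library",
]

_FORMAT_VERSION = 1


def library_size(n: int) -> int:
    """Number of pairwise models for ``n`` users: C(n, 2) = n(n−1)/2.

    Adding one user to an n-user library adds exactly n models.
    """
    if n < 2:
        raise ValueError("a pairwise library needs at least 2 users")
    return n * (n - 1) // 2


def split_user(matrix: FeatureMatrix, train_frac: float = 0.6,
               seed: int | np.random.SeedSequence = 0,
               ) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Split one user's feature rows into train/test by whole trials.

    Trials are shuffled with the seed and the first
    ``round(train_frac * n_trials)`` go to training, clipped so both sides
    keep at least one trial (6/4 of 10 trials in the nominal design).
    """
    df = matrix.data
    trial_ids = list(dict.fromkeys(df.index.get_level_values("trial_id")))
    if len(trial_ids) < 2:
        raise ValueError("grouped split impossible with a single trial")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(trial_ids))
    n_train = int(round(train_frac * len(trial_ids)))
    n_train = min(max(n_train, 1), len(trial_ids) - 1)
    train_ids = set(order[:n_train])
    mask = df.index.get_level_values("trial_id").map(lambda t: t in train_ids)
    return (FeatureMatrix(df[mask], dict(matrix.tags)),
            FeatureMatrix(df[~mask], dict(matrix.tags)))


@dataclass
class EnrollmentLibrary:
    """Per-user features plus one trained classifier per user pair."""

    user_ids: list[str]
    pair_models: dict[tuple[str, str], RandomForestClassifier]
    train_features: dict[str, FeatureMatrix]
    test_features: dict[str, FeatureMatrix]
    selected_features: list[str]
    split_seed: int = 0
    rf_seed: int = 0
    rf_trees: int = 100
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.check_integrity()

    def check_integrity(self) -> None:
        n = len(self.user_ids)
        expect = {(self.user_ids[i], self.user_ids[j])
                  for i in range(n) for j in range(i + 1, n)}
        have = set(self.pair_models)
        if have != expect:
            missing = sorted(expect - have)
            extra = sorted(have - expect)
            raise ValueError(
                f"pair model set inconsistent; missing={missing} extra={extra}")
        for pair in self.pair_models:
            if pair[0] > pair[1]:
                raise ValueError(f"pair key {pair} not in canonical order")

    @property
    def n_users(self) -> int:
        return len(self.user_ids)

    def models_of(self, user_id: str) -> dict[tuple[str, str],
                                              RandomForestClassifier]:
        return {p: m for p, m in self.pair_models.items() if user_id in p}


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def _fit_pair(a: str, b: str, train: dict[str, FeatureMatrix],
              names: list[str], rf_trees: int, rf_seed: int,
              ) -> RandomForestClassifier:
    Xa = train[a].data[names].to_numpy(float)
    Xb = train[b].data[names].to_numpy(float)
    X = np.vstack([Xa, Xb])
    y = np.r_[[a] * len(Xa), [b] * len(Xb)]
    clf = RandomForestClassifier(n_estimators=rf_trees, random_state=rf_seed)
    clf.fit(X, y)
    return clf


def enroll(train_features: dict[str, FeatureMatrix],
           selected_features: list[str], *,
           test_features: dict[str, FeatureMatrix] | None = None,
           rf_trees: int = 100, rf_seed: int = 0,
           split_seed: int = 0) -> EnrollmentLibrary:
    """Train one binary classifier per user pair on the training features."""
    users = sorted(train_features)
    if len(users) < 2:
        raise ValueError("enrollment needs at least 2 users")
    for u in users:
        if len(train_features[u].data) == 0:
            raise ValueError(f"user {u!r} has no training rows")
    models = {}
    for i in range(len(users)):
        for j in range(i + 1, len(users)):
            a, b = users[i], users[j]
            models[_pair_key(a, b)] = _fit_pair(
                a, b, train_features, selected_features, rf_trees, rf_seed)
    return EnrollmentLibrary(users, models, dict(train_features),
                             dict(test_features or {}),
                             list(selected_features),
                             split_seed=split_seed, rf_seed=rf_seed,
                             rf_trees=rf_trees)


def add_user(library: EnrollmentLibrary, user_id: str,
             train: FeatureMatrix,
             test: FeatureMatrix | None = None) -> EnrollmentLibrary:
    """Enroll one more user: n new pair models, existing models reused."""
    if user_id in library.user_ids:
        raise ValueError(f"user {user_id!r} already enrolled")
    if len(train.data) == 0:
        raise ValueError(f"user {user_id!r} has no training rows")
    train_features = dict(library.train_features)
    train_features[user_id] = train
    test_features = dict(library.test_features)
    if test is not None:
        test_features[user_id] = test
    models = dict(library.pair_models)
    for other in library.user_ids:
        models[_pair_key(other, user_id)] = _fit_pair(
            other, user_id, train_features, library.selected_features,
            library.rf_trees, library.rf_seed)
    return EnrollmentLibrary(sorted(library.user_ids + [user_id]), models,
                             train_features, test_features,
                             list(library.selected_features),
                             split_seed=library.split_seed,
                             rf_seed=library.rf_seed,
                             rf_trees=library.rf_trees,
                             metadata=dict(library.metadata))


# ---------------------------------------------------------------------------
# persistence: directory with JSON manifest, per-pair model files, CSVs
# ---------------------------------------------------------------------------

def _feature_csv(fm: FeatureMatrix, path: Path) -> None:
    fm.data.to_csv(path)


def _read_feature_csv(path: Path) -> FeatureMatrix:
    df = pd.read_csv(path, index_col=[0, 1, 2])
    df.index = df.index.set_names(["user_id", "trial_id", "segment_index"])
    # trial ids round-trip as strings
    df.index = df.index.set_levels(
        [df.index.levels[0].astype(str), df.index.levels[1].astype(str),
         df.index.levels[2]], verify_integrity=False)
    return FeatureMatrix(df)


def save_library(library: EnrollmentLibrary, directory: str | Path) -> None:
    """Persist the library as manifest.json + one model file per pair.

    One file per model keeps loading embarrassingly parallel, matching how
    the pairwise design is meant to be deployed.
    """
    d = Path(directory)
    (d / "models").mkdir(parents=True, exist_ok=True)
    (d / "features").mkdir(exist_ok=True)
    pair_files = {}
    for (a, b), model in library.pair_models.items():
        fname = f"pair_{a}_{b}.bin"
        joblib.dump(model, d / "models" / fname)
        pair_files[f"{a}|{b}"] = fname
    for u, fm in library.train_features.items():
        _feature_csv(fm, d / "features" / f"train_{u}.csv")
    for u, fm in library.test_features.items():
        _feature_csv(fm, d / "features" / f"test_{u}.csv")
    manifest = {
        "format_version": _FORMAT_VERSION,
        "user_ids": library.user_ids,
        "selected_features": library.selected_features,
        "split_seed": library.split_seed,
        "rf_seed": library.rf_seed,
        "rf_trees": library.rf_trees,
        "pairs": pair_files,
        "test_users": sorted(library.test_features),
        "metadata": library.metadata,
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_library(directory: str | Path) -> EnrollmentLibrary:
    d = Path(directory)
    manifest_path = d / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no library manifest at {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    if manifest.get("format_version") != _FORMAT_VERSION:
        raise ValueError("library format version mismatch")
    models = {}
    for key, fname in manifest["pairs"].items():
        a, b = key.split("|")
        fpath = d / "models" / fname
        if not fpath.exists():
            raise ValueError(f"library integrity error: missing model for "
                             f"pair ({a}, {b})")
        models[(a, b)] = joblib.load(fpath)
    train = {u: _read_feature_csv(d / "features" / f"train_{u}.csv")
             for u in manifest["user_ids"]}
    test = {u: _read_feature_csv(d / "features" / f"test_{u}.csv")
            for u in manifest["test_users"]}
    return EnrollmentLibrary(manifest["user_ids"], models, train, test,
                             manifest["selected_features"],
                             split_seed=manifest["split_seed"],
                             rf_seed=manifest["rf_seed"],
                             rf_trees=manifest["rf_trees"],
                             metadata=manifest.get("metadata", {}))


def model_fingerprint(model: RandomForestClassifier,
                      probe: np.ndarray) -> str:
    """Digest of a model's predictions on a probe matrix; used to verify
    that add_user leaves existing models untouched."""
    pred = model.predict_proba(np.asarray(probe, float))
    return hashlib.sha256(np.ascontiguousarray(pred).tobytes()).hexdigest()
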