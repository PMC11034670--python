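"""End-to-end pipeline: signals → segments → MFDFA screening → features →
enrollment → evaluation, with a rejection log for every discarded segment."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import mfdfa
from .authentication import EvaluationReport, evaluate
from .config import PipelineConfig
from .enrollment import EnrollmentLibrary, enroll, split_user
from .features import (FeatureMatrix, SIGNATURE_FEATURES, extract_features,
                       select_by_importance, variance_filter)
from .preprocessing import prepare_trial
from .signal_io import BreathSignal, CohortManifest, read_signal

__all__ = ["SegmentRejection", "extract_cohort_features", "run_pipeline"]

log = logging.getLogger("breathauth")


@dataclass(frozen=True)
class SegmentRejection:
    user_id: str
    trial_id: str
    segment_index: int
    reason: str


def _iter_signals(manifest: CohortManifest, fs_hz: float):
    for user_id, trial_id, path in manifest.entries:
        yield read_signal(path, fs_hz, user_id=user_id, trial_id=trial_id)


def extract_cohort_features(signals, config: PipelineConfig | None = None,
                            ) -> tuple[dict[str, FeatureMatrix],
                                       list[SegmentRejection]]:
    """Segment, screen and featurize every trial of a cohort.

    ``signals`` is an iterable of :class:`BreathSignal` (or a
    :class:`CohortManifest`, in which case files are read at 10 kHz).
    Returns one FeatureMatrix per user plus the list of rejected segments
    with their reasons.
    """
    cfg = config or PipelineConfig()
    if isinstance(signals, CohortManifest):
        signals = _iter_signals(signals, 10_000.0)
    q_grid = mfdfa.default_q_grid(cfg.q_min, cfg.q_max, cfg.q_step)
    rejections: list[SegmentRejection] = []
    rows: dict[str, list[dict]] = {}
    labels: dict[str, list[tuple]] = {}
    for signal in signals:
        segments = prepare_trial(signal, cfg.window_fraction,
                                 cfg.slide_fraction, cfg.normalize_scope)
        scales = mfdfa.default_scales(len(segments[0]), cfg.scale_min,
                                      cfg.n_scales) if segments else None
        for seg in segments:
            idx = seg.source.start_index
            _, feats, validity = mfdfa.analyze_segment(
                seg.values, scales=scales, q_grid=q_grid,
                detrend_order=cfg.detrend_order, width_min=cfg.width_min,
                convexity_tol=cfg.convexity_tol)
            if not validity.valid:
                rej = SegmentRejection(signal.user_id, signal.trial_id, idx,
                                       validity.reason.value)
                rejections.append(rej)
                log.info("rejected segment %s/%s@%d: %s", signal.user_id,
                         signal.trial_id, idx, validity.reason.value)
                continue
            rows.setdefault(signal.user_id, []).append(
                extract_features(seg, feats))
            labels.setdefault(signal.user_id, []).append(
                (signal.user_id, signal.trial_id, idx))
    matrices = {}
    for user, user_rows in rows.items():
        index = pd.MultiIndex.from_tuples(
            labels[user], names=["user_id", "trial_id", "segment_index"])
        matrices[user] = FeatureMatrix(
            pd.DataFrame(user_rows, index=index,
                         columns=list(SIGNATURE_FEATURES)))
    return matrices, rejections


def run_pipeline(manifest_or_signals, config: PipelineConfig | None = None,
                 with_evaluation: bool = True,
                 ) -> tuple[EnrollmentLibrary, EvaluationReport | None,
                            list[SegmentRejection]]:
    """Run the full protocol and return library, report and rejection log.

    The evaluation re-splits and re-enrolls ``config.n_shuffles`` times; the
    returned library is the one enrolled on the first split (the state a
    deployed system would persist). ``with_evaluation=False`` stops after
    enrollment and returns ``None`` for the report.
    """
    cfg = config or PipelineConfig()
    features_by_user, rejections = extract_cohort_features(
        manifest_or_signals, cfg)
    if len(features_by_user) < 2:
        raise ValueError("pipeline needs at least 2 users with valid segments")
    # variance screen on the pooled matrix decides the candidate columns
    pooled = FeatureMatrix(
        pd.concat([m.data for m in features_by_user.values()]))
    surviving = variance_filter(pooled, cfg.variance_threshold).feature_names
    features_by_user = {u: m.restrict(surviving)
                        for u, m in features_by_user.items()}
    users = sorted(features_by_user)
    split_children = np.random.SeedSequence(cfg.seed).spawn(len(users))
    train, test = {}, {}
    for ui, u in enumerate(users):
        train[u], test[u] = split_user(features_by_user[u], cfg.train_frac,
                                       split_children[ui])
    selected = select_by_importance(train, top_k=cfg.top_k,
                                    rf_seed=cfg.rf_seed,
                                    rf_trees=cfg.rf_trees)
    library = enroll(train, selected, test_features=test,
                     rf_trees=cfg.rf_trees, rf_seed=cfg.rf_seed,
                     split_seed=cfg.seed)
    if not with_evaluation:
        return library, None, rejections
    report = evaluate(features_by_user, n_shuffles=cfg.n_shuffles,
                      seed=cfg.seed, train_frac=cfg.train_frac,
                      top_k=cfg.top_k, rf_trees=cfg.rf_trees,
                      weights=cfg.weights, eta_t=cfg.eta_t,
                      confirm_threshold=cfg.confirm_threshold,
                      alpha=cfg.alpha, selected_features=selected)
    report.config["pipeline"] = cfg.to_dict()
    report.config["n_rejected_segments"] = len(rejections)
    return library, report, rejections
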