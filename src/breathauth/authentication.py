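"""User confirmation, identification, vote fusion and evaluation.

Two confirmation engines answer "are you really user i?":

* **HT** — instance-based: the claimant's test features are compared with
  the stored training features of every pair of users containing user i via
  two-sample Hotelling T² tests at 99.9% confidence. In each pair the user
  with the higher p-value is the predicted identity (no prediction if both
  null hypotheses are rejected); the confidence of confirmation is
  η = 100·v/(n−1), the percentage of the n−1 pairwise decisions that favor
  the claimed user.

* **ML** — model-based: each of the n−1 stored pair classifiers involving
  user i votes "yes" if the majority of its per-row predictions equal i;
  η is again the percentage of favorable votes.

A user is confirmed when η reaches the confirmation threshold (50% by
default). Identification runs the confirmation block for every enrolled
identity, producing a vote vector V per engine; the engines are fused as a
convex combination V' = w₁·V_HT + w₂·V_ML and the identity is the unique
argmax of V' provided it reaches the identification threshold η_t.

Performance metrics: TCR = c/n·100 (confirmed fraction), precision
P = t/(t+f)·100 and accuracy E = t/n·100 over identification outcomes
(t correct, f incorrect, h not identified). The evaluation harness repeats
the whole protocol over reshuffled train/test splits and reports each
metric as mean ± 2 SD.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .enrollment import EnrollmentLibrary, enroll, split_user
from .features import FeatureMatrix, select_by_importance

__all__ = [
    "TestResult",
    "ConfirmationResult",
    "IdentificationResult",
    "EvaluationReport",
    "hotelling_t2",
    "confirm_ht",
    "confirm_ml",
    "combine_votes",
    "identify",
    "true_confirmation_rate",
    "precision_accuracy",
    "ztest_boundary",
    "evaluate",
]


# ---------------------------------------------------------------------------
# Hotelling's T-squared
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    dims: int
    n_a: int
    n_b: int
    ridged: bool = False


def hotelling_t2(sample_a: np.ndarray, sample_b: np.ndarray) -> TestResult:
    """Two-sample Hotelling T² test of equal means, pooled covariance.

    The p-value uses the exact transform
    F = (n_a + n_b − p − 1) / ((n_a + n_b − 2)·p) · T² with
    (p, n_a + n_b − p − 1) degrees of freedom. A near-singular pooled
    covariance is stabilized with a ridge of 1e−8·trace/p on the diagonal
    and flagged in the result.
    """
    A = np.atleast_2d(np.asarray(sample_a, float))
    B = np.atleast_2d(np.asarray(sample_b, float))
    na, p = A.shape
    nb, p2 = B.shape
    if p != p2:
        raise ValueError("samples must share dimensionality")
    if na + nb - 2 <= p:
        raise ValueError(
            f"insufficient samples ({na}+{nb}) for {p} dimensions")
    d = A.mean(axis=0) - B.mean(axis=0)
    Sa = np.cov(A, rowvar=False, ddof=1).reshape(p, p)
    Sb = np.cov(B, rowvar=False, ddof=1).reshape(p, p)
    S = ((na - 1) * Sa + (nb - 1) * Sb) / (na + nb - 2)
    ridged = False
    try:
        cond = np.linalg.cond(S)
    except np.linalg.LinAlgError:
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e12:
        S = S + np.eye(p) * (1e-8 * max(np.trace(S) / p, 1e-300))
        ridged = True
    try:
        sol = np.linalg.solve(S, d)
    except np.linalg.LinAlgError:
        S = S + np.eye(p) * (1e-8 * max(np.trace(S) / p, 1e-300))
        ridged = True
        sol = np.linalg.solve(S, d)
    t2 = float((na * nb) / (na + nb) * d @ sol)
    t2 = max(t2, 0.0)
    f_stat = (na + nb - p - 1) / ((na + nb - 2) * p) * t2
    p_value = float(stats.f.sf(f_stat, p, na + nb - p - 1))
    return TestResult(t2, p_value, p, na, nb, ridged)


# ---------------------------------------------------------------------------
# confirmation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfirmationResult:
    claimed_user: str
    v: int
    eta: float
    confirmed: bool
    method: str
    per_pair_detail: tuple = ()

    def __post_init__(self) -> None:
        if not 0 <= self.eta <= 100:
            raise ValueError("eta must be a percentage")


def _ht_pvalues(test_rows: np.ndarray, library: EnrollmentLibrary,
                names: list[str],
                cache: dict[str, float] | None = None) -> dict[str, float]:
    """p-value of the test sample against every user's training sample."""
    out = {} if cache is None else cache
    for u in library.user_ids:
        if u not in out:
            train = library.train_features[u].data[names].to_numpy(float)
            out[u] = hotelling_t2(test_rows, train).p_value
    return out


def confirm_ht(test_matrix: FeatureMatrix | np.ndarray, claimed_user: str,
               library: EnrollmentLibrary, *, alpha: float = 0.001,
               confirm_threshold: float = 50.0,
               _pvalue_cache: dict[str, float] | None = None,
               ) -> ConfirmationResult:
    """Hypothesis-testing confirmation of a claimed identity."""
    if claimed_user not in library.user_ids:
        raise KeyError(f"user {claimed_user!r} not enrolled")
    names = library.selected_features
    X = (test_matrix.data[names].to_numpy(float)
         if isinstance(test_matrix, FeatureMatrix) else
         np.asarray(test_matrix, float))
    if len(X) == 0:
        raise ValueError("empty test sample")
    pvals = _ht_pvalues(X, library, names, _pvalue_cache)
    p_i = pvals[claimed_user]
    v = 0
    detail = []
    for other in library.user_ids:
        if other == claimed_user:
            continue
        p_j = pvals[other]
        if p_i <= alpha and p_j <= alpha:
            decision = None  # both rejected: no prediction
        else:
            decision = claimed_user if p_i >= p_j else other
        if decision == claimed_user:
            v += 1
        detail.append((other, decision, (p_i, p_j)))
    n = library.n_users
    eta = 100.0 * v / (n - 1)
    return ConfirmationResult(claimed_user, v, eta,
                              eta >= confirm_threshold, "HT", tuple(detail))


def confirm_ml(test_matrix: FeatureMatrix | np.ndarray, claimed_user: str,
               library: EnrollmentLibrary, *,
               confirm_threshold: float = 50.0,
               vote_rule: str = "majority") -> ConfirmationResult:
    """Machine-learning confirmation of a claimed identity.

    Each pair model involving the claimed user predicts a class per test
    row; under the default committee rule a model votes "yes" when the
    majority of its row predictions equal the claimed user
    (``vote_rule="proportion"`` instead credits the fractional vote).
    """
    if claimed_user not in library.user_ids:
        raise KeyError(f"user {claimed_user!r} not enrolled")
    names = library.selected_features
    X = (test_matrix.data[names].to_numpy(float)
         if isinstance(test_matrix, FeatureMatrix) else
         np.asarray(test_matrix, float))
    if len(X) == 0:
        raise ValueError("empty test sample")
    models = library.models_of(claimed_user)
    v = 0.0
    detail = []
    for pair, model in sorted(models.items()):
        pred = model.predict(X)
        frac = float(np.mean(pred == claimed_user))
        if vote_rule == "majority":
            yes = frac > 0.5
            v += 1.0 if yes else 0.0
            detail.append((pair[0] if pair[1] == claimed_user else pair[1],
                           yes, frac))
        else:
            v += frac
            detail.append((pair[0] if pair[1] == claimed_user else pair[1],
                           frac > 0.5, frac))
    n = library.n_users
    eta = 100.0 * v / (n - 1)
    return ConfirmationResult(claimed_user, int(round(v)), eta,
                              eta >= confirm_threshold, "ML", tuple(detail))


# ---------------------------------------------------------------------------
# identification and fusion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IdentificationResult:
    vote_vectors: dict
    fused: np.ndarray
    weights: tuple
    user_order: tuple
    identified: str | None
    outcome: str  # true_positive / false_positive / not_identified / unknown


def combine_votes(vectors: list[np.ndarray],
                  weights: list[float]) -> np.ndarray:
    """Convex combination of per-method vote vectors (on the η % scale)."""
    if len(vectors) != len(weights):
        raise ValueError("one weight per vector required")
    w = np.asarray(weights, float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {w.sum()!r}")
    arrs = [np.asarray(v, float) for v in vectors]
    length = arrs[0].size
    if any(a.size != length for a in arrs):
        raise ValueError("vote vectors must have equal length")
    return sum(wi * a for wi, a in zip(w, arrs))


def identify(test_matrix: FeatureMatrix | np.ndarray,
             library: EnrollmentLibrary, *,
             methods: tuple[str, ...] = ("HT", "ML"),
             weights: tuple[float, ...] = (0.3, 0.7),
             eta_t: float = 55.0, alpha: float = 0.001,
             true_user: str | None = None) -> IdentificationResult:
    """Identify an unknown subject by exhaustive trial confirmation.

    The confirmation block runs once per enrolled identity and method; the
    fused vote vector's unique maximum is the identified user provided it
    reaches ``eta_t``; a tied maximum or a sub-threshold maximum yields no
    identification.
    """
    users = tuple(library.user_ids)
    vote_vectors: dict[str, np.ndarray] = {}
    ht_cache: dict[str, float] = {}
    for method in methods:
        etas = np.empty(len(users))
        for idx, trial_user in enumerate(users):
            if method == "HT":
                res = confirm_ht(test_matrix, trial_user, library,
                                 alpha=alpha, _pvalue_cache=ht_cache)
            elif method == "ML":
                res = confirm_ml(test_matrix, trial_user, library)
            else:
                raise ValueError(f"unknown method {method!r}")
            etas[idx] = res.eta
        vote_vectors[method] = etas
    fused = combine_votes([vote_vectors[m] for m in methods], list(weights))
    vmax = fused.max()
    argmaxes = np.flatnonzero(fused == vmax)
    if argmaxes.size != 1 or vmax < eta_t:
        identified = None
    else:
        identified = users[argmaxes[0]]
    if true_user is None:
        outcome = "unknown" if identified is not None else "not_identified"
    elif identified is None:
        outcome = "not_identified"
    elif identified == true_user:
        outcome = "true_positive"
    else:
        outcome = "false_positive"
    return IdentificationResult(vote_vectors, fused, tuple(weights), users,
                                identified, outcome)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def true_confirmation_rate(c: int, n: int) -> float:
    """TCR = c/n · 100, to one decimal."""
    if c < 0 or n <= 0 or c > n:
        raise ValueError("need 0 <= c <= n")
    return round(100.0 * c / n, 1)


def precision_accuracy(t: int, f: int, h: int, n: int,
                       ) -> tuple[float | None, float]:
    """Identification precision P = t/(t+f)·100 and accuracy E = t/n·100.

    P is undefined (None) when the algorithm never committed to an identity.
    """
    if min(t, f, h) < 0 or t + f + h != n:
        raise ValueError("outcomes must be non-negative and sum to n")
    precision = round(100.0 * t / (t + f), 1) if (t + f) > 0 else None
    accuracy = round(100.0 * t / n, 1)
    return precision, accuracy


# ---------------------------------------------------------------------------
# z-test decision-boundary diagnostic
# ---------------------------------------------------------------------------

def ztest_boundary(train_a: np.ndarray, train_b: np.ndarray,
                   grid_points: np.ndarray,
                   confidence: float = 0.999) -> np.ndarray:
    """Label 2-D grid points by per-dimension two-sided z-tests.

    A point belongs to a training class when the null hypothesis "the point
    is drawn from that class's distribution" is accepted in *both*
    dimensions at the stated confidence. Returns an array of labels from
    {"a", "b", "both", "neither"} — a direct visualization of how coarse an
    axis-aligned hypothesis-test boundary is compared to a learned one.
    """
    A = np.atleast_2d(np.asarray(train_a, float))
    B = np.atleast_2d(np.asarray(train_b, float))
    G = np.atleast_2d(np.asarray(grid_points, float))
    if A.shape[1] != 2 or B.shape[1] != 2 or G.shape[1] != 2:
        raise ValueError("ztest_boundary operates on a 2-D feature plane")
    alpha = 1.0 - confidence
    labels = np.empty(len(G), dtype=object)
    accept = {}
    for name, T in (("a", A), ("b", B)):
        mu, sd = T.mean(axis=0), T.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError(f"training set {name} has a zero-variance dimension")
        z = (G - mu) / sd
        pv = 2.0 * stats.norm.sf(np.abs(z))
        accept[name] = np.all(pv > alpha, axis=1)
    labels[accept["a"] & accept["b"]] = "both"
    labels[accept["a"] & ~accept["b"]] = "a"
    labels[~accept["a"] & accept["b"]] = "b"
    labels[~accept["a"] & ~accept["b"]] = "neither"
    return labels


# ---------------------------------------------------------------------------
# shuffle-evaluation harness
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Per-shuffle confirmation/identification outcomes and μ ± 2σ summaries."""

    n: int
    n_shuffles: int
    per_shuffle: pd.DataFrame
    summaries: dict[str, dict[str, float]]
    config: dict = field(default_factory=dict)

    def format_summary(self, key: str) -> str:
        s = self.summaries[key]
        return f"{s['mean']:.1f}±{s['two_sigma']:.1f}%"

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "n": self.n,
            "n_shuffles": self.n_shuffles,
            "summaries": self.summaries,
            "config": self.config,
            "per_shuffle": self.per_shuffle.to_dict(orient="records"),
        }, indent=2))

    def per_shuffle_csv(self, path: str | Path) -> None:
        self.per_shuffle.to_csv(path, index=False)


def _summary(values: list[float]) -> dict[str, float]:
    arr = np.asarray([v for v in values if v is not None], float)
    if arr.size == 0:
        return {"mean": float("nan"), "two_sigma": float("nan")}
    return {"mean": float(arr.mean()),
            "two_sigma": float(2.0 * arr.std(ddof=0))}


def evaluate(cohort_features: dict[str, FeatureMatrix], *,
             n_shuffles: int = 66, seed: int = 0, train_frac: float = 0.6,
             top_k: int = 10, rf_trees: int = 100,
             weights: tuple[float, float] = (0.3, 0.7),
             eta_t: float = 55.0, confirm_threshold: float = 50.0,
             alpha: float = 0.001,
             selected_features: list[str] | None = None) -> EvaluationReport:
    """Repeat the full confirmation + identification protocol over shuffles.

    Each shuffle re-splits every user's trials, re-enrolls the library and
    runs (i) a genuine confirmation test per user and engine, giving (c, u),
    and (ii) an identification test per user, giving (t, f, h). Feature
    selection is performed once, on the first split, and the selected names
    are reused across shuffles; all randomness derives from ``seed``.
    """
    users = sorted(cohort_features)
    n = len(users)
    if n < 2:
        raise ValueError("evaluation needs at least 2 users")
    root = np.random.SeedSequence(seed)
    shuffle_seeds = root.spawn(n_shuffles)
    rows = []
    for k in range(n_shuffles):
        split_children = shuffle_seeds[k].spawn(n)
        train, test = {}, {}
        for ui, u in enumerate(users):
            tr, te = split_user(cohort_features[u], train_frac,
                                split_children[ui])
            train[u], test[u] = tr, te
        if selected_features is None:
            selected_features = select_by_importance(train, top_k=top_k,
                                                     rf_trees=rf_trees)
        library = enroll(train, selected_features, test_features=test,
                         rf_trees=rf_trees)
        c = {"HT": 0, "ML": 0}
        for u in users:
            res_ht = confirm_ht(test[u], u, library, alpha=alpha,
                                confirm_threshold=confirm_threshold)
            res_ml = confirm_ml(test[u], u, library,
                                confirm_threshold=confirm_threshold)
            c["HT"] += int(res_ht.confirmed)
            c["ML"] += int(res_ml.confirmed)
        t = f = h = 0
        for u in users:
            res = identify(test[u], library, weights=weights, eta_t=eta_t,
                           alpha=alpha, true_user=u)
            if res.outcome == "true_positive":
                t += 1
            elif res.outcome == "false_positive":
                f += 1
            else:
                h += 1
        P, E = precision_accuracy(t, f, h, n)
        rows.append({
            "shuffle": k,
            "c_ht": c["HT"], "u_ht": n - c["HT"],
            "c_ml": c["ML"], "u_ml": n - c["ML"],
            "tcr_ht": true_confirmation_rate(c["HT"], n),
            "tcr_ml": true_confirmation_rate(c["ML"], n),
            "t": t, "f": f, "h": h,
            "precision": P, "accuracy": E,
        })
    table = pd.DataFrame(rows)
    summaries = {
        "TCR_HT": _summary(list(table["tcr_ht"])),
        "TCR_ML": _summary(list(table["tcr_ml"])),
        "P": _summary(list(table["precision"])),
        "E": _summary(list(table["accuracy"])),
    }
    config = {"n_shuffles": n_shuffles, "seed": seed,
              "train_frac": train_frac, "weights": list(weights),
              "eta_t": eta_t, "confirm_threshold": confirm_threshold,
              "alpha": alpha, "rf_trees": rf_trees,
              "selected_features": list(selected_features)}
    return EvaluationReport(n, n_shuffles, table, summaries, config)
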