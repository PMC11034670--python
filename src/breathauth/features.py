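"""The ten-feature breath signature and the feature-reduction cascade.

Each valid z-scored segment is summarized by ten dimensionless statistics,
listed in decreasing classification importance:

1.  ``beta`` — singularity strength at the multifractal spectrum maximum,
2.  ``abs_sum_changes`` — total absolute first difference,
3.  ``ar10_coef3`` — 3rd coefficient of an AR(10) model,
4.  ``n_peaks_s1`` — count of local maxima with support 1,
5.  ``n_cwt_peaks_w1`` — Ricker-CWT peak count at width 1,
6.  ``pacf_lag3`` — partial autocorrelation at lag 3,
7.  ``omega`` — multifractal spectrum width,
8.  ``ar10_coef4`` — 4th AR(10) coefficient,
9.  ``n_cwt_peaks_w5`` — Ricker-CWT peak count over widths 1..5,
10. ``kurtosis_g2`` — adjusted Fisher–Pearson excess kurtosis.

The reduction cascade that selected them from a much larger automated
candidate pool is also implemented, operating over an extensible registry:
a low-variance filter (on min–max-scaled columns), a pairwise-correlation
filter, removal of absolute-scale features (means, extrema, quantiles —
anything that would let a classifier key on how hard a subject blows rather
than on the structure of the flow), and a prevalence vote over the
impurity-based importances of all pairwise random-forest classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import find_peaks_cwt
from sklearn.ensemble import RandomForestClassifier
from statsmodels.tsa.ar_model import AutoReg
from statsmodels.tsa.stattools import pacf as _sm_pacf

from .mfdfa import SpectrumFeatures
from .preprocessing import NormalizedSegment

__all__ = [
    "SIGNATURE_FEATURES",
    "FEATURE_REGISTRY",
    "FeatureMatrix",
    "absolute_sum_of_changes",
    "ar_coefficient",
    "number_peaks",
    "number_cwt_peaks",
    "partial_autocorrelation",
    "kurtosis_g2",
    "extract_features",
    "variance_filter",
    "correlation_filter",
    "drop_absolute_scale",
    "select_by_importance",
]


# ---------------------------------------------------------------------------
# scalar extractors
# ---------------------------------------------------------------------------

def absolute_sum_of_changes(x: np.ndarray) -> float:
    """Sum of absolute consecutive differences, Σ|x_{i+1} − x_i|."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    return float(np.abs(np.diff(x)).sum())


def ar_coefficient(x: np.ndarray, order: int = 10, k: int = 3) -> float:
    """k-th lag coefficient of an AR(order) model.

    Fitted by conditional least squares (OLS on the lagged design matrix
    with intercept), which is deterministic and standard.
    """
    x = np.asarray(x, dtype=float)
    if not 1 <= k <= order:
        raise ValueError("k must lie in 1..order")
    if x.size <= order + 10:
        raise ValueError("series too short for the requested order")
    if x.std() == 0:
        raise ValueError("constant series has a singular AR design")
    fit = AutoReg(x, lags=order, trend="c", old_names=False).fit()
    return float(fit.params[k])  # params[0] is the intercept


def number_peaks(x: np.ndarray, support: int = 1) -> int:
    """Count interior values strictly greater than all ``support`` neighbors
    on each side; boundary points without a full neighborhood never count."""
    x = np.asarray(x, dtype=float)
    if x.size < 2 * support + 1:
        raise ValueError("series shorter than the peak neighborhood")
    core = x[support:-support]
    is_peak = np.ones(core.size, dtype=bool)
    for off in range(1, support + 1):
        is_peak &= core > x[support - off:-support - off]
        right = x[support + off:][:core.size]
        is_peak &= core > right
    return int(is_peak.sum())


def _ricker(points: int, a: float) -> np.ndarray:
    """Ricker (Mexican-hat) wavelet, the normalized negative second
    derivative of a Gaussian of width ``a``."""
    amp = 2.0 / (np.sqrt(3.0 * a) * np.pi ** 0.25)
    t = np.arange(points) - (points - 1.0) / 2.0
    return amp * (1.0 - (t / a) ** 2) * np.exp(-(t ** 2) / (2.0 * a ** 2))


def number_cwt_peaks(x: np.ndarray, max_width: int = 1,
                     min_snr: float = 3.0) -> int:
    """Ridge-line peak count on the Ricker CWT over widths 1..max_width.

    A peak must trace a ridge across the width scales and exceed
    ``min_snr`` times the noise floor of the width-1 transform; the default
    of 3 keeps single-sample noise wiggles from registering as peaks while
    isolated bumps of the bracketed widths are retained. Constant input has
    no structure and counts zero.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 samples")
    if np.ptp(x) == 0:
        return 0
    widths = np.arange(1, max_width + 1)
    return int(len(find_peaks_cwt(x, widths, wavelet=_ricker,
                                  min_snr=min_snr)))


def partial_autocorrelation(x: np.ndarray, lag: int = 3) -> float:
    """PACF at ``lag`` via the Levinson–Durbin recursion on the biased
    sample autocorrelation."""
    x = np.asarray(x, dtype=float)
    if x.size <= 10 * lag:
        raise ValueError("series too short for a stable PACF estimate")
    if x.std() == 0:
        raise ValueError("constant series has undefined autocorrelation")
    return float(_sm_pacf(x, nlags=lag, method="ldb")[lag])


def kurtosis_g2(x: np.ndarray) -> float:
    """Adjusted Fisher–Pearson standardized 4th moment G2 (excess, so the
    Gaussian value is 0); the small-sample bias-corrected estimator."""
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 samples")
    if x.std() == 0:
        raise ValueError("zero variance")
    return float(stats.kurtosis(x, fisher=True, bias=False))


# ---------------------------------------------------------------------------
# feature registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureSpec:
    func: Callable[[np.ndarray], float]
    absolute_scale: bool = False


#: Signature features in the fixed column order used everywhere.
SIGNATURE_FEATURES: tuple[str, ...] = (
    "beta", "abs_sum_changes", "ar10_coef3", "n_peaks_s1", "n_cwt_peaks_w1",
    "pacf_lag3", "omega", "ar10_coef4", "n_cwt_peaks_w5", "kurtosis_g2",
)

#: Extensible candidate pool. ``beta`` and ``omega`` are filled from the
#: MFDFA stage rather than recomputed here. The absolute-scale entries stand
#: in for the larger automated pool's raw-amplitude statistics and exist so
#: the exclusion rule has something real to act on.
FEATURE_REGISTRY: dict[str, FeatureSpec] = {
    "beta": FeatureSpec(lambda x: np.nan),
    "abs_sum_changes": FeatureSpec(absolute_sum_of_changes),
    "ar10_coef3": FeatureSpec(lambda x: ar_coefficient(x, 10, 3)),
    "n_peaks_s1": FeatureSpec(lambda x: float(number_peaks(x, 1))),
    "n_cwt_peaks_w1": FeatureSpec(lambda x: float(number_cwt_peaks(x, 1))),
    "pacf_lag3": FeatureSpec(lambda x: partial_autocorrelation(x, 3)),
    "omega": FeatureSpec(lambda x: np.nan),
    "ar10_coef4": FeatureSpec(lambda x: ar_coefficient(x, 10, 4)),
    "n_cwt_peaks_w5": FeatureSpec(lambda x: float(number_cwt_peaks(x, 5))),
    "kurtosis_g2": FeatureSpec(kurtosis_g2),
    # absolute-scale candidates, excluded by drop_absolute_scale
    "mean": FeatureSpec(lambda x: float(np.mean(x)), absolute_scale=True),
    "maximum": FeatureSpec(lambda x: float(np.max(x)), absolute_scale=True),
    "minimum": FeatureSpec(lambda x: float(np.min(x)), absolute_scale=True),
    "quantile_q90": FeatureSpec(lambda x: float(np.quantile(x, 0.9)),
                                absolute_scale=True),
}


@dataclass
class FeatureMatrix:
    """Segment-by-feature table with (user, trial, segment) row labels."""

    data: pd.DataFrame
    tags: dict[str, bool] = field(default_factory=dict)  # absolute-scale flags

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("row labels must be unique")
        self.tags = {c: self.tags.get(c, False) for c in self.data.columns}

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def restrict(self, names: Sequence[str]) -> "FeatureMatrix":
        return FeatureMatrix(self.data[list(names)].copy(),
                             {n: self.tags[n] for n in names})

    def rows_of_user(self, user_id: str) -> "FeatureMatrix":
        return FeatureMatrix(self.data.loc[[user_id]], dict(self.tags))

    def to_csv(self, path) -> None:
        self.data.to_csv(path)


def extract_features(segment: NormalizedSegment,
                     spectrum_features: SpectrumFeatures,
                     names: Sequence[str] = SIGNATURE_FEATURES) -> dict[str, float]:
    """Evaluate the named registry features on one valid segment."""
    x = segment.values
    out: dict[str, float] = {}
    for name in names:
        if name == "beta":
            out[name] = float(spectrum_features.beta)
        elif name == "omega":
            out[name] = float(spectrum_features.omega)
        else:
            out[name] = float(FEATURE_REGISTRY[name].func(x))
    return out


# ---------------------------------------------------------------------------
# reduction cascade
# ---------------------------------------------------------------------------

def variance_filter(matrix: FeatureMatrix,
                    threshold: float = 0.01) -> FeatureMatrix:
    """Drop columns whose variance after min–max scaling to [0, 1] is below
    ``threshold`` — a 1% cut that is meaningful across heterogeneous units."""
    df = matrix.data
    if len(df) < 2:
        raise ValueError("need at least 2 rows")
    keep = []
    for col in df.columns:
        v = df[col].to_numpy(float)
        rng = np.ptp(v)
        if rng == 0:
            continue
        scaled = (v - v.min()) / rng
        if scaled.var() >= threshold:
            keep.append(col)
    if not keep:
        raise ValueError("variance filter removed every column")
    return matrix.restrict(keep)


def correlation_filter(matrix: FeatureMatrix,
                       threshold: float = 0.8) -> FeatureMatrix:
    """Scan columns in order; drop any whose absolute Pearson correlation
    with an already-retained column exceeds ``threshold``."""
    df = matrix.data
    if len(df) < 3:
        raise ValueError("need at least 3 rows")
    corr = df.corr().abs()
    kept: list[str] = []
    for col in df.columns:
        if all(corr.loc[col, k] <= threshold or np.isnan(corr.loc[col, k])
               for k in kept):
            kept.append(col)
    return matrix.restrict(kept)


def drop_absolute_scale(matrix: FeatureMatrix) -> FeatureMatrix:
    """Remove columns tagged as deriving from the raw signal amplitude."""
    keep = [c for c in matrix.feature_names if not matrix.tags.get(c, False)]
    return matrix.restrict(keep)


def select_by_importance(per_user_training: Mapping[str, FeatureMatrix],
                         top_k: int = 10, rf_seed: int = 0,
                         rf_trees: int = 100) -> list[str]:
    """Prevalence vote over pairwise random-forest importances.

    For every unordered user pair a seeded random forest is fitted on the
    two users' training rows; its ``top_k`` features by impurity importance
    are recorded. The ``top_k`` most prevalent names are returned, ties
    broken by mean importance rank and then by name.
    """
    users = sorted(per_user_training)
    if len(users) < 2:
        raise ValueError("need at least 2 users")
    columns = per_user_training[users[0]].feature_names
    if len(columns) <= top_k:
        return list(columns)
    prevalence = {c: 0 for c in columns}
    rank_sums = {c: 0.0 for c in columns}
    n_pairs = 0
    for ai in range(len(users)):
        for bi in range(ai + 1, len(users)):
            a, b = users[ai], users[bi]
            Xa = per_user_training[a].data[columns].to_numpy(float)
            Xb = per_user_training[b].data[columns].to_numpy(float)
            X = np.vstack([Xa, Xb])
            y = np.r_[np.zeros(len(Xa)), np.ones(len(Xb))]
            clf = RandomForestClassifier(n_estimators=rf_trees,
                                         random_state=rf_seed)
            clf.fit(X, y)
            order = np.argsort(-clf.feature_importances_, kind="stable")
            for rank, idx in enumerate(order):
                rank_sums[columns[idx]] += rank
                if rank < top_k:
                    prevalence[columns[idx]] += 1
            n_pairs += 1
    ranked = sorted(columns,
                    key=lambda c: (-prevalence[c], rank_sums[c] / n_pairs, c))
    return ranked[:top_k]
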