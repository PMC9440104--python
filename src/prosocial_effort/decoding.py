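"""Self-other representational overlap via cross-validated linear decoding.

For each participant, a linear support vector machine is trained to decode
whether a trial's reward target was the self or the other (charity or
stranger) from five trial features: choice decision time, task accuracy,
task reaction time, effort level, and reward level. Choice itself is never
a feature — that would leak the very behavior the overlap score is later
correlated with. Performance is the mean out-of-fold accuracy over
stratified five-fold cross-validation with features z-scored inside each
training fold (margin classifiers need comparable scales; the test fold is
transformed with the training fold's parameters).

Accuracy near chance (50%) means the multivariate signatures of self and
other trials overlap; high accuracy means they are distinct. Per-participant
accuracies feed three group-level analyses: an OLS regression of the
prosocial delta on accuracy (the overlap-vs-effort relationship), a paired
t-test comparing self-vs-charity with self-vs-stranger decoders, and an OLS
of accuracy on a participant covariate (e.g. trait compassion).

Accuracies are reported in percent; regressions use proportion units
(divide by 100) — conversion is centralized here.

A multiclass variant (`decode_labels`) can decode the trial's effort or
reward level instead of the target, via a one-vs-rest reduction of the same
linear classifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .design import TARGET_SELF

#: the five permitted trial features, in canonical column order
DEFAULT_FEATURES = ("decision_time", "task_accuracy", "task_rt", "effort_rank", "reward")

#: SVM inverse regularization, conventional default, never tuned
SVM_C = 1.0


@dataclass(frozen=True)
class FeatureMatrix:
    """Feature rows and self/other labels for one participant's target pair."""

    X: np.ndarray
    y: np.ndarray  # 0 = self, 1 = other
    feature_names: tuple[str, ...]
    pair: tuple[str, str]
    participant_id: str

    def __post_init__(self) -> None:
        if self.X.shape[0] != len(self.y):
            raise ValueError("X and y row counts differ")
        if np.isnan(self.X).any():
            raise ValueError("feature matrix contains missing values")


def build_features(
    trials: pd.DataFrame,
    pair: tuple[str, str],
    features: tuple[str, ...] = DEFAULT_FEATURES,
    include_decision_time: bool = True,
) -> FeatureMatrix:
    """Assemble the decoding matrix for one participant and one target pair.

    ``pair`` is (self_target, other_target). Setting
    ``include_decision_time=False`` ablates the choice-decision-time feature
    (a robustness variant that removes any residual circularity with the
    choice analyses). Requesting ``choice`` as a feature is an error.
    """
    if "choice" in features:
        raise ValueError("choice must never be a decoding feature")
    missing = [f for f in features if f not in trials.columns]
    if missing:
        raise KeyError(f"trial table lacks feature column(s) {missing}")
    if not include_decision_time:
        features = tuple(f for f in features if f != "decision_time")

    a, b = pair
    sub = trials[trials["target"].isin(pair)]
    for t in pair:
        if not (sub["target"] == t).any():
            raise ValueError(f"no trials for target {t!r}")
    X = sub.loc[:, list(features)].to_numpy(dtype=float)
    y = (sub["target"] == b).to_numpy(dtype=int)
    pid = str(sub["participant_id"].iloc[0]) if "participant_id" in sub else "unknown"
    return FeatureMatrix(X=X, y=y, feature_names=tuple(features), pair=pair, participant_id=pid)


@dataclass(frozen=True)
class DecodingResult:
    """Cross-validated decoding accuracy for one participant and pair."""

    participant_id: str
    pair: tuple[str, str]
    fold_accuracies: tuple[float, ...]
    mean_accuracy: float  # percent
    seed: int
    feature_names: tuple[str, ...]


def decode_pair(fm: FeatureMatrix, k_folds: int = 5, seed: int = 0) -> DecodingResult:
    """Linear-SVM decoding accuracy under stratified k-fold cross-validation.

    Folds are stratified by label and shuffled with ``seed``; features are
    standardized on each training fold only. Returns per-fold and mean
    out-of-fold accuracy in percent.
    """
    counts = np.bincount(fm.y)
    if len(counts) < 2 or counts.min() < k_folds:
        raise ValueError(
            f"need at least {k_folds} trials per class, got class counts {counts.tolist()}"
        )
    cv = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    accs = []
    for train, test in cv.split(fm.X, fm.y):
        clf = make_pipeline(StandardScaler(), SVC(kernel="linear", C=SVM_C))
        clf.fit(fm.X[train], fm.y[train])
        accs.append(float(np.mean(clf.predict(fm.X[test]) == fm.y[test])))
    return DecodingResult(
        participant_id=fm.participant_id,
        pair=fm.pair,
        fold_accuracies=tuple(accs),
        mean_accuracy=100.0 * float(np.mean(accs)),
        seed=seed,
        feature_names=fm.feature_names,
    )


def decode_cohort(
    trials: pd.DataFrame,
    other_target: str,
    k_folds: int = 5,
    seed: int = 0,
    include_decision_time: bool = True,
) -> pd.DataFrame:
    """Per-participant self-vs-other decoding accuracies for one pair (tidy)."""
    rows = []
    for i, (pid, sub) in enumerate(sorted(trials.groupby("participant_id"))):
        fm = build_features(
            sub, (TARGET_SELF, other_target), include_decision_time=include_decision_time
        )
        res = decode_pair(fm, k_folds=k_folds, seed=(seed * 9973 + i) % (2**31))
        rows.append(
            {
                "participant_id": pid,
                "pair": f"{TARGET_SELF}_vs_{other_target}",
                "accuracy_pct": res.mean_accuracy,
            }
        )
    return pd.DataFrame(rows)


def decode_labels(
    trials: pd.DataFrame,
    label: str = "effort_rank",
    features: tuple[str, ...] = ("decision_time", "task_accuracy", "task_rt"),
    k_folds: int = 5,
    seed: int = 0,
) -> DecodingResult:
    """Multiclass variant: decode effort or reward level (one-vs-rest SVM).

    The decoded label's own column must not appear among the features.
    """
    if label in features or "choice" in features:
        raise ValueError("decoded label and choice cannot be features")
    X = trials.loc[:, list(features)].to_numpy(dtype=float)
    y = trials[label].to_numpy()
    classes, y_idx = np.unique(y, return_inverse=True)
    if np.bincount(y_idx).min() < k_folds:
        raise ValueError(f"need at least {k_folds} trials per class of {label!r}")
    cv = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    accs = []
    for train, test in cv.split(X, y_idx):
        clf = make_pipeline(
            StandardScaler(), OneVsRestClassifier(SVC(kernel="linear", C=SVM_C))
        )
        clf.fit(X[train], y_idx[train])
        accs.append(float(np.mean(clf.predict(X[test]) == y_idx[test])))
    pid = str(trials["participant_id"].iloc[0]) if "participant_id" in trials else "unknown"
    return DecodingResult(
        participant_id=pid,
        pair=(label, "multiclass"),
        fold_accuracies=tuple(accs),
        mean_accuracy=100.0 * float(np.mean(accs)),
        seed=seed,
        feature_names=tuple(features),
    )


@dataclass(frozen=True)
class RegressionResult:
    """Simple OLS slope with its t-test and Pearson r."""

    slope: float
    intercept: float
    se: float
    t: float
    df: int
    p: float
    r: float


def _ols(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    if len(x) != len(y):
        raise ValueError("x and y must be paired")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0.0:
        raise ValueError("zero variance in the predictor")
    res = sps.linregress(x, y)
    df = len(x) - 2
    t = res.slope / res.stderr if res.stderr > 0 else float("inf")
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        se=float(res.stderr),
        t=float(t),
        df=df,
        p=float(res.pvalue),
        r=float(res.rvalue),
    )


def overlap_regression(deltas: np.ndarray | pd.Series, accuracies_pct: np.ndarray | pd.Series) -> RegressionResult:
    """OLS of the prosocial delta on decoding accuracy (proportion units).

    A negative slope means participants whose self/other trial signatures
    are easier to tell apart (less representational overlap) invest less
    effort for the other target.
    """
    acc = np.asarray(accuracies_pct, dtype=float) / 100.0
    return _ols(acc, np.asarray(deltas, dtype=float))


def compare_decoders(
    acc_charity: np.ndarray | pd.Series, acc_stranger: np.ndarray | pd.Series
) -> "DecoderComparison":
    """Paired t-test of self-vs-stranger minus self-vs-charity accuracy.

    Inputs are percent accuracies paired by participant; the difference is
    reported in percentage points with effect size r.
    """
    a = np.asarray(acc_charity, dtype=float)
    b = np.asarray(acc_stranger, dtype=float)
    if a.shape != b.shape:
        raise ValueError("accuracies must be paired by participant")
    diff = b - a
    t, p = sps.ttest_rel(b, a)
    df = len(a) - 1
    r = math.copysign(math.sqrt(t**2 / (t**2 + df)), t) if np.isfinite(t) else float("nan")
    return DecoderComparison(
        mean_diff_pct=float(np.mean(diff)), t=float(t), df=df, p=float(p), r=r
    )


@dataclass(frozen=True)
class DecoderComparison:
    mean_diff_pct: float
    t: float
    df: int
    p: float
    r: float


def covariate_correlation(
    accuracies_pct: np.ndarray | pd.Series, covariate: np.ndarray | pd.Series
) -> RegressionResult:
    """OLS of decoding accuracy (proportion units) on a participant covariate."""
    acc = np.asarray(accuracies_pct, dtype=float) / 100.0
    cov = np.asarray(covariate, dtype=float)
    if np.std(cov) == 0.0:
        raise ValueError("zero variance in the covariate")
    return _ols(cov, acc)
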