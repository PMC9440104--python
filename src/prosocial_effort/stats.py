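"""Behavioral descriptives and a two-stage surrogate for choice regressions.

`choice_proportions` summarizes effortful-choice rates by effort or reward
level and target: the cell value is the mean of per-participant proportions,
with a normal-approximation 95% CI across participants.

`cohort_summary` gives each participant's effortful-choice rate per target
and the prosocial delta for each non-self target — rate(other) - rate(self);
negative deltas mean less effort invested for the other.

`two_stage_choice_regression` is a summary-statistics stand-in for a full
trialwise mixed-effects choice model: stage 1 fits a weakly ridge-penalized
logistic regression of choice on normalized effort, normalized reward, and
target dummies (vs. self) per participant; stage 2 tests each coefficient
against zero across participants with a one-sample t-test and effect size
r = sqrt(t^2/(t^2+df)). Signs and relative magnitudes of the group-level
coefficients — not their z-values — are the quantities comparable to a full
mixed model. Effort and reward enter as their 5 ordinal levels mapped
linearly onto [-1, 1] ({-1, -0.5, 0, 0.5, 1}); the ridge penalty (sklearn
C = 1.0) keeps coefficients finite under perfect separation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression

from .design import TARGET_SELF

#: z quantile for the 95% normal-approximation interval
_Z95 = 1.959963984540054

#: inverse ridge strength for the stage-1 logistic fits
STAGE1_C = 1.0


def normalize_levels(values: pd.Series | np.ndarray, levels: list | None = None) -> np.ndarray:
    """Map ordinal condition levels linearly onto [-1, 1].

    With the standard 5 levels the result is {-1, -0.5, 0, 0.5, 1}.
    """
    values = np.asarray(values)
    if levels is None:
        levels = sorted(np.unique(values))
    rank = {lvl: i for i, lvl in enumerate(levels)}
    idx = np.array([rank[v] for v in values], dtype=float)
    return 2.0 * idx / (len(levels) - 1) - 1.0


def per_participant_rates(trials: pd.DataFrame) -> pd.DataFrame:
    """Effortful-choice rate per participant x target (tidy)."""
    return (
        trials.groupby(["participant_id", "target"])["choice"]
        .mean()
        .rename("rate")
        .reset_index()
    )


def choice_proportions(trials: pd.DataFrame, by: str = "effort") -> pd.DataFrame:
    """Mean effortful-choice proportion by condition level and target.

    ``by`` is ``"effort"`` (groups on effort_rank) or ``"reward"``. Each
    cell averages participant-level proportions; the 95% CI is the normal
    approximation across participants. Cells with a single participant get
    ``ci_undefined=True``.
    """
    col = {"effort": "effort_rank", "reward": "reward"}.get(by)
    if col is None:
        raise ValueError(f"by must be 'effort' or 'reward', got {by!r}")
    if len(trials) == 0:
        raise ValueError("empty trial table")
    per = trials.groupby(["participant_id", "target", col])["choice"].mean().rename("prop")
    rows = []
    for (target, level), grp in per.reset_index().groupby(["target", col]):
        props = grp["prop"].to_numpy()
        n = len(props)
        mean = float(np.mean(props))
        if n > 1:
            se = float(np.std(props, ddof=1) / math.sqrt(n))
            lo_ci, hi_ci = mean - _Z95 * se, mean + _Z95 * se
            undef = False
        else:
            lo_ci = hi_ci = float("nan")
            undef = True
        rows.append(
            {
                "target": target,
                col: level,
                "proportion": mean,
                "ci_low": lo_ci,
                "ci_high": hi_ci,
                "n_participants": n,
                "ci_undefined": undef,
            }
        )
    return pd.DataFrame(rows)


def cohort_summary(trials: pd.DataFrame, covariate: pd.Series | None = None) -> pd.DataFrame:
    """Per-participant rates per target, prosocial deltas, and covariate.

    Wide table: one row per participant, columns ``rate_<target>``,
    ``delta_<other>`` = rate(other) - rate(self) for each non-self target,
    overall ``rate_overall``, and optionally ``covariate`` (indexed by
    participant_id).
    """
    rates = per_participant_rates(trials).pivot(
        index="participant_id", columns="target", values="rate"
    )
    out = rates.add_prefix("rate_")
    out["rate_overall"] = trials.groupby("participant_id")["choice"].mean()
    if TARGET_SELF in rates.columns:
        for target in rates.columns:
            if target != TARGET_SELF:
                out[f"delta_{target}"] = rates[target] - rates[TARGET_SELF]
    if covariate is not None:
        out["covariate"] = covariate
    return out.reset_index()


def prosocial_delta(summary: pd.DataFrame, other_target: str) -> pd.Series:
    """Per-participant rate(other) - rate(self) from a cohort summary."""
    col = f"delta_{other_target}"
    if col not in summary.columns:
        raise KeyError(f"no delta column for target {other_target!r}")
    return summary.set_index("participant_id")[col]


@dataclass(frozen=True)
class TwoStageResult:
    """Stage-1 coefficients per participant and stage-2 group tests."""

    coefficients: pd.DataFrame  # one row per participant, one col per term
    group: pd.DataFrame  # term, mean, t, df, p, effect_r


def two_stage_choice_regression(trials: pd.DataFrame) -> TwoStageResult:
    """Two-stage logistic surrogate for a trialwise mixed choice model.

    Stage 1: per participant, ridge-penalized logistic regression of choice
    on normalized effort, normalized reward, and target dummies (vs. self).
    Stage 2: one-sample t-test of each coefficient against zero across
    participants, with effect size r.
    """
    targets = sorted(trials["target"].unique())
    others = [t for t in targets if t != TARGET_SELF]
    effort_levels = sorted(trials["effort_rank"].unique())
    reward_levels = sorted(trials["reward"].unique())

    coef_rows = []
    for pid, sub in trials.groupby("participant_id"):
        X = np.column_stack(
            [normalize_levels(sub["effort_rank"], effort_levels),
             normalize_levels(sub["reward"], reward_levels)]
            + [(sub["target"] == t).to_numpy(dtype=float) for t in others]
        )
        y = sub["choice"].to_numpy(dtype=int)
        if y.min() == y.max():
            # degenerate all-same-choice participant: coefficients are 0 at
            # the ridge optimum apart from the intercept; skip the fit
            coefs = np.zeros(X.shape[1])
        else:
            # l2 (ridge) penalty is sklearn's default; C = 1.0 keeps
            # coefficients finite under perfect separation
            model = LogisticRegression(C=STAGE1_C, solver="lbfgs", max_iter=2000)
            model.fit(X, y)
            coefs = model.coef_[0]
        row = {"participant_id": pid, "effort": coefs[0], "reward": coefs[1]}
        row.update({f"target_{t}": c for t, c in zip(others, coefs[2:])})
        coef_rows.append(row)
    coefficients = pd.DataFrame(coef_rows)

    group_rows = []
    terms = [c for c in coefficients.columns if c != "participant_id"]
    for term in terms:
        vals = coefficients[term].to_numpy()
        t, p = sps.ttest_1samp(vals, 0.0)
        df = len(vals) - 1
        r = math.copysign(math.sqrt(t**2 / (t**2 + df)), t) if np.isfinite(t) else float("nan")
        group_rows.append(
            {"term": term, "mean": float(np.mean(vals)), "t": float(t), "df": df,
             "p": float(p), "effect_r": r}
        )
    return TwoStageResult(coefficients=coefficients, group=pd.DataFrame(group_rows))
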