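"""Generative simulation of prosocial effort-choice cohorts.

Choices are simulated from the same discounting + softmax family that the
fitting module estimates: on each trial the effortful option's subjective
value is compared with the fixed 1-credit baseline and a Bernoulli choice is
drawn from the softmax probability, using per-participant, per-target k and
beta. An optional fatigue term drifts the effortful-choice log-odds linearly
over the session (default off).

Behavioral features are drawn per target from a simple parametric model —
Gaussian choice decision time truncated to (0, choice deadline], Bernoulli
task accuracy, Gaussian task reaction time truncated to (0, response
deadline] — so the separability of self vs. other feature distributions is
directly controllable for the decoding analyses.

Cohort-level filtering mirrors the preregistered exclusions: participants
choosing the effortful option on 85% or more of trials, or on 15% or fewer,
are removed (cutoffs inclusive, configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .design import StudyDesign, build_design, effort_scaled
from .discounting import subjective_value

TRIAL_COLUMNS = [
    "participant_id",
    "study_id",
    "trial_index",
    "target",
    "effort_rank",
    "addend",
    "reward",
    "choice",
    "decision_time",
    "task_accuracy",
    "task_rt",
]


@dataclass(frozen=True)
class FeatureModel:
    """Per-target distribution of the three behavioral features."""

    decision_time_mean: float = 1.4
    decision_time_sd: float = 0.45
    accuracy_rate: float = 0.94
    task_rt_mean: float = 1.5
    task_rt_sd: float = 0.4

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy_rate <= 1.0:
            raise ValueError("accuracy_rate must lie in [0, 1]")
        if self.decision_time_sd <= 0 or self.task_rt_sd <= 0:
            raise ValueError("feature standard deviations must be > 0")

    def shifted(self, delta: float) -> "FeatureModel":
        """Shift both time means by ``delta`` seconds (controls separability)."""
        return replace(
            self,
            decision_time_mean=self.decision_time_mean + delta,
            task_rt_mean=self.task_rt_mean + delta,
        )


@dataclass(frozen=True)
class SimParams:
    """Generative parameters for one simulated participant.

    k and beta are keyed by target; ``form`` names the discounting form the
    choices are generated from. ``fatigue_slope`` adds a linear drift to the
    effortful-choice log-odds over the session (value reached at the final
    trial; 0 disables it).
    """

    k: Mapping[str, float]
    beta: Mapping[str, float]
    form: str = "linear"
    features: Mapping[str, FeatureModel] = field(default_factory=dict)
    fatigue_slope: float = 0.0

    def __post_init__(self) -> None:
        if any(b < 0 for b in self.beta.values()):
            raise ValueError("beta must be >= 0")


def _trunc_normal(
    rng: np.random.Generator, mean: float, sd: float, upper: float, size: int
) -> np.ndarray:
    a, b = (0.0 - mean) / sd, (upper - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_participant(
    design: StudyDesign,
    params: SimParams,
    participant_id: str = "p000",
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate one participant's full trial table.

    The trial schedule, choices, and features all derive from ``seed``
    (an int or a Generator), so identical seeds give byte-identical tables.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    schedule = build_design(design, seed=int(rng.integers(2**31)))

    uniq, inverse = np.unique(schedule["target"].to_numpy(), return_inverse=True)
    missing = set(uniq) - set(params.k)
    if missing:
        raise KeyError(f"no generative parameters for target(s) {sorted(missing)}")
    k_trial = np.array([params.k[t] for t in uniq])[inverse]
    b_trial = np.array([params.beta[t] for t in uniq])[inverse]

    sv = subjective_value(
        params.form,
        k_trial,
        schedule["reward"].to_numpy(dtype=float),
        effort_scaled(schedule["effort_rank"]),
    )
    logit = b_trial * (sv - design.baseline_reward)
    if params.fatigue_slope != 0.0:
        n = len(schedule)
        frac = (schedule["trial_index"].to_numpy(dtype=float) - 1.0) / max(n - 1, 1)
        logit = logit + params.fatigue_slope * frac
    p = expit(logit)
    choice = (rng.random(len(schedule)) < p).astype(int)

    n = len(schedule)
    decision_time = np.empty(n)
    accuracy = np.empty(n, dtype=int)
    task_rt = np.empty(n)
    for target in uniq:
        fm = params.features.get(target, FeatureModel())
        mask = schedule["target"].to_numpy() == target
        m = int(mask.sum())
        decision_time[mask] = _trunc_normal(
            rng, fm.decision_time_mean, fm.decision_time_sd, design.choice_deadline, m
        )
        accuracy[mask] = (rng.random(m) < fm.accuracy_rate).astype(int)
        task_rt[mask] = _trunc_normal(
            rng, fm.task_rt_mean, fm.task_rt_sd, design.response_deadline, m
        )

    out = schedule.copy()
    out.insert(0, "participant_id", participant_id)
    out.insert(1, "study_id", design.study_id)
    out["choice"] = choice
    out["decision_time"] = np.round(decision_time, 6)
    out["task_accuracy"] = accuracy
    out["task_rt"] = np.round(task_rt, 6)
    return out[TRIAL_COLUMNS]


def simulate_cohort(
    design: StudyDesign,
    param_sampler: Callable[[np.random.Generator], SimParams] | Sequence[SimParams],
    n_participants: int,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[SimParams]]:
    """Simulate ``n_participants`` independent participants.

    ``param_sampler`` is either a callable drawing a fresh SimParams from a
    Generator, or an explicit sequence of SimParams (one per participant).
    Per-participant seeds are spawned deterministically from ``seed``.
    Returns the concatenated trial table and the parameters actually used.
    """
    children = np.random.SeedSequence(seed).spawn(n_participants)
    frames, used = [], []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        if callable(param_sampler):
            params = param_sampler(rng)
        else:
            params = param_sampler[i]
        used.append(params)
        pid = f"p{i:03d}"
        frames.append(simulate_participant(design, params, participant_id=pid, seed=rng))
    return pd.concat(frames, ignore_index=True), used


def simulate_null_features(
    design: StudyDesign,
    pair: tuple[str, str] = ("self", "charity"),
    feature_model: FeatureModel | None = None,
    n_per_class: int | None = None,
    participant_id: str = "p000",
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate a label-uninformative trial table for decoder calibration.

    All five decoding features — decision time, task accuracy, task RT,
    effort rank, reward — are drawn i.i.d. from the same distributions
    regardless of the target label (effort and reward uniformly over their
    levels), so a classifier's expected out-of-sample accuracy is exactly
    chance. Note this differs from a factorial trial schedule, where the
    exact balancing of the discrete effort/reward cells across targets
    induces a negative train/test dependence under cross-validation and a
    below-chance bias ("anti-learning") even when nothing is decodable.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    fm = feature_model or FeatureModel()
    m = n_per_class or design.trials_per_target
    n = 2 * m
    ranks = sorted(set(design.effort_rank_map.values()))
    frame = pd.DataFrame(
        {
            "participant_id": participant_id,
            "study_id": design.study_id,
            "trial_index": np.arange(1, n + 1),
            "target": np.repeat(list(pair), m),
            "effort_rank": rng.choice(ranks, size=n),
            "reward": rng.choice(design.reward_levels, size=n),
            "choice": 0,
            "decision_time": _trunc_normal(
                rng, fm.decision_time_mean, fm.decision_time_sd, design.choice_deadline, n
            ),
            "task_accuracy": (rng.random(n) < fm.accuracy_rate).astype(int),
            "task_rt": _trunc_normal(
                rng, fm.task_rt_mean, fm.task_rt_sd, design.response_deadline, n
            ),
        }
    )
    frame["addend"] = 0
    return frame[TRIAL_COLUMNS]


@dataclass(frozen=True)
class ExclusionReport:
    """Partition of a cohort by the effortful-choice-rate exclusion filter."""

    kept_ids: tuple[str, ...]
    excluded_high_ids: tuple[str, ...]
    excluded_low_ids: tuple[str, ...]
    cutoffs: tuple[float, float] = (0.85, 0.15)

    @property
    def all_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.kept_ids + self.excluded_high_ids + self.excluded_low_ids))

    def as_frame(self) -> pd.DataFrame:
        rows = (
            [(pid, "kept") for pid in self.kept_ids]
            + [(pid, "excluded_high") for pid in self.excluded_high_ids]
            + [(pid, "excluded_low") for pid in self.excluded_low_ids]
        )
        return pd.DataFrame(sorted(rows), columns=["participant_id", "status"])


def apply_exclusions(
    trials: pd.DataFrame, hi: float = 0.85, lo: float = 0.15
) -> ExclusionReport:
    """Flag participants with near-ceiling or near-floor effortful-choice rates.

    A participant is excluded if their overall effortful proportion is at or
    above ``hi`` or at or below ``lo`` (both cutoffs inclusive).
    """
    if len(trials) == 0:
        raise ValueError("empty cohort")
    rates = trials.groupby("participant_id")["choice"].mean()
    high = tuple(sorted(rates.index[rates >= hi]))
    low = tuple(sorted(rates.index[rates <= lo]))
    kept = tuple(sorted(set(rates.index) - set(high) - set(low)))
    return ExclusionReport(kept_ids=kept, excluded_high_ids=high, excluded_low_ids=low, cutoffs=(hi, lo))
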