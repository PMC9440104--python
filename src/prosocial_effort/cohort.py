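"""Default cohort-level generative model for simulated studies.

Per-participant parameters are drawn to emulate the qualitative structure
of the empirical cohorts:

- Discount rates are ordered on average self < charity < stranger (people
  discount rewards by effort more steeply for others), with wide individual
  variation including near-zero discounters who end up excluded for ceiling
  effortful-choice rates — the empirical studies excluded large fractions
  of recruits at the 85% ceiling.
- Inverse temperatures are lower for other targets than for self (choices
  for others are less consistent).
- Behavioral features for other targets are shifted relative to self
  (slower decisions and task responses, slightly lower accuracy), with the
  shift growing with that participant's discounting gap k_other - k_self.
  This `feature_link` coupling makes self-other feature separability — and
  hence decoding accuracy — covary with how differently the participant
  values the other, which is the structure behind the overlap-vs-effort
  relationship.
- An optional compassion-like covariate decreases with the feature shift
  (more compassionate participants represent others more like themselves).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import StudyDesign, TARGET_SELF
from .simulate import FeatureModel, SimParams


@dataclass(frozen=True)
class CohortModel:
    """Hyperparameters of the per-participant parameter distribution."""

    form: str = "linear"
    k_self_mean: float = 0.90
    k_self_sd: float = 0.25
    k_gap_charity_mean: float = 0.10
    k_gap_stranger_extra_mean: float = 0.12
    k_gap_sd: float = 0.08
    k_max: float = 1.4
    beta_low: float = 3.0
    beta_high: float = 10.0
    beta_other_shrink: tuple[float, float] = (0.6, 1.0)
    #: self-target behavioral feature model
    features_self: FeatureModel = field(
        default_factory=lambda: FeatureModel(
            decision_time_mean=1.25,
            decision_time_sd=0.45,
            accuracy_rate=0.95,
            task_rt_mean=1.45,
            task_rt_sd=0.40,
        )
    )
    #: constant decision/RT slowdown for other targets (s)
    base_shift: float = 0.10
    #: extra slowdown per unit of (k_other - k_self) (s); couples feature
    #: separability to prosocial discounting
    feature_link: float = 0.60
    accuracy_drop_other: float = 0.02
    fatigue_slope: float = 0.0

    def sample(self, rng: np.random.Generator, design: StudyDesign) -> SimParams:
        """Draw one participant's generative parameters."""
        k_self = float(np.clip(rng.normal(self.k_self_mean, self.k_self_sd), 0.0, self.k_max))
        k = {TARGET_SELF: k_self}
        gap_prev = 0.0
        for target in design.targets:
            if target == TARGET_SELF:
                continue
            mean = (
                self.k_gap_charity_mean
                if target == "charity"
                else self.k_gap_charity_mean + self.k_gap_stranger_extra_mean
            )
            gap = gap_prev + abs(rng.normal(mean - gap_prev, self.k_gap_sd))
            k[target] = float(np.clip(k_self + gap, 0.0, self.k_max))
            gap_prev = gap

        beta_self = float(rng.uniform(self.beta_low, self.beta_high))
        beta = {TARGET_SELF: beta_self}
        features = {TARGET_SELF: self.features_self}
        for target in design.targets:
            if target == TARGET_SELF:
                continue
            beta[target] = beta_self * float(rng.uniform(*self.beta_other_shrink))
            shift = self.base_shift + self.feature_link * max(k[target] - k_self, 0.0)
            fm = self.features_self.shifted(shift)
            features[target] = FeatureModel(
                decision_time_mean=fm.decision_time_mean,
                decision_time_sd=fm.decision_time_sd,
                accuracy_rate=max(fm.accuracy_rate - self.accuracy_drop_other, 0.0),
                task_rt_mean=fm.task_rt_mean,
                task_rt_sd=fm.task_rt_sd,
            )
        return SimParams(
            k=k, beta=beta, form=self.form, features=features, fatigue_slope=self.fatigue_slope
        )

    def covariate(self, rng: np.random.Generator, params: SimParams) -> float:
        """Compassion-like score (1-5) decreasing with self-other feature shift.

        Coupling strength and noise are set so that, through the shift ->
        decodability chain, covariate-accuracy correlations land in the
        moderate negative range reported for trait compassion.
        """
        others = [t for t in params.k if t != TARGET_SELF]
        if not others:
            return float(np.clip(rng.normal(3.5, 0.6), 1.0, 5.0))
        shift = float(
            np.mean(
                [
                    params.features[t].decision_time_mean
                    - params.features[TARGET_SELF].decision_time_mean
                    for t in others
                ]
            )
        )
        return float(np.clip(rng.normal(3.6 - 3.5 * shift, 0.35), 1.0, 5.0))
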