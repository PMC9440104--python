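"""Effort-discounting model family, softmax choice rule, and likelihood.

The subjective value of the effortful option is the offered reward
discounted by the (scaled) effort required to earn it, under one of three
functional forms:

    linear      SV = reward * (1 - k * effort)
    parabolic   SV = reward * (1 - k * effort**2)
    hyperbolic  SV = reward / (1 + k * effort)

with effort scaled to (0, 1] (rank / 5) and a discount-rate parameter k.
Choices between the effortful option and the fixed 1-credit baseline follow
a two-option softmax — the logistic of the subjective-value difference
scaled by an inverse temperature beta (credits^-1):

    P(effortful) = 1 / (1 + exp(-beta * (SV_effortful - SV_baseline)))

Each of k and beta may be shared across reward targets or estimated
per target (self / charity / stranger), giving a family of
3 forms x 2 k-schemes x 2 beta-schemes = 12 models. Negative subjective
values are allowed (a strongly discounted reward can be worth less than
nothing); they are not floored at zero.

Parameter bounds: k in [0, 1.5] for the linear and parabolic forms (values
above 1 push SV below zero at high effort) and [0, 20] for the hyperbolic
form, beta in [0, 30] credits^-1 — wide enough to span indifference to
near-deterministic choice on the 2-12 credit reward range without numeric
overflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

FORMS = ("linear", "parabolic", "hyperbolic")
SCHEMES = ("shared", "per_target")

#: probability clip for the log-likelihood, avoids log(0)
LIK_EPS = 1e-10

K_BOUNDS = {"linear": (0.0, 1.5), "parabolic": (0.0, 1.5), "hyperbolic": (0.0, 20.0)}
BETA_BOUNDS = (0.0, 30.0)


def subjective_value(form: str, k, reward, effort_scaled):
    """Effort-discounted value of a reward, in credits (vectorized)."""
    k = np.asarray(k, dtype=float)
    reward = np.asarray(reward, dtype=float)
    e = np.asarray(effort_scaled, dtype=float)
    if form == "linear":
        return reward * (1.0 - k * e)
    if form == "parabolic":
        return reward * (1.0 - k * e**2)
    if form == "hyperbolic":
        return reward / (1.0 + k * e)
    raise ValueError(f"unknown discounting form {form!r}; expected one of {FORMS}")


def choice_probability(sv_effortful, sv_baseline, beta):
    """Two-option softmax: P(choose effortful) as a logistic in the value gap."""
    beta = np.asarray(beta, dtype=float)
    if np.any(beta < 0):
        raise ValueError("softmax inverse temperature beta must be >= 0")
    return expit(beta * (np.asarray(sv_effortful, float) - np.asarray(sv_baseline, float)))


@dataclass(frozen=True)
class ModelSpec:
    """One member of the discounting family: form x k-scheme x beta-scheme."""

    form: str
    k_scheme: str
    beta_scheme: str
    targets: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.form not in FORMS:
            raise ValueError(f"unknown form {self.form!r}")
        if self.k_scheme not in SCHEMES or self.beta_scheme not in SCHEMES:
            raise ValueError(f"schemes must be one of {SCHEMES}")
        if not self.targets:
            raise ValueError("targets must be non-empty")

    @property
    def name(self) -> str:
        k = "Target" if self.k_scheme == "per_target" else "Shared"
        b = "Target" if self.beta_scheme == "per_target" else "Shared"
        return f"{self.form}_k{k}_beta{b}"

    @property
    def n_params(self) -> int:
        nk = len(self.targets) if self.k_scheme == "per_target" else 1
        nb = len(self.targets) if self.beta_scheme == "per_target" else 1
        return nk + nb

    @property
    def param_names(self) -> tuple[str, ...]:
        ks = (
            [f"k_{t}" for t in self.targets]
            if self.k_scheme == "per_target"
            else ["k"]
        )
        bs = (
            [f"beta_{t}" for t in self.targets]
            if self.beta_scheme == "per_target"
            else ["beta"]
        )
        return tuple(ks + bs)

    def bounds(self) -> list[tuple[float, float]]:
        kb = K_BOUNDS[self.form]
        nk = len(self.targets) if self.k_scheme == "per_target" else 1
        nb = len(self.targets) if self.beta_scheme == "per_target" else 1
        return [kb] * nk + [BETA_BOUNDS] * nb

    def pack(self, params: "ParamVector") -> np.ndarray:
        """Flatten a ParamVector into the optimizer's coordinate order."""
        ks = (
            [params.k[t] for t in self.targets]
            if self.k_scheme == "per_target"
            else [params.k[self.targets[0]]]
        )
        bs = (
            [params.beta[t] for t in self.targets]
            if self.beta_scheme == "per_target"
            else [params.beta[self.targets[0]]]
        )
        return np.array(ks + bs, dtype=float)

    def unpack(self, x: Sequence[float]) -> "ParamVector":
        x = np.asarray(x, dtype=float)
        if len(x) != self.n_params:
            raise ValueError(f"expected {self.n_params} parameters, got {len(x)}")
        nk = len(self.targets) if self.k_scheme == "per_target" else 1
        ks, bs = x[:nk], x[nk:]
        if self.k_scheme == "per_target":
            k = dict(zip(self.targets, ks))
        else:
            k = {t: ks[0] for t in self.targets}
        if self.beta_scheme == "per_target":
            beta = dict(zip(self.targets, bs))
        else:
            beta = {t: bs[0] for t in self.targets}
        return ParamVector(k=k, beta=beta)

    def random_params(self, rng: np.random.Generator) -> "ParamVector":
        lo, hi = np.array(self.bounds()).T
        return self.unpack(rng.uniform(lo, hi))


@dataclass(frozen=True)
class ParamVector:
    """Discount rates and inverse temperatures keyed by reward target.

    Shared-parameter schemes store the same value under every target, so a
    ParamVector can always be evaluated trial-by-trial without consulting
    the scheme.
    """

    k: Mapping[str, float]
    beta: Mapping[str, float]

    def __post_init__(self) -> None:
        if any(b < 0 for b in self.beta.values()):
            raise ValueError("beta must be >= 0")

    def as_series(self, spec: ModelSpec) -> pd.Series:
        return pd.Series(dict(zip(spec.param_names, spec.pack(self))))


def model_family(targets: Sequence[str]) -> list[ModelSpec]:
    """All 12 specs (3 forms x 2 k-schemes x 2 beta-schemes) for a target set."""
    return [
        ModelSpec(form=f, k_scheme=ks, beta_scheme=bs, targets=tuple(targets))
        for f in FORMS
        for ks in SCHEMES
        for bs in SCHEMES
    ]


def spec_from_name(name: str, targets: Sequence[str]) -> ModelSpec:
    """Parse a canonical model name like ``linear_kTarget_betaShared``."""
    try:
        form, kpart, bpart = name.split("_")
        scheme = {"kTarget": "per_target", "kShared": "shared"}[kpart]
        bscheme = {"betaTarget": "per_target", "betaShared": "shared"}[bpart]
    except (ValueError, KeyError) as err:
        raise ValueError(f"unrecognized model name {name!r}") from err
    return ModelSpec(form=form, k_scheme=scheme, beta_scheme=bscheme, targets=tuple(targets))


def trial_choice_probabilities(
    params: ParamVector,
    form: str,
    trials: pd.DataFrame,
    baseline_reward: float = 1.0,
) -> np.ndarray:
    """P(effortful) for each row of a trial table under the given parameters.

    ``trials`` needs columns ``target, effort_rank, reward``. Raises KeyError
    if a trial's target has no parameter.
    """
    targets = trials["target"].to_numpy()
    # map each trial to its target's parameters
    uniq, inverse = np.unique(targets, return_inverse=True)
    k_trial = np.array([params.k[t] for t in uniq])[inverse]
    b_trial = np.array([params.beta[t] for t in uniq])[inverse]
    e = trials["effort_rank"].to_numpy(dtype=float) / 5.0
    sv = subjective_value(form, k_trial, trials["reward"].to_numpy(dtype=float), e)
    return choice_probability(sv, baseline_reward, b_trial)


def negative_log_likelihood(
    params: ParamVector,
    spec: ModelSpec,
    trials: pd.DataFrame,
    baseline_reward: float = 1.0,
) -> float:
    """Bernoulli negative log-likelihood of observed choices.

    NLL = -sum_t [ c_t ln p_t + (1 - c_t) ln(1 - p_t) ], with p clipped to
    [eps, 1 - eps], eps = 1e-10.
    """
    if len(trials) == 0:
        raise ValueError("empty trial list")
    missing = set(trials["target"]) - set(params.k) | set(trials["target"]) - set(params.beta)
    if missing:
        raise KeyError(f"no parameters for target(s) {sorted(missing)}")
    p = trial_choice_probabilities(params, spec.form, trials, baseline_reward)
    p = np.clip(p, LIK_EPS, 1.0 - LIK_EPS)
    c = trials["choice"].to_numpy(dtype=float)
    return float(-np.sum(c * np.log(p) + (1.0 - c) * np.log(1.0 - p)))
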