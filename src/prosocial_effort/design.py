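"""Factorial study designs and the digit-addition effort task rule.

Two within-subject designs are supported. Study 1 crosses 5 effort levels
(addends 1, 3, 5, 7, 9) with 5 reward levels (2, 4, 6, 8, 12 credits) and
2 reward targets (self, charity). Study 2 uses addends 1, 3, 5, 6, 7 and
adds a third target (an intragroup stranger). Each participant makes 75
choices per target (150 trials in Study 1, 225 in Study 2), every
target x effort x reward cell appearing equally often, in a seeded
pseudo-random order.

On every trial the participant chooses between a fixed baseline option
(1 credit, minimal effort) and an effortful option: add the trial's addend
to each of three digits and report the units digit of each sum.

Effort enters the discounting models as an ordinal rank 1..5. In Study 1
the add-7 condition was rated harder than add-9 in pre-testing, so the rank
map places addend 7 above addend 9; Study 2 addends are rank-ordered
naturally. Rank maps are configurable per design.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

REWARD_LEVELS: tuple[int, ...] = (2, 4, 6, 8, 12)

#: addend -> ordinal effort rank (1 = easiest .. 5 = hardest)
EFFORT_RANKS_STUDY1: dict[int, int] = {1: 1, 3: 2, 5: 3, 9: 4, 7: 5}
EFFORT_RANKS_STUDY2: dict[int, int] = {1: 1, 3: 2, 5: 3, 6: 4, 7: 5}

TARGET_SELF = "self"
TARGET_CHARITY = "charity"
TARGET_STRANGER = "stranger"

#: number of rank levels the ordinal effort scale is divided by
N_EFFORT_RANKS = 5


@dataclass(frozen=True)
class StudyDesign:
    """One study's factorial trial design and task timing constants."""

    study_id: int
    effort_levels: tuple[int, ...]
    reward_levels: tuple[int, ...] = REWARD_LEVELS
    targets: tuple[str, ...] = (TARGET_SELF, TARGET_CHARITY)
    trials_per_target: int = 75
    baseline_reward: float = 1.0
    choice_deadline: float = 5.0
    response_deadline: float = 3.0
    effort_rank_map: Mapping[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.effort_levels) != 5 or len(self.reward_levels) != 5:
            raise ValueError("designs require 5 effort and 5 reward levels")
        n_cells = len(self.effort_levels) * len(self.reward_levels)
        if self.trials_per_target % n_cells != 0:
            raise ValueError(
                f"trials_per_target={self.trials_per_target} not divisible "
                f"by the {n_cells} effort x reward cells"
            )
        ranks = sorted(self.effort_rank_map.values())
        if sorted(self.effort_rank_map) != sorted(self.effort_levels) or ranks != [1, 2, 3, 4, 5]:
            raise ValueError("effort_rank_map must map the effort levels onto ranks 1..5")

    @property
    def n_trials(self) -> int:
        return self.trials_per_target * len(self.targets)

    @property
    def repeats_per_cell(self) -> int:
        return self.trials_per_target // (len(self.effort_levels) * len(self.reward_levels))

    def effort_rank(self, addend: int) -> int:
        return self.effort_rank_map[addend]

    def with_targets(self, targets: Sequence[str]) -> "StudyDesign":
        return replace(self, targets=tuple(targets))


def study1_design(**overrides) -> StudyDesign:
    """Study 1: addends {1,3,5,7,9}, targets self and charity."""
    kwargs = dict(
        study_id=1,
        effort_levels=(1, 3, 5, 7, 9),
        targets=(TARGET_SELF, TARGET_CHARITY),
        effort_rank_map=dict(EFFORT_RANKS_STUDY1),
    )
    kwargs.update(overrides)
    return StudyDesign(**kwargs)


def study2_design(**overrides) -> StudyDesign:
    """Study 2: addends {1,3,5,6,7}, targets self, charity, stranger."""
    kwargs = dict(
        study_id=2,
        effort_levels=(1, 3, 5, 6, 7),
        targets=(TARGET_SELF, TARGET_CHARITY, TARGET_STRANGER),
        effort_rank_map=dict(EFFORT_RANKS_STUDY2),
    )
    kwargs.update(overrides)
    return StudyDesign(**kwargs)


def get_design(study_id: int, **overrides) -> StudyDesign:
    if study_id == 1:
        return study1_design(**overrides)
    if study_id == 2:
        return study2_design(**overrides)
    raise ValueError(f"unknown study_id {study_id!r}; expected 1 or 2")


def build_design(study: int | StudyDesign, seed: int) -> pd.DataFrame:
    """Build one participant's ordered trial schedule.

    The balanced cell list (every target x effort x reward combination
    repeated ``trials_per_target / 25`` times) is shuffled with a seeded
    uniform permutation — the targets are fully interleaved — and
    ``trial_index`` runs 1..N in session order.

    Returns a DataFrame with columns ``trial_index, target, addend,
    effort_rank, reward``.
    """
    design = get_design(study) if isinstance(study, int) else study
    cells = [
        (target, addend, design.effort_rank(addend), reward)
        for target in design.targets
        for addend in design.effort_levels
        for reward in design.reward_levels
        for _ in range(design.repeats_per_cell)
    ]
    frame = pd.DataFrame(cells, columns=["target", "addend", "effort_rank", "reward"])
    rng = np.random.default_rng(seed)
    frame = frame.iloc[rng.permutation(len(frame))].reset_index(drop=True)
    frame.insert(0, "trial_index", np.arange(1, len(frame) + 1))
    return frame


def effort_scaled(effort_rank: int | np.ndarray | pd.Series) -> np.ndarray | float:
    """Map ordinal effort rank 1..5 onto (0, 1]: rank / 5.

    This is the effort scale the discounting models operate on; at k = 1 the
    hardest level discounts a reward fully under the linear form.
    """
    return np.asarray(effort_rank, dtype=float) / N_EFFORT_RANKS


def correct_task_response(addend: int, digits: Sequence[int]) -> str:
    """Correct response string for the effortful digit-addition task.

    The addend is added to each stimulus digit and only the units digit of
    each sum is kept (mod 10): adding 3 to the digits 2, 6, 7 gives 590.
    """
    if not 0 <= addend <= 9:
        raise ValueError(f"addend must be a single digit 0..9, got {addend}")
    digits = list(digits)
    if any(not 0 <= int(d) <= 9 for d in digits):
        raise ValueError(f"stimulus digits must each be 0..9, got {digits}")
    return "".join(str((int(d) + addend) % 10) for d in digits)
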