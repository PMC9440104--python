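import numpy as np
import pandas as pd
import pytest

import prosocial_effort as pe


@pytest.fixture(scope="session")
def study1():
    return pe.study1_design()


@pytest.fixture(scope="session")
def study2():
    return pe.study2_design()


@pytest.fixture(scope="session")
def small_cohort(study1):
    """Six simulated Study-1 participants with interior choice rates."""
    def sampler(rng):
        k_self = float(rng.uniform(0.8, 1.2))
        return pe.SimParams(
            k={"self": k_self, "charity": min(k_self + float(rng.uniform(0.05, 0.2)), 1.4)},
            beta={"self": float(rng.uniform(4, 9)), "charity": float(rng.uniform(3, 8))},
        )

    trials, params = pe.simulate_cohort(study1, sampler, n_participants=6, seed=11)
    return trials, params


@pytest.fixture()
def handcrafted_trials():
    """Tiny fixed trial table for oracle checks (4 trials, 2 targets)."""
    return pd.DataFrame(
        {
            "participant_id": ["p0"] * 4,
            "study_id": [1] * 4,
            "trial_index": [1, 2, 3, 4],
            "target": ["self", "self", "charity", "charity"],
            "effort_rank": [1, 5, 2, 4],
            "addend": [1, 7, 3, 9],
            "reward": [2, 12, 6, 8],
            "choice": [1, 0, 1, 1],
            "decision_time": [1.1, 2.0, 1.5, 0.9],
            "task_accuracy": [1, 1, 0, 1],
            "task_rt": [1.2, 1.8, 1.4, 1.0],
        }
    )
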