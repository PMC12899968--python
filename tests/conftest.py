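import numpy as np
import pandas as pd
import pytest

from racestop import CohortSpec, DesignSpec, RaceParams, simulate_participant


@pytest.fixture(scope="session")
def default_spec() -> DesignSpec:
    return DesignSpec()


@pytest.fixture(scope="session")
def food_log() -> pd.DataFrame:
    """One simulated food-condition trial log under default parameters."""
    return simulate_participant(RaceParams(), seed=11, conditions=("food",))["food"]


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort (no trial simulation) for table-level tests."""
    from racestop import simulate_cohort

    spec = CohortSpec(n_rpg=10, n_iag=10, simulate_trials=False, seed=42)
    return simulate_cohort(spec)


def random_trial_log(rng: np.random.Generator, n_go: int = 30, n_stop: int = 10) -> pd.DataFrame:
    """Arbitrary (not race-generated) trial log for oracle-equivalence tests."""
    rows = []
    for i in range(n_go):
        responded = rng.random() > 0.1
        rt = float(rng.uniform(250, 1100)) if responded else np.nan
        rows.append(
            {
                "condition": "food",
                "trial_type": "go",
                "ssd_ms": np.nan,
                "responded": responded,
                "rt_ms": rt,
                "correct": responded and rng.random() > 0.1,
            }
        )
    for i in range(n_stop):
        responded = rng.random() < rng.uniform(0.2, 0.8)
        rows.append(
            {
                "condition": "food",
                "trial_type": "stop",
                "ssd_ms": float(rng.choice(np.arange(50, 1001, 50))),
                "responded": responded,
                "rt_ms": float(rng.uniform(250, 900)) if responded else np.nan,
                "correct": not responded,
            }
        )
    return pd.DataFrame(rows)
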