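import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from riskylearn.agent_models import MODELS, ParamSet, simulate_agent
from riskylearn.synthetic_cohort import (CohortSpec, default_cohort_spec,
                                         simulate_cohort)
from riskylearn.mixture_recovery import single_strategy_group
from riskylearn.task_engine import make_block_schedule, session_tapes


@pytest.fixture(scope="session")
def default_cohort():
    """Study-like cohort: 31 early, 39 mid-late, 35 adult subjects."""
    return simulate_cohort(default_cohort_spec(master_seed=20))


@pytest.fixture(scope="session")
def session_layout():
    """A fixed block schedule with its outcome tapes."""
    schedule = make_block_schedule(42)
    return schedule, session_tapes(schedule, 42)


def simulate_one(model: str, seed: int, schedule=None, tapes=None,
                 **params) -> pd.DataFrame:
    """One agent's 200-trial session as a DataFrame."""
    from riskylearn.task_engine import records_to_frame
    if schedule is None:
        schedule = make_block_schedule(seed)
        tapes = session_tapes(schedule, seed)
    spec = MODELS[model]
    recs = simulate_agent(spec, ParamSet(**params), schedule, tapes, seed)
    return records_to_frame(recs)


def single_model_cohort(model: str, n_subjects: int, seed: int,
                        age_group: str = "adult"):
    """Cohort where every subject uses the same strategy."""
    g = single_strategy_group(model, n_subjects, age_group)
    return simulate_cohort(CohortSpec(groups=[g], master_seed=seed))
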