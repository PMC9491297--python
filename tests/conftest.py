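import numpy as np
import pandas as pd
import pytest

from grlkit.models import Params
from grlkit.simulate import BehavioralRecord, run_agent
from grlkit.task import TaskConfig, generate_session


@pytest.fixture(scope="session")
def default_session():
    return generate_session(TaskConfig(rng_seed=11))


@pytest.fixture(scope="session")
def cm_session():
    return generate_session(TaskConfig(variant="7CM", rng_seed=12))


@pytest.fixture(scope="session")
def discriminative_params():
    """A strong discriminative generalizer (negative g_A and g_S, low
    temperature)."""
    return Params(alpha=0.5, g_A=-0.7, g_S=-0.8, g_SA=-0.7, tau=0.3,
                  beta_0=-0.1, lambda_beta=0.5, beta_R=0.1)


@pytest.fixture(scope="session")
def grl_record(default_session, discriminative_params):
    return run_agent(default_session, "AX|SY", discriminative_params, seed=7)


def make_oracle_record(session) -> BehavioralRecord:
    """A record whose chooser always takes the rewarded action (complete
    reward-encounter coverage: every scheduled reward is collected)."""
    tr = session.trials.copy().reset_index(drop=True)
    tr["chosen_action"] = tr["rewarded_action"]
    tr["reward"] = tr["reward_available"].astype(int)
    tr["missed"] = False
    tr["reaction_time"] = 0.5
    return BehavioralRecord(trials=tr)


def make_fixed_action_record(session, action="left") -> BehavioralRecord:
    tr = session.trials.copy().reset_index(drop=True)
    tr["chosen_action"] = action
    tr["reward"] = (tr["reward_available"]
                    & (tr["rewarded_action"] == action)).astype(int)
    tr["missed"] = False
    tr["reaction_time"] = 0.5
    return BehavioralRecord(trials=tr)


@pytest.fixture(scope="session")
def oracle_record(default_session):
    return make_oracle_record(default_session)


def toy_record(rows: list[dict]) -> BehavioralRecord:
    """Build a minimal hand-specified record; rows give per-trial fields,
    defaults fill the rest."""
    base = {"run": 1, "block": 1, "quartet": 1, "category": 1, "state": "A",
            "cue_id": "run1_1A", "rewarded_action": "left",
            "reward_available": True, "chosen_action": "left", "reward": 0,
            "reaction_time": 0.5, "missed": False}
    recs = []
    for i, r in enumerate(rows):
        rec = {**base, **r}
        rec["trial"] = i + 1
        if "cue_id" not in r:
            rec["cue_id"] = f"run{rec['run']}_{rec['category']}{rec['state']}"
        recs.append(rec)
    return BehavioralRecord(trials=pd.DataFrame(recs))


@pytest.fixture
def rng():
    return np.random.default_rng(123)
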