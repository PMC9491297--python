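"""Run model agents through task sessions to produce behavioral records.

A :class:`BehavioralRecord` is a per-trial table (the session's trial fields
plus choice, reward, reaction time and missed flag) with optional latent
traces (preparatory-state value, policy value inputs, prediction errors,
choice probabilities).

Two modes are supported:

* **free-running** -- the agent's own sampled choices determine outcomes,
  resolved against the session's pre-scheduled reward availability;
* **yoked** -- the trial sequence and reward contingencies of a reference
  record are pinned, and the simulated agent's own choice on each trial is
  resolved against that pinned contingency (the agent experiences exactly the
  environment its reference subject did).

Reaction times are synthesized (affine in the negative normalized absolute
value difference, plus truncated Gaussian noise) purely so the RT regression
machinery can be exercised; no behavioral model of RT is implied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import engine
from .models import ModelSpec, Params, get_model
from .task import Session

RECORD_COLUMNS = [
    "run", "block", "trial", "quartet", "category", "state", "cue_id",
    "rewarded_action", "reward_available", "chosen_action", "reward",
    "reaction_time", "missed",
]

# carried through from the session when present (regressor export)
TIMING_COLUMNS = ["cue_onset", "isi_onset", "outcome_onset", "iti_duration"]

TRACE_COLUMNS = ["p_left", "V0", "svpe", "value_left", "value_right", "avpe"]

# synthetic RT defaults: seconds; slope applies to |dQ| normalized to [0, 1]
RT_INTERCEPT, RT_SLOPE, RT_NOISE_SD = 0.85, 0.30, 0.15
RT_MIN, RT_MAX = 0.2, 2.0


@dataclass
class BehavioralRecord:
    trials: pd.DataFrame
    model_id: str | None = None
    params: dict = field(default_factory=dict)
    traces: pd.DataFrame | None = None
    session: Session | None = None

    def __post_init__(self):
        missing = [c for c in RECORD_COLUMNS if c not in self.trials.columns]
        if missing:
            raise ValueError(f"record is missing columns: {missing}")
        resp = self.trials[~self.trials["missed"]]
        bad = resp[(resp["reward"] == 1)
                   & ((resp["chosen_action"] != resp["rewarded_action"])
                      | (~resp["reward_available"]))]
        if len(bad):
            raise ValueError("rewards present on trials whose contingency "
                             "could not pay out")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def accuracy(self) -> float:
        """Proportion of non-missed choices of the rewarded action."""
        resp = self.trials[~self.trials["missed"]]
        return float((resp["chosen_action"] == resp["rewarded_action"]).mean())


def synthesize_rt(abs_dq: np.ndarray, rng: np.random.Generator,
                  intercept: float = RT_INTERCEPT, slope: float = RT_SLOPE,
                  noise_sd: float = RT_NOISE_SD) -> np.ndarray:
    """RT = intercept - slope * |dQ|_norm + noise, truncated to [0.2, 2] s."""
    norm = np.max(np.abs(abs_dq)) or 1.0
    rt = intercept - slope * np.abs(abs_dq) / norm \
        + rng.normal(0.0, noise_sd, size=len(abs_dq))
    return np.clip(rt, RT_MIN, RT_MAX)


def run_agent(session: Session, spec: ModelSpec | str, params: Params,
              seed: int | np.random.Generator = 0, *,
              yoked_to: BehavioralRecord | None = None,
              record_traces: bool = True,
              reset_v0: bool = False) -> BehavioralRecord:
    """Simulate one agent over a session (or yoked to a reference record)."""
    if isinstance(spec, str):
        spec = get_model(spec)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if yoked_to is not None:
        base = yoked_to.trials
        if len(base) != len(session.trials):
            raise ValueError("yoked reference does not cover the session")
    else:
        base = session.trials
    arrays = engine.encode_session_arrays(base)
    choice, reward, traces = engine.simulate_choices(
        arrays, spec, params, rng, reset_v0=reset_v0)

    keep = [c for c in RECORD_COLUMNS + TIMING_COLUMNS if c in base.columns]
    out = base[keep].copy().reset_index(drop=True)
    out["chosen_action"] = np.where(choice == 0, "left", "right")
    out["reward"] = reward
    out["missed"] = False
    dq_policy = traces["value_left"] - traces["value_right"]
    out["reaction_time"] = synthesize_rt(dq_policy, rng)
    out = out[RECORD_COLUMNS + [c for c in TIMING_COLUMNS if c in out.columns]]
    trace_df = pd.DataFrame(traces)[TRACE_COLUMNS] if record_traces else None
    return BehavioralRecord(trials=out, model_id=spec.model_id,
                            params=params.__dict__.copy(), traces=trace_df)


def replay_traces(record: BehavioralRecord, spec: ModelSpec | str,
                  params: Params, reset_v0: bool = False) -> pd.DataFrame:
    """Deterministically replay a record under a model to recover its latent
    traces (used for psychometric regressions and regressor export)."""
    if isinstance(spec, str):
        spec = get_model(spec)
    arrays = engine.encode_session_arrays(record.trials)
    chosen, reward = engine.encode_choices(record.trials)
    _, traces = engine.replay_nll(arrays, chosen, reward, spec, params,
                                  reset_v0=reset_v0, return_traces=True)
    return pd.DataFrame(traces)[TRACE_COLUMNS]


# Uniform sampling ranges: the region typical of successful human learners
# (temperatures well below the fitting upper bound), so sampled agents
# produce informative choice sequences.
UNIFORM_RANGES = {
    "alpha": (0.1, 0.9), "g_A": (-1.0, 0.0), "g_S": (-1.0, 1.0),
    "g_SA": (-1.0, 0.0), "tau": (0.2, 1.5), "beta_0": (-0.5, 0.5),
    "lambda_beta": (0.0, 1.0), "beta_R": (-0.5, 0.5),
    "alpha_SPE": (0.1, 0.9), "theta_0": (0.55, 0.95),
    "theta_1": (0.0, 0.3), "w_MB": (0.0, 1.0),
    "p_intercept": (0.2, 0.8),
}

# Group-level parameter statistics (mean, SD) of fitted good learners in the
# face/house data set; the default generating population for synthetic
# cohorts, sampled as truncated normals within the parameter bounds.
GOOD_LEARNER_STATS = {
    "alpha": (0.517, 0.242), "g_A": (-0.355, 0.367), "g_S": (-0.184, 0.344),
    "tau": (0.698, 0.464), "beta_0": (-0.066, 0.235),
    "lambda_beta": (0.543, 0.371), "beta_R": (0.113, 0.354),
}

# Named generalizer-cohort conditions for posterior predictive checks:
# unambiguous state generalization of either sign, clear action
# generalization, and mild choice biases. A single rewarded observation must
# relay a value difference of the order g_S*alpha to the complementary state
# for the first-generalization probe to bite against the softmax noise, which
# these ranges guarantee; hysteresis biases are kept small because a strong
# perseverator mechanically fails the complementary-action probe regardless
# of its generalization weights.
COHORT_PRESETS: dict[str, dict] = {
    "discriminative": {"g_S": (-1.0, -0.4), "g_A": (-1.0, -0.3),
                       "alpha": (0.3, 0.8), "tau": (0.2, 0.8),
                       "beta_0": (-0.2, 0.2), "beta_R": (-0.2, 0.2)},
    "associative": {"g_S": (0.4, 1.0), "g_A": (-1.0, -0.3),
                    "alpha": (0.3, 0.8), "tau": (0.2, 0.8),
                    "beta_0": (-0.2, 0.2), "beta_R": (-0.2, 0.2)},
    # model-recovery condition: agents that materially use both
    # generalization dimensions (an agent with g near 0 is behaviorally a
    # nested model, so including it tests cohort composition rather than
    # model discriminability)
    "generalizer": {"g_S": (-1.0, -0.3), "g_A": (-1.0, -0.3),
                    "tau": (0.2, 1.0)},
}


def sample_params(spec: ModelSpec | str, rng: np.random.Generator,
                  overrides: dict | None = None,
                  population: str | None = None,
                  truncate: dict | None = None) -> Params:
    """Draw an in-bounds random parameter vector for a model.

    ``population="good_learner"`` samples each free parameter from a normal
    distribution with the fitted good-learner group statistics, truncated to
    its bounds (parameters without group statistics fall back to the uniform
    ranges). ``truncate`` narrows individual parameters to sub-intervals
    (e.g. a strictly discriminative cohort, ``{"g_S": (-1.0, -0.05)}``);
    ``overrides`` pins exact values.
    """
    from .models import PARAM_BOUNDS
    if isinstance(spec, str):
        spec = get_model(spec)
    values = {}
    for name in spec.free:
        lo, hi = UNIFORM_RANGES.get(name, PARAM_BOUNDS[name])
        blo, bhi = PARAM_BOUNDS[name]
        if truncate and name in truncate:
            lo, hi = truncate[name]
        stats = GOOD_LEARNER_STATS if population == "good_learner" else None
        if stats and name in stats:
            mu, sd = stats[name]
            lo, hi = max(lo, blo), min(hi, bhi)
            for _ in range(1000):
                v = rng.normal(mu, sd)
                if lo <= v <= hi:
                    break
            else:
                v = min(max(mu, lo), hi)
            values[name] = float(v)
        else:
            values[name] = float(rng.uniform(lo, hi))
    if overrides:
        values.update({k: v for k, v in overrides.items() if k in spec.free})
    return spec.build_params(values)


def simulate_cohort(n_subjects: int, spec: ModelSpec | str,
                    seed: int = 0, *,
                    param_sampler=None, overrides: dict | None = None,
                    population: str | None = None,
                    truncate: dict | None = None,
                    session: Session | None = None,
                    variant: str = "3FH") -> list[BehavioralRecord]:
    """Independent per-subject sessions and simulated records.

    Each subject gets a fresh counterbalanced session (unless a shared
    ``session`` is supplied) and parameters drawn in bounds by
    ``param_sampler`` (default: :func:`sample_params` with ``overrides``).
    """
    from .task import TaskConfig, generate_session
    if isinstance(spec, str):
        spec = get_model(spec)
    rng = np.random.default_rng(seed)
    records = []
    for _ in range(n_subjects):
        if session is None:
            sess = generate_session(
                TaskConfig(variant=variant,
                           rng_seed=int(rng.integers(2 ** 31))))
        else:
            sess = session
        params = (param_sampler(spec, rng) if param_sampler is not None
                  else sample_params(spec, rng, overrides,
                                     population=population,
                                     truncate=truncate))
        rec = run_agent(sess, spec, params,
                        seed=np.random.default_rng(int(rng.integers(2 ** 31))))
        rec.session = sess
        records.append(rec)
    return records
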