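"""Single-trial model computations: the generalized-RL family, metastate
learners, and choice baselines.

The learning models fall into three classes:

* **GRL / CQ(lambda)** -- model-free temporal-difference learning with a
  critic for the passive preparatory state (state-value-prediction error,
  SVPE, at cue onset) and a Q-learner for the four active states
  (action-value-prediction error, AVPE, at outcome). Generalization weights
  relay the AVPE to the nonchosen action (``g_A``, counterfactual/inverse),
  to the complementary state within the category (``g_S``, signed:
  negative = discriminative, positive = associative), and multiplicatively to
  the complementary state's complementary action (``g_S * g_A``, or
  ``g_S * g_SA`` with a free interaction weight). A TD(lambda) eligibility
  trace relays the AVPE back to the preparatory state. Updated values are
  clamped to [0, 1] only where a relayed error could exit the unit interval
  (the direct delta updates cannot).

* **Metastate learners** -- belief trackers over the two rule hypotheses per
  category (AL/BR vs AR/BL): a delta-rule learner driven by a
  (meta)state-prediction error (SPE), and a hidden Markov model with a
  consistency likelihood ``theta_0`` and optional reversal rate ``theta_1``
  propagating the posterior between a category's observations. Beliefs map to
  model-based action values, optionally mixed with model-free Q values by a
  weight ``w_MB`` (dual-systems models).

* **Baselines** -- hysteresis (exponentially decaying perseveration /
  alternation bias plus lateral bias, outcome-insensitive), a one-parameter
  intercept model, and a zero-parameter chance model.

Choice follows a softmax with temperature ``tau`` over
``w_MB*Q_MB + (1 - w_MB)*Q + beta_hist(a) + beta_R*I_R(a)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

LEFT, RIGHT = 0, 1
N_STATES = 4  # (category, state) pairs: (1,A), (1,B), (2,A), (2,B)

PROB_FLOOR = 1e-12


def state_index(category: int, state: str) -> int:
    return (category - 1) * 2 + (0 if state == "A" else 1)


def clamp_unit(x: float) -> float:
    """f(x) = max(0, min(1, x)): value estimates are reward probabilities."""
    return 0.0 if x < 0.0 else (1.0 if x > 1.0 else x)


# ---------------------------------------------------------------------------
# parameters and model registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Params:
    """Union of all model parameters (fixed values filled per ModelSpec)."""
    alpha: float = 0.0          # model-free learning rate, [0, 1]
    g_A: float = 0.0            # action generalization, [-1, 0]
    g_S: float = 0.0            # state generalization, [-1, 1]
    g_SA: float = 0.0           # interaction weight, [-1, 0] (free only in AX|SY|Z)
    lambda_elig: float = 0.5    # eligibility trace, fixed 0.5
    tau: float = 1.0            # softmax temperature, > 0
    beta_0: float = 0.0         # hysteresis initial magnitude (signed)
    lambda_beta: float = 0.0    # hysteresis inverse decay, [0, 1]
    beta_R: float = 0.0         # lateral bias, rightward positive
    alpha_SPE: float = 0.0      # metastate delta-rule learning rate, [0, 1]
    theta_0: float = 0.5        # HMM consistency, [0.5, 1]
    theta_1: float = 0.0        # HMM reversal rate, [0, 1]
    w_MB: float = 0.0           # model-based weight, [0, 1]
    p_intercept: float = 0.5    # intercept model: P(right)


@dataclass(frozen=True)
class ModelSpec:
    """A model in the comparison set: free parameters and fixed values."""
    model_id: str
    free: tuple[str, ...]
    fixed: dict = field(default_factory=dict)
    mb_system: str | None = None        # None | "SPE" | "HMM"
    kind: str = "learner"               # "learner" | "hysteresis" | "intercept" | "chance"
    tied: dict = field(default_factory=dict)  # param -> callable(Params)

    @property
    def df(self) -> int:
        return len(self.free)

    def build_params(self, values: dict[str, float]) -> Params:
        p = Params(**{**self.fixed, **values})
        for name, fn in self.tied.items():
            p = replace(p, **{name: fn(p)})
        return p


# bounds used by the fitter for free parameters (natural space)
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha": (0.0, 1.0),
    "g_A": (-1.0, 0.0),
    "g_S": (-1.0, 1.0),
    "g_SA": (-1.0, 0.0),
    "tau": (0.01, 20.0),
    "beta_0": (-5.0, 5.0),
    "beta_R": (-5.0, 5.0),
    "lambda_beta": (0.0, 1.0),
    "alpha_SPE": (0.0, 1.0),
    "theta_0": (0.5, 1.0),
    "theta_1": (0.0, 1.0),
    "w_MB": (0.0, 1.0),
    "p_intercept": (0.001, 0.999),
}

_POLICY = ("tau", "beta_0", "lambda_beta", "beta_R")


def _grl(model_id, extra_free=(), **fixed):
    tied = {}
    if "g_SA" not in fixed and "g_SA" not in extra_free:
        tied["g_SA"] = lambda p: p.g_A  # 7-parameter interaction g_S * g_A
    return ModelSpec(model_id, ("alpha", *extra_free, *_POLICY),
                     fixed=fixed, tied=tied)


MODEL_REGISTRY: dict[str, ModelSpec] = {m.model_id: m for m in [
    _grl("A0|S0", g_A=0.0, g_S=0.0),
    _grl("A-|S0", g_A=-1.0, g_S=0.0),
    _grl("AX|S0", extra_free=("g_A",), g_S=0.0),
    _grl("A0|S+", g_A=0.0, g_S=1.0),
    _grl("A0|S-", g_A=0.0, g_S=-1.0),
    _grl("A0|SY", extra_free=("g_S",), g_A=0.0),
    _grl("A-|S+", g_A=-1.0, g_S=1.0),
    _grl("A-|S-", g_A=-1.0, g_S=-1.0),
    ModelSpec("AW|SW", ("alpha", "g_S", *_POLICY),
              tied={"g_A": lambda p: min(0.0, p.g_S),
                    "g_SA": lambda p: min(0.0, p.g_S)}),
    _grl("AX|SY", extra_free=("g_A", "g_S")),
    _grl("AX|SY|Z", extra_free=("g_A", "g_S", "g_SA")),
    ModelSpec("SPE", ("alpha_SPE", *_POLICY), fixed={"w_MB": 1.0},
              mb_system="SPE"),
    ModelSpec("SPE+RL", ("alpha", "alpha_SPE", "w_MB", *_POLICY),
              mb_system="SPE"),
    ModelSpec("HMM0", ("theta_0", *_POLICY),
              fixed={"w_MB": 1.0, "theta_1": 0.0}, mb_system="HMM"),
    ModelSpec("HMM", ("theta_0", "theta_1", *_POLICY), fixed={"w_MB": 1.0},
              mb_system="HMM"),
    ModelSpec("HMM0+RL", ("alpha", "theta_0", "w_MB", *_POLICY),
              fixed={"theta_1": 0.0}, mb_system="HMM"),
    ModelSpec("HMM+RL", ("alpha", "theta_0", "theta_1", "w_MB", *_POLICY),
              mb_system="HMM"),
    ModelSpec("hysteresis", _POLICY, kind="hysteresis"),
    ModelSpec("intercept", ("p_intercept",), kind="intercept"),
    ModelSpec("chance", (), kind="chance"),
]}

LEARNING_MODELS = [m for m in MODEL_REGISTRY
                   if MODEL_REGISTRY[m].kind == "learner"]


def get_model(model_id: str) -> ModelSpec:
    try:
        return MODEL_REGISTRY[model_id]
    except KeyError:
        raise KeyError(
            f"unknown model {model_id!r}; valid labels: "
            + ", ".join(MODEL_REGISTRY)) from None


# ---------------------------------------------------------------------------
# agent state
# ---------------------------------------------------------------------------

@dataclass
class AgentState:
    """Cached values and biases of a model-free (GRL) agent."""
    V0: float = 0.0
    Q: np.ndarray = field(default_factory=lambda: np.zeros((N_STATES, 2)))
    beta_hist: np.ndarray = field(default_factory=lambda: np.zeros(2))
    N: int = 0

    def reset_run(self, reset_V0: bool = False) -> None:
        """A run boundary re-initializes Q values, hysteresis and the action
        counter; the preparatory-state value persists by default."""
        self.Q[:] = 0.0
        self.beta_hist[:] = 0.0
        self.N = 0
        if reset_V0:
            self.V0 = 0.0


@dataclass
class BeliefState:
    """P(metastate hypothesis | category); index 0 = AL/BR, 1 = AR/BL."""
    P: np.ndarray = field(default_factory=lambda: np.full((2, 2), 0.5))

    def reset_run(self) -> None:
        self.P[:] = 0.5

    def check(self) -> None:
        assert np.all(self.P >= 0) and np.all(self.P <= 1)
        assert np.allclose(self.P.sum(axis=1), 1.0)


# ---------------------------------------------------------------------------
# single-trial operations
# ---------------------------------------------------------------------------

def policy_probabilities(q_values: np.ndarray, state: AgentState,
                         params: Params, q_mb: np.ndarray | None = None
                         ) -> np.ndarray:
    """Softmax choice probabilities over (left, right).

    ``q_values`` are the model-free Q(s, .) entries for the current state;
    ``q_mb`` the model-based values (required when ``w_MB > 0``). The exponent
    per action is ``(w*Q_MB + (1-w)*Q + beta_hist + beta_R*I_R) / tau``;
    a max-subtraction guard makes the result invariant to common shifts.
    """
    if params.tau <= 0:
        raise ValueError("softmax temperature must be positive")
    w = params.w_MB
    q = (1.0 - w) * np.asarray(q_values, dtype=float)
    if w > 0:
        if q_mb is None:
            raise ValueError("model-based weight > 0 requires Q_MB values")
        q = q + w * np.asarray(q_mb, dtype=float)
    z = q + state.beta_hist + np.array([0.0, params.beta_R])
    z = z / params.tau
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def svpe_update(state: AgentState, s_idx: int, params: Params) -> float:
    """State-value-prediction error at cue onset: delta_V = max_a Q(s', a) - V.

    V moves toward the best available action value (no clamp needed: a convex
    combination of unit-interval values stays in the unit interval).
    """
    delta_v = float(state.Q[s_idx].max() - state.V0)
    state.V0 += params.alpha * delta_v
    assert -1e-12 <= state.V0 <= 1 + 1e-12
    return delta_v


def outcome_update(state: AgentState, s_idx: int, action: int, reward: int,
                   params: Params) -> float:
    """AVPE-driven value updates at outcome, including generalization.

    Order: (1) direct Q(s,a); (2) eligibility-trace relay to V(s0);
    (3) nonchosen action via g_A; (4) complementary state via g_S;
    (5) complementary state's nonchosen action via g_S*g_SA. Relayed updates
    are clamped to [0, 1]; the direct update cannot leave the interval.
    """
    if reward not in (0, 1):
        raise ValueError("reward must be 0 or 1")
    a, a_c = action, 1 - action
    s_c = s_idx + 1 if s_idx % 2 == 0 else s_idx - 1  # complementary state
    alpha = params.alpha
    delta_q = float(reward - state.Q[s_idx, a])
    state.Q[s_idx, a] += alpha * delta_q
    assert -1e-12 <= state.Q[s_idx, a] <= 1 + 1e-12
    state.V0 = clamp_unit(state.V0 + params.lambda_elig * alpha * delta_q)
    state.Q[s_idx, a_c] = clamp_unit(
        state.Q[s_idx, a_c] + params.g_A * alpha * delta_q)
    state.Q[s_c, a] = clamp_unit(
        state.Q[s_c, a] + params.g_S * alpha * delta_q)
    state.Q[s_c, a_c] = clamp_unit(
        state.Q[s_c, a_c] + params.g_S * params.g_SA * alpha * delta_q)
    return delta_q


def hysteresis_update(state: AgentState, action: int, params: Params) -> None:
    """Decay both action biases and add beta_0 to the executed action.

    The recursion ``beta(a) <- lambda_beta*beta(a) + beta_0*[a == a_t]``
    equals the closed-form sum over the action history,
    ``beta_{t+1}(a) = sum_i beta_0 * lambda_beta^i * I_{N_t - i}(a)``.
    """
    state.N += 1
    state.beta_hist *= params.lambda_beta
    state.beta_hist[action] += params.beta_0


def hysteresis_closed_form(actions: list[int], params: Params) -> np.ndarray:
    """Direct evaluation of the hysteresis sum (independent oracle)."""
    n = len(actions)
    beta = np.zeros(2)
    for i in range(n):
        beta[actions[n - 1 - i]] += params.beta_0 * params.lambda_beta ** i
    return beta


def consistent_hypothesis(state: str, action: int, reward: int) -> tuple[int, int]:
    """The metastate hypothesis consistent with (s, a, r) and its complement.

    Returns indices into the hypothesis pair (0 = AL/BR, 1 = AR/BL):
    e.g. a rewarded left press in state A is consistent with AL/BR.
    """
    congruent = (state == "A") == (action == LEFT)  # (s, a) congruent w/ AL/BR
    h_hat = 0 if congruent == (reward == 1) else 1
    return h_hat, 1 - h_hat


def spe_update(belief: BeliefState, category: int, h_hat: int,
               params: Params) -> float:
    """Delta-rule metastate update: delta = 1 - P(h_hat | c)."""
    c = category - 1
    delta = 1.0 - belief.P[c, h_hat]
    belief.P[c, h_hat] += params.alpha_SPE * delta
    belief.P[c, 1 - h_hat] -= params.alpha_SPE * belief.P[c, 1 - h_hat]
    return delta


def hmm_propagate_prior(belief: BeliefState, category: int,
                        params: Params) -> np.ndarray:
    """Prior for the category's next observation: mixes in reversals at rate
    theta_1 (in place)."""
    c = category - 1
    post = belief.P[c].copy()
    belief.P[c, 0] = params.theta_1 * post[1] + (1 - params.theta_1) * post[0]
    belief.P[c, 1] = params.theta_1 * post[0] + (1 - params.theta_1) * post[1]
    return belief.P[c].copy()


def hmm_posterior_update(belief: BeliefState, category: int, state: str,
                         action: int, reward: int, params: Params
                         ) -> np.ndarray:
    """Bayes update: likelihood theta_0 for the consistent hypothesis,
    1 - theta_0 for its complement; floor-guarded normalization."""
    c = category - 1
    h_hat, h_alt = consistent_hypothesis(state, action, reward)
    lik = np.empty(2)
    lik[h_hat] = params.theta_0
    lik[h_alt] = 1.0 - params.theta_0
    post = lik * belief.P[c]
    norm = post.sum()
    if norm < PROB_FLOOR:
        post = np.full(2, 0.5)
    else:
        post = post / norm
    post = np.clip(post, PROB_FLOOR, 1.0 - PROB_FLOOR)
    post = post / post.sum()
    belief.P[c] = post
    return post.copy()


def model_based_q(belief: BeliefState, category: int, state: str,
                  action: int) -> float:
    """Q_MB(c, s, a): probability of the hypothesis under which (s, a) is
    rewarded: AL/BR for (A, left) and (B, right), else AR/BL."""
    c = category - 1
    congruent = (state == "A") == (action == LEFT)
    return float(belief.P[c, 0] if congruent else belief.P[c, 1])


def model_based_q_pair(belief: BeliefState, category: int,
                       state: str) -> np.ndarray:
    return np.array([model_based_q(belief, category, state, a)
                     for a in (LEFT, RIGHT)])


def expected_reward(belief: BeliefState, category: int, state: str,
                    action: int, params: Params) -> float:
    """E[r | c, s, a] under the HMM likelihood; tracked for regressor export,
    not an input to the choice policy."""
    p_congruent = model_based_q(belief, category, state, action)
    return params.theta_0 * p_congruent + (1 - params.theta_0) * (1 - p_congruent)


def reward_sensitivity(params: Params) -> float:
    """log(alpha * (1 - g_A - g_S + g_S*g_A) / tau), the net learning gain
    over all four relayed updates relative to choice stochasticity.

    Returns -inf when the argument is nonpositive (e.g. alpha = 0).
    """
    arg = params.alpha * (1 - params.g_A - params.g_S
                          + params.g_S * params.g_A) / params.tau
    if arg <= 0:
        return -math.inf
    return math.log(arg)
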