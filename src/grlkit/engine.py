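"""Vectorized trial-loop engine shared by likelihood evaluation and simulation.

One compiled kernel replays (or generates) a whole session for any model in
the registry. The pure-Python single-trial operations in :mod:`grlkit.models`
define the semantics; this kernel reproduces them exactly (asserted in the
test suite) at the speed needed for maximum-likelihood fitting with many
restarts and for large simulated cohorts.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .models import ModelSpec, Params

# packed parameter vector layout
_P_ALPHA, _P_GA, _P_GS, _P_GSA, _P_LAM, _P_TAU, _P_B0, _P_LB, _P_BR, \
    _P_ASPE, _P_TH0, _P_TH1, _P_WMB, _P_INT = range(14)

MB_NONE, MB_SPE, MB_HMM = 0, 1, 2
KIND_SOFTMAX, KIND_INTERCEPT, KIND_CHANCE = 0, 1, 2

MODE_REPLAY, MODE_SIMULATE = 0, 1

_LOG_FLOOR = 1e-12


def pack_params(params: Params) -> np.ndarray:
    return np.array([
        params.alpha, params.g_A, params.g_S, params.g_SA,
        params.lambda_elig, params.tau, params.beta_0, params.lambda_beta,
        params.beta_R, params.alpha_SPE, params.theta_0, params.theta_1,
        params.w_MB, params.p_intercept,
    ], dtype=np.float64)


def model_flags(spec: ModelSpec) -> tuple[int, int]:
    mb = {None: MB_NONE, "SPE": MB_SPE, "HMM": MB_HMM}[spec.mb_system]
    kind = {"learner": KIND_SOFTMAX, "hysteresis": KIND_SOFTMAX,
            "intercept": KIND_INTERCEPT, "chance": KIND_CHANCE}[spec.kind]
    return mb, kind


@njit(cache=True)
def _clamp(x):
    if x < 0.0:
        return 0.0
    if x > 1.0:
        return 1.0
    return x


@njit(cache=True)
def run_core(mode, s_idx, cat, run_start,
             chosen_in, reward_in,
             rewarded_action, reward_available, u,
             pv, mb_system, kind, reset_v0,
             out_choice, out_reward, out_p_left,
             out_v, out_dv, out_q_left, out_q_right, out_dq):
    """Replay (mode 0) or simulate (mode 1) a session; returns the NLL.

    In replay mode ``chosen_in`` (-1 = missed) and ``reward_in`` drive all
    updates and the NLL of the observed choices accumulates. In simulate mode
    choices are sampled from the policy via the uniform draws ``u`` and
    rewards resolve from the schedule. Traces are always written.
    """
    alpha = pv[_P_ALPHA]
    g_a = pv[_P_GA]
    g_s = pv[_P_GS]
    g_sa = pv[_P_GSA]
    lam = pv[_P_LAM]
    tau = pv[_P_TAU]
    beta_0 = pv[_P_B0]
    lam_b = pv[_P_LB]
    beta_r = pv[_P_BR]
    a_spe = pv[_P_ASPE]
    th0 = pv[_P_TH0]
    th1 = pv[_P_TH1]
    w = pv[_P_WMB]
    p_int = pv[_P_INT]

    n = s_idx.shape[0]
    v0 = 0.0
    q = np.zeros((4, 2))
    beta = np.zeros(2)
    belief = np.full((2, 2), 0.5)
    nll = 0.0

    for t in range(n):
        if run_start[t]:
            for i in range(4):
                q[i, 0] = 0.0
                q[i, 1] = 0.0
            beta[0] = 0.0
            beta[1] = 0.0
            belief[0, 0] = belief[0, 1] = 0.5
            belief[1, 0] = belief[1, 1] = 0.5
            if reset_v0 == 1:
                v0 = 0.0
        s = s_idx[t]
        c = cat[t]
        is_state_a = (s % 2) == 0

        # SVPE at cue onset
        max_q = q[s, 0] if q[s, 0] > q[s, 1] else q[s, 1]
        dv = max_q - v0
        v0 += alpha * dv

        # belief propagation on each encounter of the category (HMM)
        if mb_system == MB_HMM:
            p0 = belief[c, 0]
            p1 = belief[c, 1]
            belief[c, 0] = th1 * p1 + (1.0 - th1) * p0
            belief[c, 1] = th1 * p0 + (1.0 - th1) * p1

        # policy value inputs
        if mb_system != MB_NONE:
            qmb_l = belief[c, 0] if is_state_a else belief[c, 1]
            qmb_r = belief[c, 1] if is_state_a else belief[c, 0]
        else:
            qmb_l = 0.0
            qmb_r = 0.0
        val_l = w * qmb_l + (1.0 - w) * q[s, 0]
        val_r = w * qmb_r + (1.0 - w) * q[s, 1]

        if kind == KIND_CHANCE:
            p_left = 0.5
        elif kind == KIND_INTERCEPT:
            p_left = 1.0 - p_int
        else:
            x_l = (val_l + beta[0]) / tau
            x_r = (val_r + beta[1] + beta_r) / tau
            m = x_l if x_l > x_r else x_r
            e_l = np.exp(x_l - m)
            e_r = np.exp(x_r - m)
            p_left = e_l / (e_l + e_r)

        if mode == MODE_REPLAY:
            a = chosen_in[t]
            r = reward_in[t]
            if a >= 0:
                pa = p_left if a == 0 else 1.0 - p_left
                if pa < _LOG_FLOOR:
                    pa = _LOG_FLOOR
                nll -= np.log(pa)
        else:
            a = 0 if u[t] < p_left else 1
            r = 1 if (a == rewarded_action[t] and reward_available[t] == 1) \
                else 0

        out_choice[t] = a
        out_reward[t] = r if a >= 0 else 0
        out_p_left[t] = p_left
        out_v[t] = v0
        out_dv[t] = dv
        out_q_left[t] = val_l
        out_q_right[t] = val_r

        if a >= 0:
            # hysteresis: decay then add to the executed action
            beta[0] *= lam_b
            beta[1] *= lam_b
            beta[a] += beta_0

            # AVPE and generalized value updates
            dq = r - q[s, a]
            q[s, a] += alpha * dq
            v0 = _clamp(v0 + lam * alpha * dq)
            sc = s + 1 if is_state_a else s - 1
            q[s, 1 - a] = _clamp(q[s, 1 - a] + g_a * alpha * dq)
            q[sc, a] = _clamp(q[sc, a] + g_s * alpha * dq)
            q[sc, 1 - a] = _clamp(q[sc, 1 - a] + g_s * g_sa * alpha * dq)
            out_dq[t] = dq

            if mb_system != MB_NONE:
                congruent = is_state_a == (a == 0)
                h_hat = 0 if congruent == (r == 1) else 1
                if mb_system == MB_SPE:
                    d_spe = 1.0 - belief[c, h_hat]
                    belief[c, h_hat] += a_spe * d_spe
                    belief[c, 1 - h_hat] -= a_spe * belief[c, 1 - h_hat]
                else:
                    lik_hat = th0
                    lik_alt = 1.0 - th0
                    p_hat = lik_hat * belief[c, h_hat]
                    p_alt = lik_alt * belief[c, 1 - h_hat]
                    norm = p_hat + p_alt
                    if norm < _LOG_FLOOR:
                        p_hat = 0.5
                        p_alt = 0.5
                    else:
                        p_hat /= norm
                        p_alt /= norm
                    if p_hat < _LOG_FLOOR:
                        p_hat = _LOG_FLOOR
                    if p_alt < _LOG_FLOOR:
                        p_alt = _LOG_FLOOR
                    tot = p_hat + p_alt
                    belief[c, h_hat] = p_hat / tot
                    belief[c, 1 - h_hat] = p_alt / tot
        else:
            out_dq[t] = np.nan

    return nll


def encode_session_arrays(trials) -> dict[str, np.ndarray]:
    """Integer-encode a trial table (session or record) for the kernel."""
    s_idx = ((trials["category"].to_numpy() - 1) * 2
             + (trials["state"].to_numpy() == "B").astype(np.int64))
    cat = trials["category"].to_numpy().astype(np.int64) - 1
    run = trials["run"].to_numpy()
    run_start = np.zeros(len(trials), dtype=np.int64)
    run_start[0] = 1
    run_start[1:] = (run[1:] != run[:-1]).astype(np.int64)
    rew_act = (trials["rewarded_action"].to_numpy() == "right").astype(np.int64)
    avail = trials["reward_available"].to_numpy().astype(np.int64)
    return {"s_idx": s_idx.astype(np.int64), "cat": cat,
            "run_start": run_start, "rewarded_action": rew_act,
            "reward_available": avail}


def encode_choices(trials) -> tuple[np.ndarray, np.ndarray]:
    """Choices (-1 = missed) and rewards from a behavioral record table."""
    chosen = np.full(len(trials), -1, dtype=np.int64)
    act = trials["chosen_action"].to_numpy()
    missed = trials["missed"].to_numpy().astype(bool)
    chosen[~missed & (act == "left")] = 0
    chosen[~missed & (act == "right")] = 1
    reward = trials["reward"].to_numpy().astype(np.int64)
    return chosen, reward


def _alloc(n):
    return (np.empty(n, dtype=np.int64), np.empty(n, dtype=np.int64),
            np.empty(n), np.empty(n), np.empty(n), np.empty(n),
            np.empty(n), np.empty(n))


def replay_nll(arrays: dict, chosen: np.ndarray, reward: np.ndarray,
               spec: ModelSpec, params: Params,
               reset_v0: bool = False, return_traces: bool = False):
    """NLL of observed choices with all latent updates replayed from the
    record's own outcomes."""
    n = len(arrays["s_idx"])
    mb, kind = model_flags(spec)
    outs = _alloc(n)
    dummy = np.zeros(n, dtype=np.int64)
    du = np.zeros(n)
    nll = run_core(MODE_REPLAY, arrays["s_idx"], arrays["cat"],
                   arrays["run_start"], chosen, reward,
                   dummy, dummy, du,
                   pack_params(params), mb, kind, int(reset_v0), *outs)
    if return_traces:
        return nll, _traces_dict(outs)
    return nll


def simulate_choices(arrays: dict, spec: ModelSpec, params: Params,
                     rng: np.random.Generator, reset_v0: bool = False):
    """Sample a full session of choices; rewards resolve from the schedule."""
    n = len(arrays["s_idx"])
    mb, kind = model_flags(spec)
    outs = _alloc(n)
    u = rng.random(n)
    dummy = np.zeros(n, dtype=np.int64)
    run_core(MODE_SIMULATE, arrays["s_idx"], arrays["cat"],
             arrays["run_start"], dummy, dummy,
             arrays["rewarded_action"], arrays["reward_available"], u,
             pack_params(params), mb, kind, int(reset_v0), *outs)
    return outs[0], outs[1], _traces_dict(outs)


def _traces_dict(outs):
    (_, _, p_left, v, dv, q_left, q_right, dq) = outs
    return {"p_left": p_left, "V0": v, "svpe": dv,
            "value_left": q_left, "value_right": q_right, "avpe": dq}
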