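"""Model-independent and model-derived behavioral statistics.

* first-generalization accuracy: within each constant-mapping epoch (a
  category's mapping changes exactly once per run, giving 2 epochs per
  category per run, hence 16 diagnostic opportunities per session), after the
  category's first rewarded state-action pair, the next encounter with the
  complementary state tests whether the complementary action is chosen before
  any direct feedback under the new contingency;
* conditional repeat probabilities in four bins (same/other antecedent state
  x rewarded/unrewarded antecedent), whose reward-effect difference between
  same- and other-state antecedents is the behavioral signature of
  discriminative state generalization;
* psychometric regressions of choice repetition (logistic, on the signed
  normalized action-value difference) and reaction time (linear, on its
  absolute value);
* posterior predictive checks: the same statistics applied to model
  simulations yoked to each subject's session, averaged over many runs;
* one-tailed group tests (one-sample and two-sample t, Pearson correlation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .models import Params, get_model
from .simulate import BehavioralRecord, replay_traces, run_agent

REPEAT_BINS = ("same_reward", "same_noreward", "other_reward",
               "other_noreward")


# ---------------------------------------------------------------------------
# first-generalization trials
# ---------------------------------------------------------------------------

def select_first_generalization_trials(record: BehavioralRecord
                                       ) -> pd.DataFrame:
    """One diagnostic trial per (run, category, mapping epoch).

    Returns a table with columns run, category, epoch, trial (session trial
    number of the diagnostic encounter) and correct; epochs lacking either a
    first reward or a subsequent complementary-state encounter (or whose
    diagnostic trial was missed) contribute no row.
    """
    tr = record.trials
    run = tr["run"].to_numpy()
    block = tr["block"].to_numpy()
    cat = tr["category"].to_numpy()
    is_b = (tr["state"].to_numpy() == "B").astype(int)
    missed = tr["missed"].to_numpy().astype(bool)
    reward = tr["reward"].to_numpy().astype(int)
    action = (tr["chosen_action"].to_numpy() == "right").astype(int)
    rew_act = (tr["rewarded_action"].to_numpy() == "right").astype(int)
    trial_no = tr["trial"].to_numpy()
    # per-block mapping of each category: action rewarded by its state A
    mapping = {}
    for i in range(len(tr)):
        mapping.setdefault((block[i], cat[i]),
                           rew_act[i] ^ is_b[i])

    rows = []
    for r in np.unique(run):
        for c in np.unique(cat):
            idx = np.flatnonzero((run == r) & (cat == c))
            # split the run's trials into constant-mapping epochs
            epochs, cur = [], None
            for i in idx:
                m = mapping[(block[i], cat[i])]
                if m != cur:
                    epochs.append([i])
                    cur = m
                else:
                    epochs[-1].append(i)
            for ei, members in enumerate(epochs):
                members = np.asarray(members)
                rewarded = members[reward[members] == 1]
                if not len(rewarded):
                    continue
                first = rewarded[0]
                comp_state = 1 - is_b[first]
                comp_action = 1 - action[first]
                later = members[(members > first)
                                & (is_b[members] == comp_state)]
                if not len(later):
                    continue
                diag = later[0]
                if missed[diag]:
                    continue  # dropped, not deferred
                rows.append({"run": int(r), "category": int(c),
                             "epoch": ei + 1, "trial": int(trial_no[diag]),
                             "correct": bool(action[diag] == comp_action)})
    return pd.DataFrame(rows,
                        columns=["run", "category", "epoch", "trial",
                                 "correct"])


def first_generalization_accuracy(record: BehavioralRecord) -> float:
    diag = select_first_generalization_trials(record)
    return float(diag["correct"].mean()) if len(diag) else math.nan


# ---------------------------------------------------------------------------
# conditional repeat probabilities
# ---------------------------------------------------------------------------

def conditional_repeat_probabilities(record: BehavioralRecord) -> dict:
    """P(repeat the antecedent trial's action) in four bins.

    For each non-missed trial, the antecedents are the most recent trial of
    the same state and the most recent trial of the category's other state
    (both within the same run); each is binned by whether it was rewarded.
    Antecedent trials without a response are excluded. The interaction
    statistic is (same: P_rew - P_norew) - (other: P_rew - P_norew).
    """
    tr = record.trials
    run = tr["run"].to_numpy()
    key = (tr["category"].to_numpy() - 1) * 2 \
        + (tr["state"].to_numpy() == "B")
    missed = tr["missed"].to_numpy().astype(bool)
    reward = tr["reward"].to_numpy().astype(int)
    action = (tr["chosen_action"].to_numpy() == "right").astype(int)
    other_key = key ^ 1  # complementary state within the category

    tallies = {b: [0, 0] for b in REPEAT_BINS}  # repeats, total
    last: dict[int, int] = {}
    prev_run = None
    for i in range(len(tr)):
        if run[i] != prev_run:
            last = {}
            prev_run = run[i]
        if not missed[i]:
            for k, which in ((key[i], "same"), (other_key[i], "other")):
                j = last.get(k)
                if j is None or missed[j]:
                    continue
                b = f"{which}_{'reward' if reward[j] else 'noreward'}"
                tallies[b][1] += 1
                tallies[b][0] += int(action[i] == action[j])
        last[key[i]] = i
    out = {}
    for b, (rep, n) in tallies.items():
        out[b] = rep / n if n else math.nan
        out[f"n_{b}"] = n
    out["interaction"] = ((out["same_reward"] - out["same_noreward"])
                          - (out["other_reward"] - out["other_noreward"]))
    return out


# ---------------------------------------------------------------------------
# psychometric regressions
# ---------------------------------------------------------------------------

@dataclass
class PsychometricFit:
    slope: float
    intercept: float
    n: int
    degenerate: bool = False


def _policy_values(record: BehavioralRecord, fit_or_params,
                   model_id: str | None = None) -> pd.DataFrame:
    from .fitting import FitResult
    if isinstance(fit_or_params, FitResult):
        return replay_traces(record, fit_or_params.model_id,
                             fit_or_params.build_params())
    if isinstance(fit_or_params, Params):
        return replay_traces(record, get_model(model_id or "AX|SY"),
                             fit_or_params)
    raise TypeError("pass a FitResult or Params")


def psychometric_choice(record: BehavioralRecord, fit_or_params,
                        model_id: str | None = None) -> PsychometricFit:
    """Logistic regression of repeating the most recent action on the signed
    normalized action-value difference (positive toward the previous action).
    Subjects who always or never repeat are flagged degenerate."""
    traces = _policy_values(record, fit_or_params, model_id)
    tr = record.trials.reset_index(drop=True)
    dq = (traces["value_left"] - traces["value_right"]).to_numpy()

    prev_action = None
    xs, ys = [], []
    for i, row in tr.iterrows():
        if row["missed"]:
            continue
        if prev_action is not None:
            signed = dq[i] if prev_action == "left" else -dq[i]
            xs.append(signed)
            ys.append(int(row["chosen_action"] == prev_action))
        prev_action = row["chosen_action"]
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys)
    norm = np.max(np.abs(xs))
    if norm > 0:
        xs = xs / norm
    if len(set(ys)) < 2 or len(xs) < 3:
        return PsychometricFit(math.nan, math.nan, len(xs), degenerate=True)
    model = sm.GLM(ys, sm.add_constant(xs), family=sm.families.Binomial())
    res = model.fit()
    return PsychometricFit(float(res.params[1]), float(res.params[0]),
                           len(xs))


def psychometric_rt(record: BehavioralRecord, fit_or_params,
                    model_id: str | None = None) -> PsychometricFit:
    """Linear regression of RT on the normalized absolute action-value
    difference (hypothesis: negative slope — faster when values differ)."""
    traces = _policy_values(record, fit_or_params, model_id)
    tr = record.trials.reset_index(drop=True)
    ok = (~tr["missed"]) & tr["reaction_time"].notna()
    if ok.sum() < 3:
        return PsychometricFit(math.nan, math.nan, int(ok.sum()),
                               degenerate=True)
    x = np.abs(traces["value_left"] - traces["value_right"]).to_numpy()[ok]
    norm = np.max(x)
    if norm > 0:
        x = x / norm
    y = tr.loc[ok, "reaction_time"].to_numpy(dtype=float)
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return PsychometricFit(float(res.params[1]), float(res.params[0]),
                           int(ok.sum()))


# ---------------------------------------------------------------------------
# group statistics (all one-tailed, directions fixed a priori)
# ---------------------------------------------------------------------------

def one_sample_t(values, popmean: float = 0.0,
                 alternative: str = "greater") -> dict:
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if len(values) < 2 or np.std(values) == 0:
        return {"t": math.nan, "p": math.nan, "n": len(values),
                "mean": float(np.mean(values)) if len(values) else math.nan,
                "flag": "degenerate"}
    t, p = stats.ttest_1samp(values, popmean, alternative=alternative)
    return {"t": float(t), "p": float(p), "n": len(values),
            "mean": float(np.mean(values)), "flag": None}

def two_sample_t(x, y, alternative: str = "greater") -> dict:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        return {"t": math.nan, "p": math.nan, "n": (len(x), len(y)),
                "flag": "group too small"}
    t, p = stats.ttest_ind(x, y, alternative=alternative)
    return {"t": float(t), "p": float(p), "n": (len(x), len(y)),
            "mean_diff": float(np.mean(x) - np.mean(y)), "flag": None}


def pearson_one_tailed(x, y, alternative: str = "greater") -> dict:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return {"r": math.nan, "p": math.nan, "n": len(x),
                "flag": "degenerate"}
    res = stats.pearsonr(x, y, alternative=alternative)
    return {"r": float(res.statistic), "p": float(res.pvalue), "n": len(x),
            "flag": None}


def first_generalization_accuracy_tests(accuracies: dict[str, list[float]],
                                        g_S: list[float] | None = None,
                                        acc_by_subject: list[float] | None = None
                                        ) -> dict:
    """Group tests of first-generalization accuracy.

    ``accuracies`` maps generalizer-group labels to per-subject accuracies.
    One-tailed one-sample tests vs 50% (Discriminative above; Associative
    below), pairwise one-tailed two-sample tests in the hypothesized order
    Discriminative > Nongeneralizer > Associative, and (optionally) the
    correlation of accuracy with the fitted state-generalization weight
    (hypothesis: more negative g_S, higher accuracy, i.e. r < 0).
    """
    out = {"groups": {}}
    directions = {"Discriminative": "greater", "Nongeneralizer": "two-sided",
                  "Associative": "less"}
    for grp, vals in accuracies.items():
        out["groups"][grp] = one_sample_t(
            vals, 0.5, directions.get(grp, "two-sided"))
    order = ["Discriminative", "Nongeneralizer", "Associative"]
    present = [g for g in order if g in accuracies]
    for i, hi in enumerate(present):
        for lo in present[i + 1:]:
            out[f"{hi}>{lo}"] = two_sample_t(accuracies[hi], accuracies[lo],
                                             alternative="greater")
    if g_S is not None and acc_by_subject is not None:
        out["corr_gS_accuracy"] = pearson_one_tailed(
            g_S, acc_by_subject, alternative="less")
    return out


# ---------------------------------------------------------------------------
# posterior predictive check
# ---------------------------------------------------------------------------

def posterior_predictive_check(records: list[BehavioralRecord],
                               fits: list, n_sims: int = 100,
                               seed: int = 0) -> pd.DataFrame:
    """Yoked-simulation statistics per subject, averaged over ``n_sims``.

    ``fits`` holds one FitResult (or (model_id, Params) pair) per record.
    For each subject, agents with the fitted parameters replay the subject's
    session; first-generalization accuracy and the four repeat bins are
    averaged across simulations and reported next to the subject's own
    statistics.
    """
    from .fitting import FitResult
    rng = np.random.default_rng(seed)
    rows = []
    for i, (rec, fit) in enumerate(zip(records, fits)):
        if isinstance(fit, FitResult):
            model_id, params = fit.model_id, fit.build_params()
        else:
            model_id, params = fit[0], fit[1]
        spec = get_model(model_id)
        session = rec.session
        if session is None:
            raise ValueError("record lacks its session; yoked simulation "
                             "needs the schedule")
        fg, bins = [], {b: [] for b in REPEAT_BINS}
        inter = []
        for _ in range(n_sims):
            sim = run_agent(session, spec, params,
                            seed=np.random.default_rng(
                                int(rng.integers(2 ** 31))),
                            yoked_to=rec, record_traces=False)
            fg.append(first_generalization_accuracy(sim))
            rb = conditional_repeat_probabilities(sim)
            for b in REPEAT_BINS:
                bins[b].append(rb[b])
            inter.append(rb["interaction"])
        obs_bins = conditional_repeat_probabilities(rec)
        row = {"subject": i, "model_id": model_id,
               "ppc_first_gen": float(np.nanmean(fg)),
               "obs_first_gen": first_generalization_accuracy(rec),
               "ppc_interaction": float(np.nanmean(inter)),
               "obs_interaction": obs_bins["interaction"]}
        for b in REPEAT_BINS:
            row[f"ppc_{b}"] = float(np.nanmean(bins[b]))
            row[f"obs_{b}"] = obs_bins[b]
        rows.append(row)
    return pd.DataFrame(rows)
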