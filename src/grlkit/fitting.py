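"""Subject-level maximum-likelihood fitting, AICc model comparison, and
learner / generalizer classification.

Each model's free parameters are mapped to an unconstrained space (scaled
logit over their natural bounds) and optimized with randomly restarted
Nelder-Mead simplex runs on the session negative log-likelihood; results are
reported back-transformed. Model comparison penalizes complexity with the
finite-sample-corrected Akaike information criterion,

    AICc = 2k + 2*NLL + 2k(k+1) / (n - k - 1),

with k the model's degrees of freedom and n the number of non-missed trials.
Goodness of fit is summarized as residual deviance relative to the
outcome-insensitive hysteresis baseline (positive = better than hysteresis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import engine
from .models import (MODEL_REGISTRY, PARAM_BOUNDS, ModelSpec, Params,
                     get_model, reward_sensitivity)
from .simulate import BehavioralRecord

__all__ = [
    "FitResult", "negative_log_likelihood", "fit_mle", "compare_models",
    "classify_learner", "classify_generalizer", "reward_sensitivity",
    "aicc", "model_recovery",
]


def aicc(nll: float, k: int, n: int) -> float:
    """Finite-sample-corrected Akaike information criterion."""
    if n - k - 1 <= 0:
        return math.inf
    return 2 * k + 2 * nll + 2 * k * (k + 1) / (n - k - 1)


@dataclass
class FitResult:
    model_id: str
    params: dict[str, float]
    nll: float
    n_trials: int
    n_restarts: int
    converged: bool

    @property
    def deviance(self) -> float:
        return 2.0 * self.nll

    @property
    def df(self) -> int:
        return get_model(self.model_id).df

    @property
    def aicc(self) -> float:
        return aicc(self.nll, self.df, self.n_trials)

    def build_params(self) -> Params:
        return get_model(self.model_id).build_params(self.params)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _encode(record: BehavioralRecord):
    arrays = engine.encode_session_arrays(record.trials)
    chosen, reward = engine.encode_choices(record.trials)
    return arrays, chosen, reward


def negative_log_likelihood(record: BehavioralRecord, spec: ModelSpec | str,
                            params: Params) -> float:
    """NLL (nats) of the record's non-missed choices under the model, with
    all value/belief updates replayed deterministically from the record's own
    outcome sequence."""
    if isinstance(spec, str):
        spec = get_model(spec)
    _check_bounds(spec, params)
    if len(record.trials) == 0:
        return 0.0
    arrays, chosen, reward = _encode(record)
    return float(engine.replay_nll(arrays, chosen, reward, spec, params))


def _check_bounds(spec: ModelSpec, params: Params) -> None:
    if params.tau <= 0:
        raise ValueError("tau must be positive")
    for name in spec.free:
        lo, hi = PARAM_BOUNDS[name]
        v = getattr(params, name)
        if not (lo - 1e-9 <= v <= hi + 1e-9):
            raise ValueError(f"parameter {name}={v} outside [{lo}, {hi}]")


# ---------------------------------------------------------------------------
# bounded <-> unconstrained transforms
# ---------------------------------------------------------------------------

_EXPIT_CLIP = 30.0


def _to_natural(y: np.ndarray, names) -> dict[str, float]:
    out = {}
    for yi, name in zip(y, names):
        lo, hi = PARAM_BOUNDS[name]
        z = 1.0 / (1.0 + math.exp(-np.clip(yi, -_EXPIT_CLIP, _EXPIT_CLIP)))
        out[name] = lo + (hi - lo) * z
    return out


def _to_unconstrained(values: dict[str, float], names) -> np.ndarray:
    y = []
    for name in names:
        lo, hi = PARAM_BOUNDS[name]
        z = (values[name] - lo) / (hi - lo)
        z = min(max(z, 1e-9), 1 - 1e-9)
        y.append(math.log(z / (1 - z)))
    return np.array(y)


def fit_mle(record: BehavioralRecord, spec: ModelSpec | str,
            n_restarts: int = 10, seed: int = 0, *,
            init_points: list[dict] | None = None,
            maxiter: int = 2000) -> FitResult:
    """Best-of-restarts Nelder-Mead maximum-likelihood fit.

    Restarts draw uniform-in-bounds starting points from ``seed``;
    ``init_points`` (natural-space dicts) are prepended as additional starts,
    which also makes nested-model dominance checks exact. Deterministic given
    the seed. If no restart converges the best point is still returned with
    ``converged=False``.
    """
    if isinstance(spec, str):
        spec = get_model(spec)
    names = spec.free
    arrays, chosen, reward = _encode(record)
    n_eff = int((chosen >= 0).sum())

    if not names:  # chance model: nothing to optimize
        nll = float(engine.replay_nll(arrays, chosen, reward, spec, Params()))
        return FitResult(spec.model_id, {}, nll, n_eff, 0, True)

    def objective(y):
        params = spec.build_params(_to_natural(y, names))
        return engine.replay_nll(arrays, chosen, reward, spec, params)

    rng = np.random.default_rng(seed)
    starts = []
    if init_points:
        starts.extend(_to_unconstrained(pt, names) for pt in init_points)
    mid = _to_unconstrained(
        {n: 0.5 * (PARAM_BOUNDS[n][0] + PARAM_BOUNDS[n][1]) if n != "tau"
         else 1.0 for n in names}, names)
    starts.append(mid)
    while len(starts) < n_restarts + (len(init_points) if init_points else 0):
        draw = {n: rng.uniform(*PARAM_BOUNDS[n]) if n != "tau"
                else rng.uniform(0.05, 3.0) for n in names}
        starts.append(_to_unconstrained(draw, names))

    best = None
    any_converged = False
    for y0 in starts:
        res = optimize.minimize(objective, y0, method="Nelder-Mead",
                                options={"maxiter": maxiter, "xatol": 1e-4,
                                         "fatol": 1e-7, "adaptive": True})
        any_converged = any_converged or bool(res.success)
        key = (res.fun, res.nit)
        if best is None or key < best[0]:
            best = (key, res)
    res = best[1]
    values = _to_natural(res.x, names)
    return FitResult(spec.model_id, values, float(res.fun), n_eff,
                     len(starts), any_converged)


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

# Warm-start map: each model is additionally initialized at the fitted optimum
# of nested submodels (parent id, parameter fill-ins completing the free set).
# This enforces likelihood monotonicity across nesting in practice and removes
# the optimizer noise that otherwise handicaps higher-dimensional models.
NESTED_INITS: dict[str, list[tuple[str, dict]]] = {
    "A0|S0": [("hysteresis", {"alpha": 0.0})],
    "A-|S0": [("A0|S0", {})],
    "A0|S+": [("A0|S0", {})],
    "A0|S-": [("A0|S0", {})],
    "A-|S+": [("A0|S0", {})],
    "A-|S-": [("A0|S0", {})],
    "AX|S0": [("A0|S0", {"g_A": 0.0}), ("A-|S0", {"g_A": -1.0})],
    "A0|SY": [("A0|S0", {"g_S": 0.0}), ("A0|S-", {"g_S": -1.0}),
              ("A0|S+", {"g_S": 1.0})],
    "AW|SW": [("A0|S0", {"g_S": 0.0}), ("A-|S-", {"g_S": -1.0})],
    "AX|SY": [("A0|SY", {"g_A": 0.0}), ("AX|S0", {"g_S": 0.0}),
              ("A-|S-", {"g_A": -1.0, "g_S": -1.0})],
    "AX|SY|Z": [("AX|SY", {})],
    "SPE": [("hysteresis", {"alpha_SPE": 0.0})],
    "HMM0": [("hysteresis", {"theta_0": 0.5})],
    "HMM": [("HMM0", {"theta_1": 0.0})],
    "SPE+RL": [("SPE", {"alpha": 0.3, "w_MB": 1.0}),
               ("A0|S0", {"alpha_SPE": 0.3, "w_MB": 0.0})],
    "HMM0+RL": [("HMM0", {"alpha": 0.3, "w_MB": 1.0}),
                ("A0|S0", {"theta_0": 0.7, "w_MB": 0.0})],
    "HMM+RL": [("HMM", {"alpha": 0.3, "w_MB": 1.0}),
               ("HMM0+RL", {"theta_1": 0.0})],
}


def _nested_init_points(model_id: str, fitted: dict[str, "FitResult"]
                        ) -> list[dict]:
    """Natural-space starting points from already-fitted nested models."""
    spec = get_model(model_id)
    points = []
    for parent_id, fill in NESTED_INITS.get(model_id, []):
        parent = fitted.get(parent_id)
        if parent is None:
            continue
        point = {**parent.params, **fill}
        # complete any remaining free parameters of the child with the
        # fixed value the parent implies (or its tied value)
        parent_params = get_model(parent_id).build_params(parent.params)
        for name in spec.free:
            if name not in point:
                point[name] = getattr(parent_params, name)
        points.append({k: v for k, v in point.items() if k in spec.free})
    return points


def _dependency_order(model_ids: list[str]) -> list[str]:
    """Order models so nested parents are fitted before their supersets."""
    ordered: list[str] = []
    seen: set[str] = set()

    def visit(mid):
        if mid in seen:
            return
        seen.add(mid)
        for parent_id, _ in NESTED_INITS.get(mid, []):
            if parent_id in model_ids:
                visit(parent_id)
        ordered.append(mid)

    for mid in model_ids:
        visit(mid)
    return ordered


def _winner(rows: pd.DataFrame) -> str:
    """argmin AICc; ties broken toward fewer degrees of freedom."""
    best = rows.sort_values(["aicc", "df"], kind="mergesort").iloc[0]
    return str(best["model_id"])


def compare_models(records: list[BehavioralRecord],
                   model_ids: list[str] | None = None,
                   n_restarts: int = 10, seed: int = 0,
                   baseline: str = "hysteresis") -> pd.DataFrame:
    """Fit every model to every record; returns a long table with one row per
    (subject, model): NLL, deviance, AICc, residuals vs the baseline model
    (with and without the complexity penalty), and per-subject winner flags.
    """
    if model_ids is None:
        model_ids = list(MODEL_REGISTRY)
    if baseline not in model_ids:
        model_ids = [*model_ids, baseline]
    order = _dependency_order(model_ids)
    rows = []
    for i, rec in enumerate(records):
        fitted: dict[str, FitResult] = {}
        for mid in order:
            fit = fit_mle(rec, mid, n_restarts=n_restarts,
                          seed=seed + 7919 * i,
                          init_points=_nested_init_points(mid, fitted))
            fitted[mid] = fit
            rows.append({
                "subject": i, "model_id": mid, "df": fit.df, "nll": fit.nll,
                "deviance": fit.deviance, "aicc": fit.aicc,
                "n_trials": fit.n_trials,
                "params": fit.params, "converged": fit.converged,
            })
    table = pd.DataFrame(rows)
    base = table[table["model_id"] == baseline].set_index("subject")
    table["resid_deviance"] = (
        table["subject"].map(base["deviance"]) - table["deviance"])
    table["resid_aicc"] = table["subject"].map(base["aicc"]) - table["aicc"]
    winners = table.groupby("subject", group_keys=False).apply(
        _winner, include_groups=False)
    table["winner"] = table["subject"].map(winners) == table["model_id"]
    return table


def winner_counts(comparison: pd.DataFrame) -> pd.Series:
    return (comparison[comparison["winner"]]
            .groupby("model_id").size().sort_values(ascending=False))


def model_recovery(generator: str, model_ids: list[str], n_subjects: int,
                   seed: int = 0, n_restarts: int = 5,
                   overrides: dict | None = None,
                   truncate: dict | None = None,
                   records: list[BehavioralRecord] | None = None):
    """Simulate a cohort from ``generator`` and refit the candidate set.

    Returns ``(comparison_table, winner_counts)`` — the confusion summary for
    one generating model (one row of a model-recovery confusion matrix).
    """
    from .simulate import simulate_cohort
    if records is None:
        records = simulate_cohort(n_subjects, generator, seed=seed,
                                  overrides=overrides, truncate=truncate)
    table = compare_models(records, model_ids, n_restarts=n_restarts,
                           seed=seed + 1)
    return table, winner_counts(table)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def first_encounter_mask(trials: pd.DataFrame) -> np.ndarray:
    """True on each cue's first presentation (cue identities are per-run in
    the face/house variant and session-constant in the color/motion variant,
    which the cue_id encoding already reflects)."""
    return trials["cue_id"].duplicated(keep="first").to_numpy() == False  # noqa: E712


def task_accuracy(record: BehavioralRecord) -> tuple[float, int, int]:
    """Accuracy excluding initial encounters with novel cues; returns
    (accuracy, n_correct, n_eligible)."""
    tr = record.trials
    eligible = ~first_encounter_mask(tr) & ~tr["missed"].to_numpy()
    sub = tr[eligible]
    n = len(sub)
    if n == 0:
        return math.nan, 0, 0
    k = int((sub["chosen_action"] == sub["rewarded_action"]).sum())
    return k / n, k, n


def classify_learner(record: BehavioralRecord,
                     comparison: pd.DataFrame | None = None,
                     fits: dict[str, FitResult] | None = None,
                     alpha_level: float = 0.05) -> str:
    """Good / Poor / Nonlearner classification.

    Good: accuracy (excluding first cue encounters) above 50% by a one-tailed
    exact binomial test. Otherwise Poor if the best learning model improves on
    the hysteresis baseline after the AICc penalty, else Nonlearner.
    """
    acc, k, n = task_accuracy(record)
    if n == 0:
        return "unclassifiable"
    p = stats.binomtest(k, n, 0.5, alternative="greater").pvalue
    if p < alpha_level:
        return "Good"
    if comparison is not None:
        sub = comparison
        if "subject" in sub.columns and sub["subject"].nunique() > 1:
            raise ValueError("pass the comparison rows of a single subject")
        hyst = float(sub.loc[sub["model_id"] == "hysteresis", "aicc"].iloc[0])
        learning = sub[sub["model_id"].map(
            lambda m: MODEL_REGISTRY[m].kind == "learner")]
        best = float(learning["aicc"].min())
    elif fits is not None:
        hyst = fits["hysteresis"].aicc
        best = min(f.aicc for m, f in fits.items()
                   if MODEL_REGISTRY[m].kind == "learner")
    else:
        raise ValueError("need a comparison table or fits to separate "
                         "Poor from Nonlearner")
    return "Poor" if best < hyst else "Nonlearner"


def classify_generalizer(g_S: float | FitResult,
                         eps: float = 1e-3) -> str:
    """Sign of the fitted state-generalization weight: Discriminative
    (g_S < 0), Nongeneralizer (|g_S| <= eps), Associative (g_S > 0)."""
    if isinstance(g_S, FitResult):
        g_S = g_S.params.get("g_S", 0.0)
    if abs(g_S) <= eps:
        return "Nongeneralizer"
    return "Discriminative" if g_S < 0 else "Associative"
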