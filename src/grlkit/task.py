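"""Hierarchical reversal-learning task: session generation and counterbalancing.

The task presents one of four cues per trial (2 categories x 2 states) in a
two-armed bandit. Within each category the two states always reward opposite
actions ("metastate" AL/BR or AR/BL), and exactly one action per state carries
a nonzero reward probability. A session comprises 4 runs x 3 blocks x 32
trials; reward probabilities are expressed in sixteenths and realized as exact
per-block reward counts, so a constant-action chooser is guaranteed to earn
exactly half of all scheduled rewards and each run carries exactly one quarter
of them.

Block conditions form a (nearly) 3 x 2 x 4 factorial:

* condition 3 -- relative category value: category-1-greater, category-2-greater
  or equal. The greater category's states pay 10/16 and 16/16; the lesser
  category pays 7/16 for both states; in the equal condition both categories
  pay 7/16 and 13/16.
* condition 2 -- which state (A or B) is the higher-valued one, partially
  balanced 2:1 within a run.
* condition 4 -- the mapping of states to rewarded actions for both categories
  (LR&LR, LR&RL, RL&LR, RL&RL), fully crossed with condition 3 across the
  session. Consecutive blocks within a run differ by remapping exactly one
  category; each category is remapped exactly once per run.

Odd net probabilities (7/16, 13/16) are realized as half-split block pairs
(3 and 4, or 6 and 7, rewards per 8 state-trials) whose counts average to the
net probability.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

ACTIONS = ("left", "right")
CATEGORIES = (1, 2)
STATES = ("A", "B")
# metastate 0: state A rewards left, state B rewards right ("AL/BR");
# metastate 1: the reverse ("AR/BL").
METASTATE_LABELS = ("AL/BR", "AR/BL")

ISI_SECONDS = 3.0
RESPONSE_WINDOW_SECONDS = 2.0
OUTCOME_SECONDS = 1.0
ITI_MIN, ITI_MAX, ITI_STEP = 3.0, 7.0, 1.0 / 24.0


class DesignError(ValueError):
    """Raised when a task configuration cannot satisfy the counterbalancing."""


@dataclass(frozen=True)
class TaskConfig:
    n_runs: int = 4
    blocks_per_run: int = 3
    trials_per_block: int = 32
    n_categories: int = 2
    states_per_category: int = 2
    actions: tuple[str, str] = ACTIONS
    probability_grid: int = 16
    variant: str = "3FH"  # "3FH": fresh cues each run; "7CM": constant cues
    rng_seed: int = 0

    def __post_init__(self):
        if self.trials_per_block % 4 != 0:
            raise DesignError("trials_per_block must be divisible by 4")
        if self.n_categories != 2 or self.states_per_category != 2:
            raise DesignError("design requires 2 categories x 2 states")
        if self.probability_grid != 16:
            raise DesignError("reward probabilities are defined in sixteenths")
        if self.blocks_per_run != 3:
            raise DesignError("the 3-level category-value condition requires "
                              "3 blocks per run")
        if self.n_runs != 4:
            raise DesignError("full crossing of the 4 action mappings over the "
                              "3-level condition requires 4 runs")
        tps = self.trials_per_block // 4
        if (tps * 2) % 16 != 0 and tps % 8 != 0:
            raise DesignError("trials per state per block must allow exact "
                              "sixteenth-probability reward counts")
        if self.variant not in ("3FH", "7CM"):
            raise DesignError(f"unknown variant {self.variant!r}")

    @property
    def trials_per_state(self) -> int:
        return self.trials_per_block // 4

    @property
    def n_blocks(self) -> int:
        return self.n_runs * self.blocks_per_run

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block


@dataclass
class BlockSpec:
    block_index: int              # 1..12 across the session
    run: int                      # 1..4
    block_in_run: int             # 1..3
    condition_3: str              # "cat1_greater" | "cat2_greater" | "equal"
    condition_2: str              # high-valued state, "A" | "B"
    condition_4: str              # e.g. "LR&RL"
    metastate: dict[int, int]     # category -> 0 (AL/BR) or 1 (AR/BL)
    reward_prob: dict[tuple[int, str], float]   # (category, state) -> k/16 net
    reward_count: dict[tuple[int, str], int]    # (category, state) -> count
    remapped_category: int | None = None        # None for first block of a run

    def rewarded_action(self, category: int, state: str) -> str:
        m = self.metastate[category]
        if state == "A":
            return ACTIONS[m]
        return ACTIONS[1 - m]


@dataclass
class Session:
    config: TaskConfig
    blocks: list[BlockSpec]
    trials: pd.DataFrame
    counterbalancing_report: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def to_files(self, trials_path, blocks_path=None) -> None:
        """Write the trial table as TSV and the block table as JSON."""
        self.trials.to_csv(trials_path, sep="\t", index=False, na_rep="NA")
        if blocks_path is not None:
            payload = {
                "config": asdict(self.config),
                "blocks": [
                    {**asdict(b),
                     "metastate": {str(k): v for k, v in b.metastate.items()},
                     "reward_prob": {f"{c}{s}": p for (c, s), p in b.reward_prob.items()},
                     "reward_count": {f"{c}{s}": n for (c, s), n in b.reward_count.items()}}
                    for b in self.blocks
                ],
            }
            with open(blocks_path, "w") as fh:
                json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# condition assignment
# ---------------------------------------------------------------------------

C3_LEVELS = ("cat1_greater", "cat2_greater", "equal")


def _c4_label(v: tuple[int, int]) -> str:
    return "&".join("LR" if m == 0 else "RL" for m in v)


def _chains():
    """All 8 single-remap chains of 3 mappings (start vertex x flip order)."""
    chains = []
    for v0 in itertools.product((0, 1), (0, 1)):
        for first in (0, 1):
            v1 = list(v0)
            v1[first] ^= 1
            v2 = list(v1)
            v2[1 - first] ^= 1
            chains.append((tuple(v0), tuple(v1), tuple(v2)))
    return chains


def _valid_chain_combos(c3_by_run, chains):
    valid = []
    for combo in itertools.product(range(8), repeat=4):
        seen: dict[str, set] = {lev: set() for lev in C3_LEVELS}
        ok = True
        for r, ci in enumerate(combo):
            for pos in range(3):
                lev = c3_by_run[r][pos]
                v = chains[ci][pos]
                if v in seen[lev]:
                    ok = False
                    break
                seen[lev].add(v)
            if not ok:
                break
        if ok:
            valid.append(combo)
    return valid


def _assign_conditions_3_and_4(rng: np.random.Generator):
    """Jointly choose per-run condition-3 orders and remap chains so that each
    run holds one block of each condition-3 level and every (condition 3,
    mapping) pair occurs exactly once across the session.

    Not every combination of per-run level orders admits a chain assignment
    (the third block of a remap chain is always the double flip of the first),
    so level orders and chains are sampled together.
    """
    chains = _chains()
    perms = list(itertools.permutations(C3_LEVELS))
    for _ in range(200):
        c3_by_run = [list(perms[rng.integers(6)]) for _ in range(4)]
        valid = _valid_chain_combos(c3_by_run, chains)
        if valid:
            combo = valid[rng.integers(len(valid))]
            return c3_by_run, [[chains[ci][pos] for pos in range(3)]
                               for ci in combo]
    raise DesignError("no remap-chain assignment satisfies the 3x4 cross")


def _assign_condition2(c3_by_run, c4_by_run, rng):
    """Choose the high-valued state per block subject to the exact
    action-balance pairings and the 2:1 within-run quota."""
    # index blocks by (run, pos)
    blocks = [(r, p) for r in range(4) for p in range(3)]

    def level_blocks(level):
        return [(r, p) for (r, p) in blocks if c3_by_run[r][p] == level]

    valid = []
    for bits in range(1 << 12):
        h = {blocks[i]: "A" if (bits >> i) & 1 else "B" for i in range(12)}
        ok = True
        # greater categories: within each same-mapping pair, h must differ
        for level, cat in (("cat1_greater", 0), ("cat2_greater", 1)):
            lb = level_blocks(level)
            for m in (0, 1):
                pair = [b for b in lb if c4_by_run[b[0]][b[1]][cat] == m]
                if h[pair[0]] == h[pair[1]]:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            # equal blocks: each category contributes its high state to the
            # fixed action in exactly 2 of the 4 equal blocks
            eb = level_blocks("equal")
            for cat in (0, 1):
                n_high = sum(
                    1 for b in eb
                    if (c4_by_run[b[0]][b[1]][cat] == 0) == (h[b] == "A")
                )
                if n_high != 2:
                    ok = False
                    break
        if ok:
            # 2:1 quota: no run may be 3:0 on the high-state condition
            for r in range(4):
                vals = {h[(r, p)] for p in range(3)}
                if len(vals) == 1:
                    ok = False
                    break
        if ok:
            valid.append(h)
    if not valid:
        raise DesignError("no high-state assignment satisfies the balance "
                          "constraints")
    return valid[rng.integers(len(valid))]


def _reward_counts(c3_by_run, c4_by_run, h_by_block, tps, rng):
    """Exact reward counts per (run, pos, category, state).

    Scales sixteenth probabilities to ``tps`` trials per state per block;
    fractional counts (odd sixteenths) are realized as half-split pairs
    arranged so each pairing cancels in the fixed-action tally.
    """
    scale = tps / 16.0

    def split(k):
        # net count over one block for probability k/16; returns (low, high)
        x = k * 2 * scale / 2.0
        lo = int(np.floor(x))
        return (lo, lo) if x == lo else (lo, lo + 1)

    counts: dict[tuple[int, int, int, str], int] = {}
    probs: dict[tuple[int, int, int, str], float] = {}
    blocks = [(r, p) for r in range(4) for p in range(3)]

    def level_blocks(level):
        return [(r, p) for (r, p) in blocks if c3_by_run[r][p] == level]

    for level, greater in (("cat1_greater", 0), ("cat2_greater", 1)):
        lesser = 1 - greater
        lb = level_blocks(level)
        for b in lb:
            hi, lo_state = h_by_block[b], ("B" if h_by_block[b] == "A" else "A")
            counts[(*b, greater, hi)] = round(16 * scale)      # 16/16
            counts[(*b, greater, lo_state)] = round(10 * scale)  # 10/16
            probs[(*b, greater, hi)] = 1.0
            probs[(*b, greater, lo_state)] = 10 / 16
            probs[(*b, lesser, "A")] = 7 / 16
            probs[(*b, lesser, "B")] = 7 / 16
        # lesser category: both states 7/16; per block counts {lo, hi} summing
        # to lo+hi, with the left-contributing state's count alternating so the
        # four blocks cancel exactly.
        lo7, hi7 = split(7)
        for m in (0, 1):
            pair = [b for b in lb if c4_by_run[b[0]][b[1]][lesser] == m]
            pair = [pair[i] for i in rng.permutation(2)]
            # contributing state (the one rewarding the fixed reference
            # action under mapping m): A if m == 0 else B
            s_contrib = "A" if m == 0 else "B"
            s_other = "B" if m == 0 else "A"
            counts[(*pair[0], lesser, s_contrib)] = hi7
            counts[(*pair[0], lesser, s_other)] = lo7
            counts[(*pair[1], lesser, s_contrib)] = lo7
            counts[(*pair[1], lesser, s_other)] = hi7

    # equal blocks: per category one state at 13/16 (high) and one at 7/16
    eb = level_blocks("equal")
    lo7, hi7 = split(7)
    lo13, hi13 = split(13)
    for b in eb:
        for cat in (0, 1):
            hi_s = h_by_block[b]
            probs[(*b, cat, hi_s)] = 13 / 16
            probs[(*b, cat, "B" if hi_s == "A" else "A")] = 7 / 16
    for cat in (0, 1):
        contrib_high = [b for b in eb
                        if (c4_by_run[b[0]][b[1]][cat] == 0) == (h_by_block[b] == "A")]
        contrib_low = [b for b in eb if b not in contrib_high]
        # contributing-high pair realizes {lo13, hi13}; the low-state count in
        # those blocks complements to keep every block at the same total.
        for pair, highs in ((contrib_high, (lo13, hi13)),
                            (contrib_low, (hi13, lo13))):
            order = rng.permutation(2)
            for b, hcount in zip([pair[i] for i in order], highs):
                hi_s = h_by_block[b]
                lo_s = "B" if hi_s == "A" else "A"
                counts[(*b, cat, hi_s)] = hcount
                counts[(*b, cat, lo_s)] = (lo13 + hi13 + lo7 + hi7) // 2 - hcount
    return counts, probs


# ---------------------------------------------------------------------------
# trial ordering and reward scheduling
# ---------------------------------------------------------------------------

CUES = [(c, s) for c in CATEGORIES for s in STATES]


def order_trials(n_quartets: int, rng: np.random.Generator,
                 prev_cue=None, max_retries: int = 1000):
    """Sequence ``n_quartets`` quartets, each containing all four
    (category, state) cues once, with no cue on consecutive trials."""
    out = []
    for _ in range(n_quartets):
        for attempt in range(max_retries):
            perm = [CUES[i] for i in rng.permutation(4)]
            if perm[0] != prev_cue:
                break
        else:
            raise DesignError("could not satisfy the no-consecutive-cue "
                              "constraint within the retry budget")
        out.extend(perm)
        prev_cue = perm[-1]
    return out


def schedule_rewards(state_trial_idx: np.ndarray, count: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Pick exactly ``count`` of a state's trial positions to carry a reward."""
    if count < 0 or count > len(state_trial_idx):
        raise DesignError(f"reward count {count} infeasible for "
                          f"{len(state_trial_idx)} trials")
    chosen = set(rng.choice(state_trial_idx, size=count, replace=False).tolist())
    return np.array([i in chosen for i in state_trial_idx])


# ---------------------------------------------------------------------------
# session generation
# ---------------------------------------------------------------------------

def generate_session(config: TaskConfig | None = None, *, seed=None) -> Session:
    """Generate a complete counterbalanced session.

    All randomness flows from ``config.rng_seed`` (or ``seed`` override).
    The returned session has passed the full counterbalancing audit.
    """
    if config is None:
        config = TaskConfig(rng_seed=0 if seed is None else int(seed))
    elif seed is not None:
        config = TaskConfig(**{**asdict(config), "rng_seed": int(seed)})
    rng = np.random.default_rng(config.rng_seed)
    tps = config.trials_per_state

    c3_by_run, c4_by_run = _assign_conditions_3_and_4(rng)
    h_by_block = _assign_condition2(c3_by_run, c4_by_run, rng)
    counts, probs = _reward_counts(c3_by_run, c4_by_run, h_by_block, tps, rng)

    blocks: list[BlockSpec] = []
    rows = []
    prev_cue = None
    clock = 0.0
    trial_counter = 0
    for r in range(config.n_runs):
        iti_grid = ITI_MIN + ITI_STEP * np.arange(
            int(round((ITI_MAX - ITI_MIN) / ITI_STEP)) + 1)
        itis = rng.choice(iti_grid,
                          size=config.blocks_per_run * config.trials_per_block,
                          replace=False)
        run_trial = 0
        for p in range(config.blocks_per_run):
            v = c4_by_run[r][p]
            meta = {1: v[0], 2: v[1]}
            remapped = None
            if p > 0:
                prev_v = c4_by_run[r][p - 1]
                changed = [c for c in (0, 1) if v[c] != prev_v[c]]
                remapped = changed[0] + 1 if changed else None
            spec = BlockSpec(
                block_index=r * config.blocks_per_run + p + 1,
                run=r + 1, block_in_run=p + 1,
                condition_3=c3_by_run[r][p],
                condition_2=h_by_block[(r, p)],
                condition_4=_c4_label(v),
                metastate=meta,
                reward_prob={(c, s): probs[(r, p, c - 1, s)]
                             for c in CATEGORIES for s in STATES},
                reward_count={(c, s): counts[(r, p, c - 1, s)]
                              for c in CATEGORIES for s in STATES},
                remapped_category=remapped,
            )
            blocks.append(spec)

            cues = order_trials(config.trials_per_block // 4, rng, prev_cue)
            # 3FH replaces cues each run, so the constraint cannot bind
            # across run boundaries; 7CM cues persist for the whole session.
            if config.variant == "3FH" and p == config.blocks_per_run - 1:
                prev_cue = None
            else:
                prev_cue = cues[-1]

            cue_arr = np.array([f"{c}{s}" for c, s in cues])
            avail = np.zeros(config.trials_per_block, dtype=bool)
            for c in CATEGORIES:
                for s in STATES:
                    idx = np.flatnonzero(cue_arr == f"{c}{s}")
                    avail[idx] = schedule_rewards(
                        idx, spec.reward_count[(c, s)], rng)
            for t, (c, s) in enumerate(cues):
                iti = float(itis[run_trial])
                cue_id = (f"run{r + 1}_{c}{s}" if config.variant == "3FH"
                          else f"{c}{s}")
                rows.append({
                    "run": r + 1,
                    "block": spec.block_index,
                    "trial": trial_counter + 1,
                    "trial_in_block": t + 1,
                    "quartet": t // 4 + 1,
                    "category": c,
                    "state": s,
                    "cue_id": cue_id,
                    "rewarded_action": spec.rewarded_action(c, s),
                    "reward_available": bool(avail[t]),
                    "cue_onset": round(clock, 4),
                    "isi_onset": round(clock + RESPONSE_WINDOW_SECONDS, 4),
                    "outcome_onset": round(
                        clock + RESPONSE_WINDOW_SECONDS + ISI_SECONDS, 4),
                    "iti_duration": round(iti, 4),
                })
                clock += RESPONSE_WINDOW_SECONDS + ISI_SECONDS \
                    + OUTCOME_SECONDS + iti
                trial_counter += 1
                run_trial += 1

    trials = pd.DataFrame(rows)
    session = Session(config=config, blocks=blocks, trials=trials)
    report = validate_counterbalancing(session)
    if not report["passed"]:
        raise DesignError("generated session failed its own audit: "
                          + "; ".join(report["failures"]))
    session.counterbalancing_report = report
    return session


# ---------------------------------------------------------------------------
# audit
# ---------------------------------------------------------------------------

def validate_counterbalancing(session: Session) -> dict:
    """Audit a session against every design invariant. Reporting only."""
    cfg = session.config
    tr = session.trials
    failures = []
    checks = {}

    def check(name, ok, detail=None):
        checks[name] = {"passed": bool(ok), "detail": detail}
        if not ok:
            failures.append(name if detail is None else f"{name}: {detail}")

    check("total_trials", len(tr) == cfg.n_trials, len(tr))
    check("n_blocks", len(session.blocks) == cfg.n_blocks, len(session.blocks))

    # quartet composition and no consecutive cues
    quartet_ok = True
    for (_, _), grp in tr.groupby(["block", "quartet"]):
        if sorted(zip(grp["category"], grp["state"])) != sorted(CUES):
            quartet_ok = False
    check("quartet_composition", quartet_ok)
    same = (tr["cue_id"].values[1:] == tr["cue_id"].values[:-1])
    check("no_consecutive_cues", not same.any(), int(same.sum()))

    # exact reward counts per (block, category, state)
    counts_ok = True
    for b in session.blocks:
        blk = tr[tr["block"] == b.block_index]
        for c in CATEGORIES:
            for s in STATES:
                n = int(blk[(blk["category"] == c) & (blk["state"] == s)]
                        ["reward_available"].sum())
                if n != b.reward_count[(c, s)]:
                    counts_ok = False
    check("exact_reward_counts", counts_ok)

    total = int(tr["reward_available"].sum())
    left = int(tr[tr["rewarded_action"] == "left"]["reward_available"].sum())
    check("fixed_action_half", left * 2 == total, {"left": left, "total": total})

    run_tot = tr.groupby("run")["reward_available"].sum()
    quarter = total / cfg.n_runs
    check("per_run_quarter", bool((np.abs(run_tot - quarter) <= 1).all()),
          run_tot.to_dict())

    cat_ok = True
    for r, grp in tr.groupby("run"):
        per_cat = grp.groupby("category")["reward_available"].sum()
        if per_cat.nunique() != 1:
            cat_ok = False
    check("per_run_category_half", cat_ok)

    # remapping schedule
    remap_ok = True
    per_run_remaps: dict[int, list[int]] = {}
    for b in session.blocks:
        if b.block_in_run == 1:
            if b.remapped_category is not None:
                remap_ok = False
            continue
        prev = session.blocks[b.block_index - 2]
        changed = [c for c in CATEGORIES
                   if b.metastate[c] != prev.metastate[c]]
        if len(changed) != 1 or b.remapped_category != changed[0]:
            remap_ok = False
        per_run_remaps.setdefault(b.run, []).append(b.remapped_category)
    for r, cats in per_run_remaps.items():
        if sorted(c for c in cats if c is not None) != [1, 2]:
            remap_ok = False
    check("single_remapping", remap_ok)

    # condition 3: one level per run; 3 x 4 cross complete
    lv_ok = all(
        sorted(b.condition_3 for b in session.blocks if b.run == r + 1)
        == sorted(C3_LEVELS) for r in range(cfg.n_runs))
    check("condition3_per_run", lv_ok)
    cross = {(b.condition_3, b.condition_4) for b in session.blocks}
    check("condition3x4_cross", len(cross) == 12, len(cross))

    # condition 2: 2:1 within each run
    quota_ok = all(
        0 < sum(b.condition_2 == "A" for b in session.blocks if b.run == r + 1) < 3
        for r in range(cfg.n_runs))
    check("condition2_quota", quota_ok)

    # odd-probability half splits average to the net probability
    halves_ok = True
    by_prob: dict[tuple[str, int, float], list[int]] = {}
    for b in session.blocks:
        for c in CATEGORIES:
            for s in STATES:
                key = (b.condition_3, c, b.reward_prob[(c, s)])
                by_prob.setdefault(key, []).append(b.reward_count[(c, s)])
    for (lev, c, p), cs in by_prob.items():
        if abs(np.mean(cs) - p * cfg.trials_per_state) > 1e-9:
            halves_ok = False
    check("half_split_average", halves_ok)

    return {"passed": not failures, "failures": failures, "checks": checks,
            "scheduled_rewards": total}
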