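"""Emotional Go/NoGo task-design generation and validation.

Builds counterbalanced rapid event-related trial sequences: four trial
types (Go/NoGo crossed with neutral/aversive distractor), 2-s trials on a
2-s volume grid, pseudo-randomized inter-trial intervals from {2, 4, 6} s
distributed 30/40/30 (mean 4 s), first-order transition counterbalancing,
and per-type ITI-precedence balance.  Also selects distractor stimuli from
a normative valence/arousal ratings table by distance to extreme target
points in [arousal, valence] space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrialType",
    "Trial",
    "SessionDesign",
    "StimulusRating",
    "StimulusSelection",
    "DesignConfig",
    "generate_iti_sequence",
    "generate_session_design",
    "check_design_independence",
    "check_session_design",
    "select_stimuli",
]

TRIAL_TYPES = ("neutral-go", "aversive-go", "neutral-nogo", "aversive-nogo")

#: default session-level trial counts: 80/80/20/20 core + one neutral-go
#: lead trial per run (4 runs)
DEFAULT_COUNTS = {
    "neutral-go": 84,
    "aversive-go": 80,
    "neutral-nogo": 20,
    "aversive-nogo": 20,
}
DEFAULT_ITI_PROPORTIONS = {2: 0.3, 4: 0.4, 6: 0.3}
TRIAL_DURATION_S = 2.0


@dataclass(frozen=True)
class TrialType:
    """One of the four Go/NoGo × valence trial types."""

    label: str

    def __post_init__(self) -> None:
        if self.label not in TRIAL_TYPES:
            raise ValueError(f"unknown trial type {self.label!r}")

    @property
    def is_go(self) -> bool:
        return self.label.endswith("-go")

    @property
    def valence(self) -> str:
        return self.label.split("-")[0]


@dataclass(frozen=True)
class Trial:
    """A single 2-s trial with its preceding inter-trial interval."""

    type: str
    onset: float  # seconds from run start
    iti_before: float  # seconds, one of {2, 4, 6}
    duration: float = TRIAL_DURATION_S

    def __post_init__(self) -> None:
        if self.onset % 2 != 0:
            raise ValueError(f"onset {self.onset} not on the 2-s volume grid")


@dataclass
class SessionDesign:
    """Ordered trials for a session of runs, plus counterbalancing metadata."""

    runs: list[list[Trial]]
    run_duration: float = 330.0
    seed: int | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        c = {t: 0 for t in TRIAL_TYPES}
        for run in self.runs:
            for tr in run:
                c[tr.type] += 1
        return c

    @property
    def n_trials(self) -> int:
        return sum(len(r) for r in self.runs)

    def all_trials(self) -> list[tuple[int, Trial]]:
        return [(i, tr) for i, run in enumerate(self.runs) for tr in run]

    def to_table(self) -> pd.DataFrame:
        """Event table with one row per trial (TSV-serializable)."""
        rows = [
            {
                "run": i,
                "onset_s": tr.onset,
                "duration_s": tr.duration,
                "trial_type": tr.type,
                "iti_before_s": tr.iti_before,
            }
            for i, tr in self.all_trials()
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_table(cls, table: pd.DataFrame, run_duration: float = 330.0) -> "SessionDesign":
        runs: list[list[Trial]] = []
        for run_id, sub in table.groupby("run", sort=True):
            runs.append(
                [
                    Trial(
                        type=r.trial_type,
                        onset=float(r.onset_s),
                        iti_before=float(r.iti_before_s),
                        duration=float(r.duration_s),
                    )
                    for r in sub.sort_values("onset_s").itertuples()
                ]
            )
        return cls(runs=runs, run_duration=run_duration)


@dataclass(frozen=True)
class StimulusRating:
    """Normative valence/arousal rating of one image, each on a 1-9 scale."""

    id: str
    valence: float
    arousal: float

    def __post_init__(self) -> None:
        for name in ("valence", "arousal"):
            v = getattr(self, name)
            if not (1.0 <= v <= 9.0):
                raise ValueError(f"{name} {v} outside [1, 9]")


@dataclass
class StimulusSelection:
    aversive_ids: list[str]
    neutral_ids: list[str]
    distances: dict[str, float]


@dataclass
class DesignConfig:
    """Parameters of a session design.

    Defaults reproduce the published task: 204 trials over four 330-s runs
    (84 neutral Go, 80 aversive Go, 20 neutral NoGo, 20 aversive NoGo), the
    first trial of every run a neutral Go, ITIs 30% 2 s / 40% 4 s / 30% 6 s.
    """

    counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    n_runs: int = 4
    run_duration: float = 330.0
    iti_proportions: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_ITI_PROPORTIONS)
    )
    first_trial_type: str = "neutral-go"
    n_attempts: int = 200
    min_lead_s: float = 12.0  # ≥ 6 discarded volumes


# ---------------------------------------------------------------------------
# ITI allocation
# ---------------------------------------------------------------------------

def _largest_remainder(n: int, proportions: Mapping[int, float]) -> dict[int, int]:
    """Integer allocation of n items to categories by largest remainder."""
    keys = sorted(proportions)
    quotas = np.array([n * proportions[k] for k in keys])
    base = np.floor(quotas).astype(int)
    short = n - base.sum()
    # ties broken toward smaller key for determinism
    order = np.argsort(-(quotas - base), kind="stable")
    for i in order[:short]:
        base[i] += 1
    return {k: int(b) for k, b in zip(keys, base)}


def _validate_proportions(proportions: Mapping[int, float]) -> None:
    vals = list(proportions.values())
    if any(v < 0 for v in vals):
        raise ValueError("ITI proportions must be non-negative")
    if abs(sum(vals) - 1.0) > 1e-9:
        raise ValueError(f"ITI proportions must sum to 1, got {sum(vals)}")


def generate_iti_sequence(
    n: int,
    proportions: Mapping[int, float] | None = None,
    seed: int | None = None,
) -> list[int]:
    """Pseudo-randomized inter-trial intervals.

    Counts per duration are fixed by largest-remainder allocation of
    ``n * proportion``; only the order is randomized.  With the default
    30/40/30 split over {2, 4, 6} s the mean is exactly 4 s whenever the
    quotas are integral.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    proportions = dict(DEFAULT_ITI_PROPORTIONS) if proportions is None else proportions
    _validate_proportions(proportions)
    counts = _largest_remainder(n, proportions)
    seq = [d for d in sorted(counts) for _ in range(counts[d])]
    rng = np.random.default_rng(seed)
    rng.shuffle(seq)
    return [int(d) for d in seq]


# ---------------------------------------------------------------------------
# Session design construction
# ---------------------------------------------------------------------------

def _transition_cost(seq: Sequence[str], counts: Mapping[str, int]) -> float:
    """Deviation of first-order transition counts from the uniform target."""
    trans: dict[tuple[str, str], int] = {}
    for a, b in zip(seq[:-1], seq[1:]):
        trans[(a, b)] = trans.get((a, b), 0) + 1
    n_pairs = len(seq) - 1
    target = n_pairs / (len(TRIAL_TYPES) ** 2)
    cost = 0.0
    for a in TRIAL_TYPES:
        for b in TRIAL_TYPES:
            cost += (trans.get((a, b), 0) - target) ** 2
    return cost


def _greedy_type_order(
    per_run_counts: list[dict[str, int]],
    first_type: str,
    rng: np.random.Generator,
) -> list[list[str]]:
    """Randomized greedy ordering balancing first-order transitions.

    Transition counts are tracked across the whole session (runs
    concatenated logically but transitions not counted across run breaks).
    At each step the next type is drawn among remaining types minimizing
    the current count of (prev -> candidate) transitions, ties random.
    """
    # desired pair count is proportional to availability; greedy on raw counts
    trans: dict[tuple[str, str], int] = {}
    orders: list[list[str]] = []
    for counts in per_run_counts:
        remaining = dict(counts)
        seq = [first_type]
        remaining[first_type] -= 1
        while any(v > 0 for v in remaining.values()):
            prev = seq[-1]
            cands = [t for t, v in remaining.items() if v > 0]
            # prefer under-used transitions, weighted by remaining supply
            costs = np.array(
                [trans.get((prev, t), 0) / max(counts[t], 1) for t in cands]
            )
            best = np.flatnonzero(costs == costs.min())
            t = cands[int(rng.choice(best))]
            trans[(prev, t)] = trans.get((prev, t), 0) + 1
            remaining[t] -= 1
            seq.append(t)
        orders.append(seq)
    return orders


def _assign_itis(
    orders: list[list[str]],
    counts: Mapping[str, int],
    proportions: Mapping[int, float],
    rng: np.random.Generator,
) -> list[list[int]]:
    """Assign ITI durations so each type's precedence matches proportions ±1."""
    pools: dict[str, list[int]] = {}
    for t in TRIAL_TYPES:
        n_t = counts.get(t, 0)
        if n_t == 0:
            pools[t] = []
            continue
        alloc = _largest_remainder(n_t, proportions)
        pool = [d for d in sorted(alloc) for _ in range(alloc[d])]
        rng.shuffle(pool)
        pools[t] = pool
    out = []
    for seq in orders:
        out.append([pools[t].pop() for t in seq])
    return out


def generate_session_design(
    config: DesignConfig | None = None,
    seed: int | None = None,
) -> SessionDesign:
    """Generate a counterbalanced session design.

    Guarantees: exact session trial counts; first trial of each run is the
    configured lead type; per-type preceding-ITI counts within ±1 of the
    proportional target; transition balance from the best of
    ``config.n_attempts`` randomized greedy constructions; runs padded with
    leading/trailing fixation to exactly ``run_duration``.
    """
    config = config or DesignConfig()
    _validate_proportions(config.iti_proportions)
    counts = dict(config.counts)
    n_total = sum(counts.values())
    if counts.get(config.first_trial_type, 0) < config.n_runs:
        raise ValueError(
            f"need at least {config.n_runs} {config.first_trial_type} trials "
            "(one lead trial per run)"
        )
    if n_total % config.n_runs != 0:
        raise ValueError("total trial count must divide evenly across runs")
    per_run = n_total // config.n_runs

    # worst-case time check: trials + mean ITI + minimum lead fixation
    mean_iti = sum(d * p for d, p in config.iti_proportions.items())
    t_needed = per_run * TRIAL_DURATION_S + per_run * mean_iti + config.min_lead_s
    if t_needed > config.run_duration:
        raise ValueError(
            f"infeasible config: ~{t_needed:.0f} s of trials+ITIs+lead exceeds "
            f"run_duration {config.run_duration} s"
        )

    # split counts across runs: lead trial per run, remainder as even as possible
    core = dict(counts)
    core[config.first_trial_type] -= config.n_runs
    per_run_counts = []
    rem = dict(core)
    for r in range(config.n_runs):
        runs_left = config.n_runs - r
        rc = {t: 0 for t in TRIAL_TYPES}
        rc[config.first_trial_type] += 1
        for t in TRIAL_TYPES:
            take = int(round(rem.get(t, 0) / runs_left))
            take = min(take, rem.get(t, 0))
            rc[t] += take
            rem[t] = rem.get(t, 0) - take
        per_run_counts.append(rc)
    for t in TRIAL_TYPES:  # distribute any leftovers
        while rem.get(t, 0) > 0:
            per_run_counts[rem[t] % config.n_runs][t] += 1
            rem[t] -= 1

    rng = np.random.default_rng(seed)
    best_orders, best_cost = None, np.inf
    for _ in range(max(1, config.n_attempts)):
        orders = _greedy_type_order(per_run_counts, config.first_trial_type, rng)
        cost = sum(_transition_cost(o, counts) for o in orders)
        if cost < best_cost:
            best_orders, best_cost = orders, cost
    assert best_orders is not None

    # ITI assignment with per-run duration feasibility retry
    max_iti_budget = config.run_duration - config.min_lead_s - per_run * TRIAL_DURATION_S
    for attempt in range(500):
        itis = _assign_itis(best_orders, counts, config.iti_proportions, rng)
        if all(sum(run) <= max_iti_budget for run in itis):
            break
    else:
        raise ValueError("could not place ITIs within run duration; reduce counts")

    runs: list[list[Trial]] = []
    for order, run_itis in zip(best_orders, itis):
        used = per_run * TRIAL_DURATION_S + sum(run_itis)
        slack = config.run_duration - used  # absorbed by lead/trail fixation
        lead = config.min_lead_s + 2.0 * np.floor((slack - config.min_lead_s) / 4.0)
        lead = max(config.min_lead_s, lead)
        t = lead - run_itis[0]  # first trial's nominal ITI sits inside the lead
        trials = []
        for typ, iti in zip(order, run_itis):
            t_onset = t + iti
            trials.append(Trial(type=typ, onset=float(t_onset), iti_before=float(iti)))
            t = t_onset + TRIAL_DURATION_S
        if t > config.run_duration:
            raise ValueError("internal error: trials overflow run duration")
        runs.append(trials)

    design = SessionDesign(
        runs=runs,
        run_duration=config.run_duration,
        seed=seed,
        metadata={
            "transition_cost": float(best_cost),
            "n_attempts": config.n_attempts,
            "iti_proportions": dict(config.iti_proportions),
        },
    )
    check_session_design(design, config)
    return design


def check_session_design(design: SessionDesign, config: DesignConfig | None = None) -> dict:
    """Validate a design against its construction constraints.

    Raises ``ValueError`` on violation; returns a diagnostics dict.
    """
    config = config or DesignConfig()
    counts = design.counts
    for t, n in config.counts.items():
        if counts.get(t, 0) != n:
            raise ValueError(f"count mismatch for {t}: {counts.get(t, 0)} != {n}")
    for i, run in enumerate(design.runs):
        if not run:
            raise ValueError(f"run {i} empty")
        if run[0].type != config.first_trial_type:
            raise ValueError(f"run {i} first trial is {run[0].type}")
        last = run[-1]
        if last.onset + last.duration > design.run_duration:
            raise ValueError(f"run {i} overruns {design.run_duration} s")
        for a, b in zip(run[:-1], run[1:]):
            if abs((b.onset - (a.onset + a.duration)) - b.iti_before) > 1e-9:
                raise ValueError("onset/ITI bookkeeping inconsistent")
    # ITI precedence: each type's preceding-ITI counts within ±1 of n_type * p_d
    prec: dict[str, dict[int, int]] = {t: {} for t in TRIAL_TYPES}
    for _, tr in design.all_trials():
        d = int(tr.iti_before)
        prec[tr.type][d] = prec[tr.type].get(d, 0) + 1
    for t in TRIAL_TYPES:
        n_t = counts.get(t, 0)
        if n_t == 0:
            continue
        for d, p in config.iti_proportions.items():
            got = prec[t].get(d, 0)
            if abs(got - n_t * p) >= 1.0 + 1e-9:
                raise ValueError(
                    f"ITI precedence imbalance: {t} preceded by {d}s x{got}, "
                    f"target {n_t * p:.1f}"
                )
    return {"counts": counts, "iti_precedence": prec, **design.metadata}


# ---------------------------------------------------------------------------
# Design-matrix diagnostics
# ---------------------------------------------------------------------------

def check_design_independence(matrix: np.ndarray) -> dict:
    """Numerical rank and condition number of a design matrix."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size == 0:
        raise ValueError("empty design matrix")
    s = np.linalg.svd(matrix, compute_uv=False)
    tol = s.max() * max(matrix.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    cond = float(s.max() / s.min()) if s.min() > 0 else float("inf")
    return {
        "rank": rank,
        "n_columns": matrix.shape[1],
        "full_rank": rank == min(matrix.shape),
        "condition_number": cond,
    }


# ---------------------------------------------------------------------------
# Stimulus selection
# ---------------------------------------------------------------------------

AVERSIVE_TARGET = (9.0, 1.0)  # (arousal, valence): maximally arousing, most negative
NEUTRAL_TARGET = (1.0, 5.0)  # minimally arousing, mid valence
AVERSIVE_VALENCE_MAX = 3.6
NEUTRAL_VALENCE_RANGE = (3.6, 6.4)  # exclusive bounds


def select_stimuli(
    ratings: Iterable[StimulusRating] | pd.DataFrame,
    n_aversive: int = 100,
    n_neutral: int = 104,
) -> StimulusSelection:
    """Select aversive and neutral distractor images from a ratings table.

    Aversive: valence ≤ 3.6, closest to [arousal, valence] = [9, 1].
    Neutral: 3.6 < valence < 6.4, closest to [1, 5].  Distances are
    Euclidean in (arousal, valence) space; ties break by id order.
    """
    if isinstance(ratings, pd.DataFrame):
        items = [
            StimulusRating(id=str(r.id), valence=float(r.valence), arousal=float(r.arousal))
            for r in ratings.itertuples()
        ]
    else:
        items = list(ratings)

    def dist(r: StimulusRating, target: tuple[float, float]) -> float:
        return float(np.hypot(r.arousal - target[0], r.valence - target[1]))

    aversive = sorted(
        (r for r in items if r.valence <= AVERSIVE_VALENCE_MAX),
        key=lambda r: (dist(r, AVERSIVE_TARGET), r.id),
    )
    lo, hi = NEUTRAL_VALENCE_RANGE
    neutral = sorted(
        (r for r in items if lo < r.valence < hi),
        key=lambda r: (dist(r, NEUTRAL_TARGET), r.id),
    )
    if len(aversive) < n_aversive:
        raise ValueError(
            f"insufficient aversive candidates: {len(aversive)} < {n_aversive}"
        )
    if len(neutral) < n_neutral:
        raise ValueError(
            f"insufficient neutral candidates: {len(neutral)} < {n_neutral}"
        )
    sel_a = aversive[:n_aversive]
    sel_n = neutral[:n_neutral]
    distances = {r.id: dist(r, AVERSIVE_TARGET) for r in sel_a}
    distances.update({r.id: dist(r, NEUTRAL_TARGET) for r in sel_n})
    return StimulusSelection(
        aversive_ids=[r.id for r in sel_a],
        neutral_ids=[r.id for r in sel_n],
        distances=distances,
    )
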