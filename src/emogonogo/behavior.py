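"""Questionnaire scoring and behavioral resampling statistics.

Scores the 30-item Barratt Impulsiveness Scale (BIS-11) from raw item
responses using a configurable key (reversal set + six-subscale partition),
classifies risk from ARBS totals (high >= 17, low <= 13), and implements
the behavioral tests used with skewed Go/NoGo error rates: percentile
bootstrap of a mean against zero, sign-flip permutation for paired rates,
residual-resampling bootstrap regression of rates on scores, and a paired
t-test for Go latencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml
from scipy import stats

__all__ = [
    "BisKey",
    "load_bis_key",
    "score_bis",
    "classify_risk",
    "bootstrap_mean_test",
    "permutation_paired_test",
    "bootstrap_regression",
    "paired_latency_test",
]

N_BIS_ITEMS = 30
ITEM_RANGE = (1, 4)


@dataclass(frozen=True)
class BisKey:
    reversed_items: frozenset[int]
    subscales: dict[str, tuple[int, ...]]

    def __post_init__(self) -> None:
        all_items = sorted(i for items in self.subscales.values() for i in items)
        if all_items != list(range(1, N_BIS_ITEMS + 1)):
            raise ValueError("subscales must partition items 1..30")
        if not self.reversed_items <= set(range(1, N_BIS_ITEMS + 1)):
            raise ValueError("reversed items outside 1..30")


def load_bis_key(path: str | None = None) -> BisKey:
    """Load a BIS scoring key from YAML (default: the packaged BIS-11 key)."""
    if path is None:
        src = resources.files("emogonogo.data").joinpath("bis11_key.yaml")
        raw = yaml.safe_load(src.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return BisKey(
        reversed_items=frozenset(int(i) for i in raw["reversed_items"]),
        subscales={k: tuple(int(i) for i in v) for k, v in raw["subscales"].items()},
    )


def score_bis(
    responses: dict[int, int] | list[int] | np.ndarray,
    key: BisKey | None = None,
) -> dict:
    """Score a 30-item BIS response vector.

    ``responses`` maps item number (1-based) to raw response in 1-4, or is a
    length-30 sequence in item order.  Reversed items score 5 - response.
    Returns total and the six subscale sums; the subscales always sum to
    the total.
    """
    key = key or load_bis_key()
    if not isinstance(responses, dict):
        seq = list(responses)
        if len(seq) != N_BIS_ITEMS:
            raise ValueError(f"expected {N_BIS_ITEMS} responses, got {len(seq)}")
        responses = {i + 1: seq[i] for i in range(N_BIS_ITEMS)}
    scored = {}
    for item in range(1, N_BIS_ITEMS + 1):
        if item not in responses:
            raise ValueError(f"missing item {item}")
        r = int(responses[item])
        if not (ITEM_RANGE[0] <= r <= ITEM_RANGE[1]):
            raise ValueError(f"item {item} response {r} outside {ITEM_RANGE}")
        scored[item] = 5 - r if item in key.reversed_items else r
    subscales = {
        name: int(sum(scored[i] for i in items))
        for name, items in key.subscales.items()
    }
    total = int(sum(subscales.values()))
    return {"total": total, "subscales": subscales}


def score_arbs(
    total: int | None = None,
    items: dict[int, int] | None = None,
    key: dict[int, dict[int, int]] | None = None,
) -> int:
    """ARBS total: accepted directly, or summed from an item table with a
    caller-supplied key mapping item -> {response: points} (the instrument's
    item content is not reproduced here)."""
    if total is not None:
        if not (9 <= int(total) <= 30):
            raise ValueError(f"ARBS total {total} outside [9, 30]")
        return int(total)
    if items is None or key is None:
        raise ValueError("provide either a total or an item table plus key")
    score = sum(key[i][r] for i, r in items.items())
    if not (9 <= score <= 30):
        raise ValueError(f"scored ARBS total {score} outside [9, 30]")
    return score


def classify_risk(arbs: int) -> str:
    """Risk class from an ARBS total: high >= 17, low <= 13, else mid."""
    if not (9 <= arbs <= 30):
        raise ValueError(f"ARBS score {arbs} outside [9, 30]")
    if arbs >= 17:
        return "high"
    if arbs <= 13:
        return "low"
    return "mid"


# ---------------------------------------------------------------------------
# Resampling tests
# ---------------------------------------------------------------------------

def bootstrap_mean_test(
    rates: np.ndarray,
    n_iter: int = 10_000,
    seed: int | None = None,
    two_sided: bool = False,
) -> dict:
    """Percentile bootstrap of the mean against zero.

    One-sided by default (rates cannot be negative): p is the fraction of
    resampled means <= 0, reported at resolution 1/n_iter (never exactly 0).
    All-zero data is degenerate and reported as p = 1.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.size < 2:
        raise ValueError("need at least 2 observations")
    if n_iter < 1000:
        raise ValueError("n_iter must be >= 1000")
    if np.all(rates == 0):
        return {"mean": 0.0, "p": 1.0, "n_iter": n_iter}
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, rates.size, size=(n_iter, rates.size))
    means = rates[idx].mean(axis=1)
    p = max(float(np.mean(means <= 0)), 1.0 / n_iter)
    if two_sided:
        p = min(1.0, 2 * min(p, max(float(np.mean(means >= 0)), 1.0 / n_iter)))
    return {"mean": float(rates.mean()), "p": p, "n_iter": n_iter}


def permutation_paired_test(
    a: np.ndarray,
    b: np.ndarray,
    n_iter: int = 10_000,
    seed: int | None = None,
) -> dict:
    """Sign-flip permutation test for paired samples (two-sided).

    The null distribution of |mean difference| is built by randomly flipping
    the sign of each pair's difference; p includes the observed statistic
    (never 0, 1 when a == b).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or a.shape != b.shape:
        raise ValueError("a and b must be equal-length, non-empty")
    if n_iter < 1000:
        raise ValueError("n_iter must be >= 1000")
    d = a - b
    obs = abs(d.mean())
    rng = np.random.default_rng(seed)
    flips = rng.choice([-1.0, 1.0], size=(n_iter, d.size))
    null = np.abs((flips * d).mean(axis=1))
    p = float((np.sum(null >= obs - 1e-15) + 1) / (n_iter + 1))
    return {"mean_difference": float(d.mean()), "p": min(p, 1.0), "n_iter": n_iter}


def bootstrap_regression(
    y: np.ndarray,
    x: np.ndarray,
    n_iter: int = 10_000,
    seed: int | None = None,
) -> dict:
    """Bootstrap regression by residual resampling (two-sided slope test).

    Fits least squares, resamples residuals with replacement onto fitted
    values, refits, and reports the two-sided fraction of resampled slopes
    on the far side of zero relative to the observed slope.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.size < 3 or y.shape != x.shape:
        raise ValueError("need >= 3 paired observations")
    if np.std(x) == 0:
        raise ValueError("constant predictor")
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, resid.size, size=(n_iter, resid.size))
    Yb = fitted[None, :] + resid[idx]
    # closed-form slope for each bootstrap sample
    xc = x - x.mean()
    slopes = (Yb - Yb.mean(axis=1, keepdims=True)) @ xc / (xc @ xc)
    slope = float(beta[1])
    if slope >= 0:
        p_one = float(np.mean(slopes <= 0))
    else:
        p_one = float(np.mean(slopes >= 0))
    p = min(1.0, max(2 * p_one, 1.0 / n_iter))
    return {"slope": slope, "p": p, "n_iter": n_iter}


def paired_latency_test(neutral: np.ndarray, aversive: np.ndarray) -> dict:
    """Paired t-test of Go latencies (neutral vs aversive distractors)."""
    res = stats.ttest_rel(aversive, neutral)
    return {
        "mean_difference": float(np.mean(np.asarray(aversive) - np.asarray(neutral))),
        "t": float(res.statistic),
        "p": float(res.pvalue),
        "df": int(len(np.asarray(neutral)) - 1),
    }
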