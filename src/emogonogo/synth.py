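"""Synthetic cohorts, atlases, and 4D BOLD sessions with known ground truth.

Emulates the statistical structure the analysis pipeline assumes: a small
adolescent cohort with bimodal risk scores (ARBS) highly correlated with
impulsivity scores (BIS), and event-related BOLD data built from
double-gamma hemodynamic responses, per-region effect amplitudes optionally
modulated by the scores, AR-correlated spatially smooth noise, and
drift/motion-like nuisance signals.  Every generator is seeded and stores
its ground truth alongside the data so downstream estimators can be tested
for parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import gamma as gamma_dist

from .design import TRIAL_TYPES, DesignConfig, SessionDesign, generate_session_design

__all__ = [
    "Participant",
    "EffectSpec",
    "NoiseSpec",
    "SyntheticSession",
    "generate_cohort",
    "hrf",
    "generate_bold_session",
    "generate_atlas_fixture",
    "make_ellipsoid_mask",
]

ARBS_RANGE = (9, 30)
BIS_RANGE = (30, 120)
HIGH_RISK_CUTOFF = 17
LOW_RISK_CUTOFF = 13

# BIS-11 first-order subscales: (name, item count); totals must sum over the
# 30 items.  Cohort means follow the published sample profile.
BIS_SUBSCALES = (
    ("attentional", 5),
    ("cognitive_instability", 3),
    ("motor", 7),
    ("perseverance", 4),
    ("self_control", 6),
    ("cognitive_complexity", 5),
)
_SUBSCALE_MEAN_PROFILE = np.array([11.8, 7.0, 15.2, 7.8, 13.8, 12.0])

# Study-reported cohort moments used as generator defaults.
DEFAULT_SCORE_MOMENTS = {
    "arbs_mean": 15.6,
    "arbs_sd": 4.6,
    "bis_mean": 67.6,
    "bis_sd": 16.1,
}


@dataclass(frozen=True)
class Participant:
    id: str
    arbs: int
    bis: int
    bis_subscales: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (ARBS_RANGE[0] <= self.arbs <= ARBS_RANGE[1]):
            raise ValueError(f"ARBS {self.arbs} outside {ARBS_RANGE}")
        if not (BIS_RANGE[0] <= self.bis <= BIS_RANGE[1]):
            raise ValueError(f"BIS {self.bis} outside {BIS_RANGE}")
        if self.bis_subscales and sum(self.bis_subscales.values()) != self.bis:
            raise ValueError("subscales do not sum to BIS total")

    @property
    def risk_class(self) -> str:
        if self.arbs >= HIGH_RISK_CUTOFF:
            return "high"
        if self.arbs <= LOW_RISK_CUTOFF:
            return "low"
        return "mid"


@dataclass
class EffectSpec:
    """Ground-truth per-region response amplitudes and score modulations.

    ``amplitudes[region][trial_type]`` is the BOLD response amplitude (peak
    units) in that atlas region.  ``arbs_slopes`` / ``bis_slopes`` add
    ``slope * (score - cohort mean)`` to the amplitude for listed
    (region, trial type) pairs.
    """

    amplitudes: dict[int, dict[str, float]] = field(default_factory=dict)
    arbs_slopes: dict[int, dict[str, float]] = field(default_factory=dict)
    bis_slopes: dict[int, dict[str, float]] = field(default_factory=dict)
    arbs_center: float = DEFAULT_SCORE_MOMENTS["arbs_mean"]
    bis_center: float = DEFAULT_SCORE_MOMENTS["bis_mean"]

    def amplitude(self, region: int, trial_type: str, participant: Participant) -> float:
        a = self.amplitudes.get(region, {}).get(trial_type, 0.0)
        a += self.arbs_slopes.get(region, {}).get(trial_type, 0.0) * (
            participant.arbs - self.arbs_center
        )
        a += self.bis_slopes.get(region, {}).get(trial_type, 0.0) * (
            participant.bis - self.bis_center
        )
        return a


@dataclass
class NoiseSpec:
    """Noise model: AR temporal structure, spatial smoothness, nuisance."""

    ar_coefficients: tuple[float, ...] = (0.3,)
    innovation_sd: float = 1.0
    spatial_fwhm_mm: float = 6.0
    drift_amplitude: float = 0.5
    motion_amplitude: float = 0.3

    def __post_init__(self) -> None:
        if self.spatial_fwhm_mm < 0:
            raise ValueError("FWHM must be >= 0")
        a = np.asarray(self.ar_coefficients, dtype=float)
        if a.size and np.any(np.abs(np.roots(np.r_[1.0, -a])) >= 1.0):
            raise ValueError("AR polynomial is not stationary")


@dataclass
class SyntheticSession:
    """4D BOLD grid for one participant plus the truth that generated it."""

    data: np.ndarray  # (x, y, z, t) including lead-in volumes
    mask: np.ndarray  # (x, y, z) bool
    atlas: np.ndarray  # (x, y, z) int labels, 0 = background
    design: SessionDesign
    participant: Participant
    effects: EffectSpec
    noise: NoiseSpec
    tr: float = 2.0
    n_discard: int = 6  # lead-in volumes per run, flagged for discard
    voxel_size_mm: float = 3.0
    seed: int | None = None

    @property
    def volumes_per_run(self) -> int:
        return int(round(self.design.run_duration / self.tr))

    @property
    def n_runs(self) -> int:
        return len(self.design.runs)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _bis_subscale_split(total: int, rng: np.random.Generator) -> dict[str, int]:
    """Partition a BIS total into six subscale sums within item-count bounds."""
    names = [n for n, _ in BIS_SUBSCALES]
    n_items = np.array([k for _, k in BIS_SUBSCALES])
    lo, hi = n_items, 4 * n_items
    excess = total - int(lo.sum())
    # allocate excess proportional to the sample profile, with jitter
    weights = _SUBSCALE_MEAN_PROFILE - lo
    weights = np.maximum(weights + rng.normal(0, 0.5, size=6), 0.01)
    quota = excess * weights / weights.sum()
    alloc = np.floor(quota).astype(int)
    rest = excess - alloc.sum()
    order = np.argsort(-(quota - alloc), kind="stable")
    for i in order[:rest]:
        alloc[i] += 1
    # clip to bounds and rebalance
    alloc = np.minimum(alloc, hi - lo)
    short = excess - alloc.sum()
    while short > 0:
        room = np.flatnonzero(alloc < hi - lo)
        alloc[room[0]] += 1
        short -= 1
    return {n: int(l + a) for n, l, a in zip(names, lo, alloc)}


def generate_cohort(
    n: int = 21,
    n_high: int = 10,
    target_corr: float = 0.78,
    score_moments: Mapping[str, float] | None = None,
    seed: int | None = None,
    corr_tolerance: float = 0.15,
    max_tries: int = 200,
) -> list[Participant]:
    """Generate a cohort with bimodal risk scores correlated with impulsivity.

    Scores are drawn from a bivariate Gaussian with the requested moments and
    correlation, rounded to integers, and clipped to valid ranges.  Exactly
    ``n_high`` participants get ARBS >= 17 and the remainder ARBS <= 13
    (mid-range 14-16 excluded, mirroring the natural break in the study
    sample).  The empirical ARBS-BIS correlation is required to fall within
    ``corr_tolerance`` of ``target_corr``; generation retries with fresh
    draws until it does.
    """
    if n_high > n:
        raise ValueError("n_high must be <= n")
    if not (-1.0 <= target_corr <= 1.0):
        raise ValueError("target_corr must be in [-1, 1]")
    m = dict(DEFAULT_SCORE_MOMENTS)
    if score_moments:
        m.update(score_moments)
    rng = np.random.default_rng(seed)
    cov = np.array(
        [
            [m["arbs_sd"] ** 2, target_corr * m["arbs_sd"] * m["bis_sd"]],
            [target_corr * m["arbs_sd"] * m["bis_sd"], m["bis_sd"] ** 2],
        ]
    )
    best = None
    for _ in range(max_tries):
        z = rng.multivariate_normal([m["arbs_mean"], m["bis_mean"]], cov, size=n)
        arbs = np.round(z[:, 0]).astype(int)
        bis = np.clip(np.round(z[:, 1]).astype(int), *BIS_RANGE)
        # enforce the bimodal break: top-n_high by latent ARBS go high-risk
        order = np.argsort(-z[:, 0], kind="stable")
        for rank, i in enumerate(order):
            if rank < n_high:
                arbs[i] = int(np.clip(max(arbs[i], HIGH_RISK_CUTOFF), HIGH_RISK_CUTOFF, ARBS_RANGE[1]))
            else:
                arbs[i] = int(np.clip(min(arbs[i], LOW_RISK_CUTOFF), ARBS_RANGE[0], LOW_RISK_CUTOFF))
        if n >= 3 and np.std(arbs) > 0 and np.std(bis) > 0:
            r = float(np.corrcoef(arbs, bis)[0, 1])
        else:
            r = target_corr
        err = abs(r - target_corr)
        if best is None or err < best[0]:
            best = (err, arbs.copy(), bis.copy(), r)
        if err <= corr_tolerance:
            break
    else:
        raise ValueError(
            f"could not reach correlation {target_corr} +/- {corr_tolerance}; "
            f"best achieved {best[3]:.3f}"
        )
    err, arbs, bis, r = best
    cohort = [
        Participant(
            id=f"sub-{i + 1:02d}",
            arbs=int(a),
            bis=int(b),
            bis_subscales=_bis_subscale_split(int(b), rng),
        )
        for i, (a, b) in enumerate(zip(arbs, bis))
    ]
    return cohort


def cohort_to_table(cohort: list[Participant]) -> pd.DataFrame:
    rows = []
    for p in cohort:
        row = {"participant_id": p.id, "arbs": p.arbs, "bis": p.bis, "risk_class": p.risk_class}
        row.update({f"bis_{k}": v for k, v in p.bis_subscales.items()})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hemodynamic response
# ---------------------------------------------------------------------------

def hrf(
    t: float | np.ndarray,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_disp: float = 1.0,
    undershoot_disp: float = 1.0,
    ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, scaled to unit peak.

    Difference of two gamma densities (shape = delay/dispersion, scale =
    dispersion): a positive lobe peaking near 5 s and a late undershoot
    near 16 s at 1/6 the peak amplitude.
    """
    for name, v in [
        ("peak_delay", peak_delay),
        ("undershoot_delay", undershoot_delay),
        ("peak_disp", peak_disp),
        ("undershoot_disp", undershoot_disp),
    ]:
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    t = np.asarray(t, dtype=float)
    pos = gamma_dist.pdf(t, peak_delay / peak_disp, scale=peak_disp)
    neg = gamma_dist.pdf(t, undershoot_delay / undershoot_disp, scale=undershoot_disp)
    h = pos - ratio * neg
    grid = np.linspace(0, 50, 2001)
    peak = np.max(
        gamma_dist.pdf(grid, peak_delay / peak_disp, scale=peak_disp)
        - ratio * gamma_dist.pdf(grid, undershoot_delay / undershoot_disp, scale=undershoot_disp)
    )
    out = h / peak
    out = np.where(t >= 0, out, 0.0)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Atlas and mask fixtures
# ---------------------------------------------------------------------------

def make_ellipsoid_mask(
    shape: tuple[int, int, int],
    n_voxels: int | None = None,
    axis_ratios: tuple[float, float, float] = (1.0, 1.2, 0.85),
) -> np.ndarray:
    """Brain-like ellipsoidal mask on a voxel grid.

    If ``n_voxels`` is given, the mask is the exact set of that many voxels
    with smallest normalized ellipsoidal distance from the grid centre
    (distance ties broken by linear index), so target voxel counts are hit
    exactly.
    """
    shape = tuple(int(s) for s in shape)
    center = (np.array(shape) - 1) / 2.0
    semi = np.array(axis_ratios) * (np.array(shape) / 2.0) / max(axis_ratios)
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    d2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    if n_voxels is None:
        return d2 <= 1.0
    if n_voxels > np.prod(shape):
        raise ValueError("n_voxels exceeds grid size")
    flat = d2.ravel()
    idx = np.argsort(flat, kind="stable")[:n_voxels]
    mask = np.zeros(flat.shape, dtype=bool)
    mask[idx] = True
    return mask.reshape(shape)


def generate_atlas_fixture(
    grid: tuple[int, int, int] = (20, 20, 12),
    n_regions: int = 26,
    seed: int | None = None,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Partition a mask into contiguous labeled regions (Voronoi cells).

    Returns an integer label volume (0 outside the mask, labels 1..n) and a
    region table (label, name, voxel count, centroid).  Stands in for a
    cortical parcellation; regions are contiguous and non-overlapping.
    """
    if mask is None:
        mask = make_ellipsoid_mask(grid)
    rng = np.random.default_rng(seed)
    coords = np.argwhere(mask)
    if n_regions > len(coords):
        raise ValueError(f"cannot place {n_regions} regions in {len(coords)} voxels")
    seeds = coords[rng.choice(len(coords), size=n_regions, replace=False)]
    # nearest-seed assignment; convex mask => connected cells
    d = ((coords[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    label_of = d.argmin(axis=1) + 1
    atlas = np.zeros(mask.shape, dtype=np.int32)
    atlas[tuple(coords.T)] = label_of
    rows = []
    for lbl in range(1, n_regions + 1):
        vox = coords[label_of == lbl]
        if len(vox) == 0:
            raise ValueError("empty region produced; try another seed")
        rows.append(
            {
                "label": lbl,
                "name": f"region_{lbl:02d}",
                "n_voxels": len(vox),
                "cx": float(vox[:, 0].mean()),
                "cy": float(vox[:, 1].mean()),
                "cz": float(vox[:, 2].mean()),
            }
        )
    return atlas, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# BOLD session synthesis
# ---------------------------------------------------------------------------

def _ar_noise(
    shape_spatial: tuple[int, ...],
    n_t: int,
    spec: NoiseSpec,
    voxel_size_mm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Spatially smooth AR noise, variance-normalized to innovation_sd scale."""
    a = np.asarray(spec.ar_coefficients, dtype=float)
    p = len(a)
    burn = 5 * p if p else 0
    eps = rng.standard_normal(shape_spatial + (n_t + burn,))
    if spec.spatial_fwhm_mm > 0:
        sigma_vox = spec.spatial_fwhm_mm / (np.sqrt(8 * np.log(2)) * voxel_size_mm)
        for ti in range(eps.shape[-1]):
            eps[..., ti] = ndimage.gaussian_filter(eps[..., ti], sigma_vox)
        sd = eps.std()
        if sd > 0:
            eps /= sd
    if p == 0:
        return spec.innovation_sd * eps[..., burn:]
    x = np.zeros_like(eps)
    for ti in range(eps.shape[-1]):
        acc = eps[..., ti].copy()
        for k in range(1, min(p, ti) + 1):
            acc += a[k - 1] * x[..., ti - k]
        x[..., ti] = acc
    return spec.innovation_sd * x[..., burn:]


def expected_fir_betas(
    design: SessionDesign,
    amplitudes: Mapping[str, float] | None = None,
    tr: float = 2.0,
    n_fir: int = 7,
    n_discard: int = 6,
    hrf_kwargs: dict | None = None,
    hrf_duration: float = 32.0,
) -> np.ndarray:
    """Forward-model oracle: dense least-squares projection of the noiseless
    hemodynamic response onto the FIR basis plus per-run intercepts.

    ``amplitudes`` maps trial type to programmed response amplitude (default
    1 for every type).  Returns an (n_types, n_fir) beta array on the
    post-discard time grid.  Independent of the GLM fitting path (direct
    ``lstsq`` on the forward model).
    """
    hrf_kwargs = hrf_kwargs or {}
    amps = {t: 1.0 for t in TRIAL_TYPES}
    if amplitudes:
        amps.update(amplitudes)
    n_per_run = int(round(design.run_duration / tr))
    h = hrf(np.arange(0.0, hrf_duration, tr), **hrf_kwargs)
    X_parts, y_parts = [], []
    n_runs = len(design.runs)
    n_task = len(TRIAL_TYPES) * n_fir
    tgrid = np.arange(n_discard, n_per_run) * tr
    period = 2.0 * design.run_duration
    for r, run in enumerate(design.runs):
        Xr = np.zeros((n_per_run, n_task + 4 * n_runs))
        Xr[n_discard:, n_task + 4 * r + 0] = 1.0
        Xr[n_discard:, n_task + 4 * r + 1] = np.linspace(-1, 1, n_per_run - n_discard)
        Xr[n_discard:, n_task + 4 * r + 2] = np.cos(2 * np.pi * tgrid / period)
        Xr[n_discard:, n_task + 4 * r + 3] = np.sin(2 * np.pi * tgrid / period)
        yr = np.zeros(n_per_run)
        for trial in run:
            vol = int(round(trial.onset / tr))
            ti = TRIAL_TYPES.index(trial.type)
            for k in range(n_fir):
                if vol + k < n_per_run:
                    Xr[vol + k, ti * n_fir + k] = 1.0
            hi = min(len(h), n_per_run - vol)
            yr[vol : vol + hi] += amps[trial.type] * h[:hi]
        X_parts.append(Xr[n_discard:])
        y_parts.append(yr[n_discard:])
    X = np.vstack(X_parts)
    y = np.concatenate(y_parts)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta[: len(TRIAL_TYPES) * n_fir].reshape(len(TRIAL_TYPES), n_fir)


def generate_bold_session(
    participant: Participant,
    design: SessionDesign | None = None,
    effects: EffectSpec | None = None,
    noise: NoiseSpec | None = None,
    grid: tuple[int, int, int] = (20, 20, 12),
    atlas: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    tr: float = 2.0,
    n_discard: int = 6,
    voxel_size_mm: float = 3.0,
    baseline: float = 100.0,
    hrf_kwargs: dict | None = None,
    hrf_duration: float = 32.0,
    seed: int | None = None,
) -> SyntheticSession:
    """Simulate a 4D BOLD session for one participant.

    Signal per voxel = baseline + sum over trials of
    amplitude(region, type, scores) * hrf(t - onset), plus linear drift, a
    slow sinusoid, motion-like low-frequency nuisance components, and
    spatially smooth AR noise.  The first ``n_discard`` volumes of each run
    carry no task signal (lead-in, flagged for discard downstream).
    """
    rng = np.random.default_rng(seed)
    if design is None:
        design = generate_session_design(DesignConfig(), seed=seed)
    if atlas is None:
        atlas, _ = generate_atlas_fixture(grid, n_regions=26, seed=seed, mask=mask)
    if mask is None:
        mask = atlas > 0
    if atlas.shape != tuple(grid) or mask.shape != tuple(grid):
        raise ValueError(f"atlas/mask shape {atlas.shape} != grid {tuple(grid)}")
    effects = effects or EffectSpec()
    noise = noise or NoiseSpec()
    hrf_kwargs = hrf_kwargs or {}

    n_per_run = int(round(design.run_duration / tr))
    n_runs = len(design.runs)
    n_t = n_per_run * n_runs
    data = np.full(tuple(grid) + (n_t,), float(baseline))

    lags = np.arange(0.0, hrf_duration, tr)
    h = hrf(lags, **hrf_kwargs)

    # per-run task regressor per trial type (unit amplitude)
    unit = np.zeros((len(TRIAL_TYPES), n_t))
    for r, run in enumerate(design.runs):
        off = r * n_per_run
        for trial in run:
            vol = int(round(trial.onset / tr))
            ti = TRIAL_TYPES.index(trial.type)
            hi = min(len(h), n_per_run - vol)
            unit[ti, off + vol : off + vol + hi] += h[:hi]

    regions = sorted(
        set(effects.amplitudes) | set(effects.arbs_slopes) | set(effects.bis_slopes)
    )
    for region in regions:
        vox = (atlas == region) & mask
        if not vox.any():
            continue
        amps = np.array(
            [effects.amplitude(region, t, participant) for t in TRIAL_TYPES]
        )
        ts = amps @ unit
        data[vox, :] += ts

    if noise.drift_amplitude or noise.motion_amplitude:
        tgrid = np.arange(n_per_run) * tr
        for r in range(n_runs):
            off = r * n_per_run
            drift = noise.drift_amplitude * np.linspace(-1, 1, n_per_run)
            sinus = noise.drift_amplitude * np.sin(
                2 * np.pi * tgrid / (2 * design.run_duration) + rng.uniform(0, 2 * np.pi)
            )
            nuis = drift + sinus
            # motion-like: smooth random walk shared across space with a
            # random spatial weighting map
            if noise.motion_amplitude:
                walk = np.cumsum(rng.standard_normal(n_per_run))
                walk = ndimage.gaussian_filter1d(walk, 5)
                walk = noise.motion_amplitude * walk / (walk.std() + 1e-12)
                wmap = ndimage.gaussian_filter(rng.standard_normal(grid), 2.0)
                data[..., off : off + n_per_run] += (
                    wmap[..., None] * walk[None, None, None, :]
                )
            data[..., off : off + n_per_run] += nuis

    if noise.innovation_sd > 0:
        for r in range(n_runs):
            off = r * n_per_run
            data[..., off : off + n_per_run] += _ar_noise(
                tuple(grid), n_per_run, noise, voxel_size_mm, rng
            )

    return SyntheticSession(
        data=data,
        mask=mask,
        atlas=atlas,
        design=design,
        participant=participant,
        effects=effects,
        noise=noise,
        tr=tr,
        n_discard=n_discard,
        voxel_size_mm=voxel_size_mm,
        seed=seed,
    )
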