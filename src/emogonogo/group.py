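"""Second-level (group) inference with cluster-extent calibration.

Produces the nine group maps (three first-level contrasts crossed with
three models: mean effect, regression on mean-centred ARBS, regression on
mean-centred BIS) by voxelwise mixed-effects regression; thresholds them
voxelwise at a two-tailed t level; and calibrates the cluster-extent
threshold that controls family-wise error either by label permutation
(re-running a simplified analysis with trial types shuffled within
participant) or by AlphaSim-style Monte Carlo simulation of spatially
smooth Gaussian noise at the estimated residual smoothness.  Surviving
clusters get a timecourse quality-assurance check against the canonical
double-gamma response shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import stats

from .design import TRIAL_TYPES, SessionDesign
from .glm import (
    BUILTIN_CONTRASTS,
    ContrastMap,
    DesignMatrix,
    build_design_matrix,
    compute_contrast,
    fit_first_level,
    prewhiten_and_fit,
)
from .synth import hrf

__all__ = [
    "GroupModel",
    "StatMapSet",
    "ThresholdSpec",
    "SmoothnessEstimate",
    "ClusterReport",
    "fit_group_maps",
    "threshold_voxelwise",
    "find_clusters",
    "permutation_cluster_threshold",
    "estimate_smoothness",
    "montecarlo_cluster_threshold",
    "qa_cluster_timecourses",
    "grow_region",
    "cluster_report",
]

CONNECTIVITY_STRUCTS = {
    "faces": ndimage.generate_binary_structure(3, 1),
    "faces+edges": ndimage.generate_binary_structure(3, 2),
    "faces+edges+corners": ndimage.generate_binary_structure(3, 3),
}

GROUP_MODELS = ("mean", "vs_ARBS", "vs_BIS")
CONTRAST_NAMES = tuple(BUILTIN_CONTRASTS)


@dataclass
class GroupModel:
    """Second-level design: intercept only, or intercept + mean-centred score."""

    score_name: str = "none"  # "none" | "ARBS" | "BIS"
    scores: np.ndarray | None = None

    def design(self, n: int) -> np.ndarray:
        if self.score_name == "none":
            return np.ones((n, 1))
        s = np.asarray(self.scores, dtype=float)
        if s.std() == 0:
            raise ValueError(f"constant {self.score_name} scores cannot be regressed")
        s = s - s.mean()
        assert abs(s.mean()) < 1e-10
        return np.column_stack([np.ones(n), s])


@dataclass
class GroupMap:
    """One second-level t-map (for the coefficient of interest)."""

    contrast: str
    model: str
    t: np.ndarray
    effect: np.ndarray
    se: np.ndarray
    df: int


@dataclass
class StatMapSet:
    """The nine second-level maps, indexed by (contrast, model)."""

    maps: dict[tuple[str, str], GroupMap]
    voxel_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        expected = {(c, m) for c in CONTRAST_NAMES for m in GROUP_MODELS}
        if set(self.maps) != expected:
            raise ValueError(f"expected exactly nine maps {sorted(expected)}")

    def __getitem__(self, key: tuple[str, str]) -> GroupMap:
        return self.maps[key]


@dataclass
class ThresholdSpec:
    voxel_p: float
    df: int
    critical_t: float
    cluster_extent: int = 1
    connectivity: str = "faces"


@dataclass
class SmoothnessEstimate:
    fwhm_mm: tuple[float, float, float]
    fwhm_combined_mm: float
    voxel_size_mm: float


@dataclass
class ClusterReport:
    """Per-cluster summary mirroring a results table."""

    clusters: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Group fit
# ---------------------------------------------------------------------------

def _group_regression(
    effects: np.ndarray,
    ses: np.ndarray | None,
    X: np.ndarray,
    coef: int,
    df_override: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Voxelwise regression of first-level effects on a group design.

    With ``ses`` given, uses inverse-variance weights 1/(se^2 + tau^2) with
    a method-of-moments (DerSimonian-Laird) random-effects variance floored
    at zero.  With ``ses=None`` it is plain OLS (the simplified model used
    by the permutation calibrator).  Returns (effect, se, t, df) for the
    requested coefficient.
    """
    n, p = X.shape
    df = df_override if df_override is not None else n - p
    if df <= 0:
        raise ValueError("non-positive group degrees of freedom")
    E = np.atleast_2d(effects)  # (n, n_vox)
    n_vox = E.shape[1]

    if ses is None:
        pinv = np.linalg.pinv(X)
        B = pinv @ E
        resid = E - X @ B
        sigma2 = (resid**2).sum(axis=0) / (n - p)
        XtX_inv = np.linalg.inv(X.T @ X)
        se_c = np.sqrt(sigma2 * XtX_inv[coef, coef])
        eff = B[coef]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se_c > 0, eff / se_c, 0.0)
        return eff, se_c, t, df

    V = np.atleast_2d(ses) ** 2  # first-level variances (n, n_vox)
    eff = np.empty(n_vox)
    se_c = np.empty(n_vox)
    XtX_inv_unw = np.linalg.inv(X.T @ X)
    H = X @ XtX_inv_unw @ X.T
    for v in range(n_vox):
        y = E[:, v]
        w0 = 1.0 / np.maximum(V[:, v], 1e-12)
        # method of moments: Q from the fixed-effects (weighted) fit
        Wm = np.diag(w0)
        XtWX = X.T @ Wm @ X
        b_fe = np.linalg.solve(XtWX, X.T @ (w0 * y))
        r = y - X @ b_fe
        Q = float(np.sum(w0 * r**2))
        # E[Q] = (n - p) + tau^2 * (tr(W) - tr((X'WX)^-1 X'W^2X))
        trW = w0.sum()
        tr2 = float(np.trace(np.linalg.solve(XtWX, X.T @ np.diag(w0**2) @ X)))
        denom = trW - tr2
        tau2 = max(0.0, (Q - (n - p)) / denom) if denom > 0 else 0.0
        w = 1.0 / (V[:, v] + tau2)
        XtWX2 = X.T @ (X * w[:, None])
        cov = np.linalg.inv(XtWX2)
        b = cov @ (X.T @ (w * y))
        eff[v] = b[coef]
        se_c[v] = np.sqrt(cov[coef, coef])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se_c > 0, eff / se_c, 0.0)
    return eff, se_c, t, df


def fit_group_maps(
    first_level: dict[str, list[ContrastMap]] | list[dict[str, ContrastMap]],
    arbs: np.ndarray,
    bis: np.ndarray,
    mixed_effects: bool = True,
    df_override: int | None = None,
) -> StatMapSet:
    """Fit the nine second-level maps.

    ``first_level`` is either a mapping contrast-name -> list of per
    participant ContrastMaps, or a list (per participant) of mappings
    contrast-name -> ContrastMap.  ``mixed_effects=False`` selects the
    unweighted OLS mode used by the permutation calibrator.
    """
    if isinstance(first_level, list):
        by_contrast: dict[str, list[ContrastMap]] = {c: [] for c in CONTRAST_NAMES}
        for sub in first_level:
            for c in CONTRAST_NAMES:
                by_contrast[c].append(sub[c])
    else:
        by_contrast = first_level

    n = len(next(iter(by_contrast.values())))
    if n < 3:
        raise ValueError("need at least 3 participants")
    models = {
        "mean": GroupModel("none"),
        "vs_ARBS": GroupModel("ARBS", np.asarray(arbs, dtype=float)),
        "vs_BIS": GroupModel("BIS", np.asarray(bis, dtype=float)),
    }
    maps: dict[tuple[str, str], GroupMap] = {}
    for cname in CONTRAST_NAMES:
        cms = by_contrast[cname]
        E = np.vstack([cm.effect for cm in cms])
        S = np.vstack([cm.se for cm in cms]) if mixed_effects else None
        for mname, model in models.items():
            X = model.design(n)
            coef = 0 if mname == "mean" else 1
            eff, se, t, df = _group_regression(E, S, X, coef, df_override)
            maps[(cname, mname)] = GroupMap(
                contrast=cname, model=mname, t=t, effect=eff, se=se, df=df
            )
    return StatMapSet(maps=maps)


# ---------------------------------------------------------------------------
# Thresholding and clustering
# ---------------------------------------------------------------------------

def threshold_voxelwise(
    t_map: np.ndarray, p: float, df: int
) -> tuple[np.ndarray, float]:
    """Two-tailed voxelwise threshold: keep voxels with |t| above the
    t-distribution quantile at p."""
    if not (0 < p < 1):
        raise ValueError("p must be in (0, 1)")
    if df <= 0:
        raise ValueError("df must be positive")
    critical = float(stats.t.ppf(1 - p / 2, df))
    return np.abs(t_map) > critical, critical


def find_clusters(
    binary: np.ndarray,
    connectivity: str = "faces",
    signs: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Connected components of a suprathreshold binary volume.

    If ``signs`` is given (same shape, e.g. the t-map), positive and
    negative voxels are clustered separately.  Returns a list of index
    arrays (voxel coordinates, shape (k, 3)), largest first.
    """
    struct = CONNECTIVITY_STRUCTS[connectivity]
    parts = []
    if signs is None:
        parts.append(binary)
    else:
        parts.append(binary & (signs > 0))
        parts.append(binary & (signs < 0))
    clusters: list[np.ndarray] = []
    for part in parts:
        labeled, n = ndimage.label(part, structure=struct)
        for lbl in range(1, n + 1):
            clusters.append(np.argwhere(labeled == lbl))
    clusters.sort(key=len, reverse=True)
    return clusters


def _max_cluster_size(
    t_map_3d: np.ndarray, critical: float, connectivity: str
) -> int:
    binary = np.abs(t_map_3d) > critical
    if not binary.any():
        return 0
    sizes = [len(c) for c in find_clusters(binary, connectivity, signs=t_map_3d)]
    return max(sizes) if sizes else 0


def _extent_from_null(null_maxima: np.ndarray, alpha: float) -> int:
    """Smallest extent k such that a max cluster >= k occurs in <= alpha
    of null simulations (clusters of size >= k are retained)."""
    if alpha >= 1:
        return 1
    m = np.sort(np.asarray(null_maxima))
    n = len(m)
    t = int(np.floor(alpha * n))  # max tolerated exceedances
    if t < 1:
        raise ValueError(f"{n} iterations cannot resolve alpha={alpha}")
    return int(m[n - t - 1]) + 1


# ---------------------------------------------------------------------------
# Permutation calibration
# ---------------------------------------------------------------------------

def _permute_design(design: SessionDesign, rng: np.random.Generator) -> SessionDesign:
    """Shuffle trial-type labels across trials within a session (onsets fixed)."""
    labels = [tr.type for _, tr in design.all_trials()]
    rng.shuffle(labels)
    it = iter(labels)
    new_runs = []
    from dataclasses import replace

    for run in design.runs:
        new_runs.append([replace(t, type=next(it)) for t in run])
    return SessionDesign(
        runs=new_runs, run_duration=design.run_duration, seed=design.seed
    )


def permutation_cluster_threshold(
    datasets: list[np.ndarray],
    designs: list[SessionDesign],
    arbs: np.ndarray,
    bis: np.ndarray,
    mask_shape: tuple[int, int, int],
    voxel_coords: np.ndarray,
    n_iter: int = 1000,
    voxel_p: float = 0.01,
    alpha: float = 0.05,
    connectivity: str = "faces",
    tr: float = 2.0,
    n_discard: int = 6,
    seed: int | None = None,
    pool_maps: bool = True,
) -> tuple[int, np.ndarray]:
    """Cluster-extent threshold from trial-type label permutation.

    Each iteration independently permutes the four trial-type labels within
    each participant (onsets fixed), refits the first-level FIR model,
    fits a basic OLS second level for all nine maps, thresholds voxelwise
    (two-tailed) and records the maximum cluster size over all maps.  The
    returned threshold is the extent exceeded by the null maxima with
    probability alpha.  ``datasets`` holds per-participant (n_vox, n_t)
    matrices on the post-discard grid; ``voxel_coords`` their common (n_vox,
    3) voxel coordinates within ``mask_shape``.
    """
    if n_iter < 100 and alpha < 1:
        if n_iter * alpha < 1:
            raise ValueError(f"n_iter={n_iter} too small to resolve alpha={alpha}")
    rng = np.random.default_rng(seed)
    n_sub = len(datasets)
    keys = [(c, m) for c in CONTRAST_NAMES for m in GROUP_MODELS]
    maxima_per_map = np.zeros((n_iter, len(keys)), dtype=int)
    vol = np.zeros(mask_shape)
    idx = tuple(voxel_coords.T)
    for it in range(n_iter):
        firsts = []
        for s in range(n_sub):
            pdes = _permute_design(designs[s], rng)
            dm = build_design_matrix(pdes, tr=tr, n_discard=n_discard)
            fit = fit_first_level(datasets[s], dm, ar_correction=False)
            firsts.append({c: compute_contrast(fit, c) for c in CONTRAST_NAMES})
        stat = fit_group_maps(firsts, arbs, bis, mixed_effects=False)
        for j, key in enumerate(keys):
            gm = stat.maps[key]
            _, critical = threshold_voxelwise(gm.t, voxel_p, gm.df)
            vol[...] = 0
            vol[idx] = gm.t
            maxima_per_map[it, j] = _max_cluster_size(vol, critical, connectivity)
    if pool_maps:
        maxima = maxima_per_map.max(axis=1)
        return _extent_from_null(maxima, alpha), maxima
    thresholds = {
        key: _extent_from_null(maxima_per_map[:, j], alpha)
        for j, key in enumerate(keys)
    }
    return thresholds, maxima_per_map


# ---------------------------------------------------------------------------
# Residual smoothness and Monte Carlo calibration
# ---------------------------------------------------------------------------

def estimate_smoothness(
    residuals: np.ndarray,
    mask: np.ndarray,
    voxel_size_mm: float = 3.0,
) -> SmoothnessEstimate:
    """Residual spatial smoothness as Gaussian-equivalent FWHM per axis.

    ``residuals`` is (x, y, z, n_volumes).  Each volume is variance
    normalized within the mask; the lag-1 spatial correlation along each
    axis is estimated from mean squared first differences,
    E[(x_i - x_j)^2] = 2 (1 - rho_1), and converted to FWHM under a
    Gaussian autocorrelation model: FWHM = d * sqrt(2 ln 2 / (-ln rho_1)).
    The combined estimate is the geometric mean over axes.
    """
    residuals = np.asarray(residuals, dtype=float)
    if residuals.ndim == 3:
        residuals = residuals[..., None]
    if residuals.shape[-1] < 2:
        raise ValueError("need at least 2 residual volumes")
    fwhms = []
    n_vol = residuals.shape[-1]
    rho_axes = np.zeros(3)
    counts = np.zeros(3)
    for v in range(n_vol):
        vol = residuals[..., v]
        mvals = vol[mask]
        sd = mvals.std()
        if sd <= 0:
            raise ValueError("degenerate (constant) residual volume")
        vol = (vol - mvals.mean()) / sd
        for ax in range(3):
            sl_a = [slice(None)] * 3
            sl_b = [slice(None)] * 3
            sl_a[ax] = slice(1, None)
            sl_b[ax] = slice(None, -1)
            pair_mask = mask[tuple(sl_a)] & mask[tuple(sl_b)]
            if pair_mask.sum() < 2:
                continue
            d = vol[tuple(sl_a)][pair_mask] - vol[tuple(sl_b)][pair_mask]
            msd = float(np.mean(d**2))
            rho = 1.0 - msd / 2.0
            rho_axes[ax] += rho
            counts[ax] += 1
    fwhm = np.zeros(3)
    for ax in range(3):
        rho = rho_axes[ax] / max(counts[ax], 1)
        if rho <= 0:
            fwhm[ax] = voxel_size_mm  # sub-voxel smoothness: flag at voxel size
        else:
            fwhm[ax] = voxel_size_mm * np.sqrt(2 * np.log(2) / (-np.log(rho)))
    combined = float(np.exp(np.mean(np.log(np.maximum(fwhm, 1e-9)))))
    return SmoothnessEstimate(
        fwhm_mm=tuple(float(f) for f in fwhm),
        fwhm_combined_mm=combined,
        voxel_size_mm=voxel_size_mm,
    )


def montecarlo_cluster_threshold(
    mask: np.ndarray,
    fwhm_mm: float,
    voxel_p: float = 0.01,
    alpha: float = 0.05,
    n_iter: int = 1000,
    voxel_size_mm: float = 3.0,
    connectivity: str = "faces",
    seed: int | None = None,
) -> tuple[int, np.ndarray]:
    """AlphaSim-style Monte Carlo cluster-extent calibration.

    Each iteration smooths Gaussian white noise (on a grid padded by two
    kernel FWHMs so the field is stationary inside the mask) to the target
    smoothness, renormalizes variance within the mask, thresholds two-tailed
    at ``voxel_p`` (normal quantile), and records the maximum cluster size
    over positive and negative clusters.  Returns the extent threshold at
    family-wise level ``alpha`` and the null maxima.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if not (0 < voxel_p < 1):
        raise ValueError("voxel_p must be in (0, 1)")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    if not mask.any():
        raise ValueError("mask is empty")
    if alpha < 1 and n_iter * alpha < 1:
        raise ValueError(f"n_iter={n_iter} cannot resolve alpha={alpha}")
    rng = np.random.default_rng(seed)
    sigma_vox = fwhm_mm / (np.sqrt(8 * np.log(2)) * voxel_size_mm)
    pad = int(np.ceil(2 * fwhm_mm / voxel_size_mm)) if fwhm_mm > 0 else 0

    # crop to the mask bounding box for speed
    nz = np.argwhere(mask)
    lo = nz.min(axis=0)
    hi = nz.max(axis=0) + 1
    sub = mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    shape_pad = tuple(s + 2 * pad for s in sub.shape)
    inner = tuple(slice(pad, pad + s) for s in sub.shape)

    zcrit = float(stats.norm.ppf(1 - voxel_p / 2))
    maxima = np.zeros(n_iter, dtype=int)
    vol = np.zeros(sub.shape)
    for it in range(n_iter):
        noise = rng.standard_normal(shape_pad)
        if sigma_vox > 0:
            noise = ndimage.gaussian_filter(noise, sigma_vox)
        field = noise[inner]
        mvals = field[sub]
        field = (field - mvals.mean()) / mvals.std()
        vol[...] = 0.0
        vol[sub] = field[sub]
        maxima[it] = _max_cluster_size(vol, zcrit, connectivity)
    return _extent_from_null(maxima, alpha), maxima


# ---------------------------------------------------------------------------
# Cluster QA and region growing
# ---------------------------------------------------------------------------

def qa_cluster_timecourses(
    cluster_voxels: np.ndarray,
    data_4d: np.ndarray,
    design: SessionDesign,
    mask: np.ndarray,
    tr: float = 2.0,
    n_discard: int = 6,
    cutoff: float = 0.0,
    hrf_kwargs: dict | None = None,
) -> dict:
    """Quality-assure a cluster by its event-related timecourses.

    The cluster-mean timecourse is refit with the first-level FIR model;
    the per-type 7-point deconvolved timecourses are compared (averaged
    across types) with the canonical double-gamma response sampled at the
    FIR lags.  Verdict: "pass" when the correlation exceeds ``cutoff``,
    "fail" below it, "indeterminate" when the timecourses are flat.
    """
    if len(cluster_voxels) == 0:
        raise ValueError("empty cluster")
    idx = tuple(np.asarray(cluster_voxels).T)
    if not mask[idx].all():
        raise ValueError("cluster extends outside the mask")
    mean_tc = data_4d[idx].mean(axis=0)

    n_per_run = int(round(design.run_duration / tr))
    keep = np.concatenate(
        [
            np.arange(r * n_per_run + n_discard, (r + 1) * n_per_run)
            for r in range(len(design.runs))
        ]
    )
    y = mean_tc[keep] if mean_tc.shape[0] == n_per_run * len(design.runs) else mean_tc

    dm = build_design_matrix(design, tr=tr, n_discard=n_discard)
    fit = fit_first_level(y[None, :], dm, ar_correction=False)
    n_fir = dm.n_fir
    tcs = {}
    for t in TRIAL_TYPES:
        tcs[t] = np.array(
            [fit.betas[0, dm.fir_column(t, k + 1)] for k in range(n_fir)]
        )
    mean_over_types = np.mean(np.vstack(list(tcs.values())), axis=0)
    canonical = hrf(np.arange(n_fir) * tr, **(hrf_kwargs or {}))
    if np.std(mean_over_types) < 1e-12 or np.std(canonical) < 1e-12:
        return {"verdict": "indeterminate", "score": None, "timecourses": tcs}
    score = float(np.corrcoef(mean_over_types, canonical)[0, 1])
    return {
        "verdict": "pass" if score >= cutoff else "fail",
        "score": score,
        "timecourses": tcs,
    }


def grow_region(
    t_map_3d: np.ndarray,
    peak: tuple[int, int, int],
    threshold: float,
    max_size: int | None = None,
    connectivity: str = "faces",
) -> np.ndarray:
    """Breadth-first region growth from a statistical peak.

    Grows through suprathreshold voxels of the same sign as the peak, in
    deterministic order (frontier sorted by ascending linear index), until
    exhaustion or ``max_size``.  Returns (k, 3) voxel coordinates.
    """
    peak = tuple(int(c) for c in peak)
    pv = t_map_3d[peak]
    if abs(pv) < threshold:
        raise ValueError(f"peak value {pv:.3f} below threshold {threshold}")
    sign = np.sign(pv)
    struct = CONNECTIVITY_STRUCTS[connectivity]
    offsets = np.argwhere(struct) - 1
    offsets = offsets[np.any(offsets != 0, axis=1)]
    shape = t_map_3d.shape
    accepted = [peak]
    seen = {peak}
    frontier = [peak]
    while frontier and (max_size is None or len(accepted) < max_size):
        nxt = []
        for vox in frontier:
            for off in offsets:
                nb = (vox[0] + off[0], vox[1] + off[1], vox[2] + off[2])
                if not all(0 <= nb[d] < shape[d] for d in range(3)):
                    continue
                if nb in seen:
                    continue
                seen.add(nb)
                if sign * t_map_3d[nb] > threshold:
                    nxt.append(nb)
        nxt.sort(key=lambda v: (v[0] * shape[1] + v[1]) * shape[2] + v[2])
        added = []
        for nb in nxt:
            if max_size is not None and len(accepted) >= max_size:
                break
            accepted.append(nb)
            added.append(nb)
        frontier = added
    return np.array(accepted)


def cluster_report(
    clusters: list[np.ndarray],
    t_map_3d: np.ndarray,
    df: int,
    affine: np.ndarray | None = None,
    voxel_size_mm: float = 3.0,
) -> ClusterReport:
    """Summarize clusters: peak coordinate, size, volume, median p and t."""
    rows = []
    for cl in clusters:
        idx = tuple(np.asarray(cl).T)
        tvals = t_map_3d[idx]
        peak_i = int(np.argmax(np.abs(tvals)))
        peak_vox = np.asarray(cl)[peak_i]
        if affine is not None:
            xyz = (affine @ np.r_[peak_vox, 1.0])[:3]
        else:
            xyz = peak_vox * voxel_size_mm
        pvals = 2 * stats.t.sf(np.abs(tvals), df)
        rows.append(
            {
                "peak_x_mm": float(xyz[0]),
                "peak_y_mm": float(xyz[1]),
                "peak_z_mm": float(xyz[2]),
                "size_voxels": int(len(cl)),
                "volume_mm3": float(len(cl) * voxel_size_mm**3),
                "median_t": float(np.median(tvals)),
                "median_p": float(np.median(pvals)),
            }
        )
    return ClusterReport(clusters=rows)
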