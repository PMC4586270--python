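"""First-level FIR GLM with AR pre-whitening and contrast maps.

The within-subject model deconvolves event-related responses with 7 finite
impulse response (FIR) predictors per trial type on the 2-s volume grid
(plus an optional FIR set for error trials), alongside per-run nuisance
regressors (offset, linear drift, cosine and sine at period twice the run
length, and any caller-supplied columns such as motion parameters or
noise-ROI means).  Temporal autocorrelation is estimated per slice to lag
10 from initial ordinary-least-squares residuals, stabilized by
Levinson-Durbin, and the fit is re-run as generalized least squares under
the implied AR covariance.  Contrasts combine the FIR betas at the 3rd and
4th timepoints (4 and 6 s after trial onset), where the hemodynamic
response peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cholesky, solve_triangular, toeplitz

from .design import TRIAL_TYPES, SessionDesign

__all__ = [
    "DesignMatrix",
    "FirstLevelFit",
    "ContrastDef",
    "ContrastMap",
    "BUILTIN_CONTRASTS",
    "build_design_matrix",
    "estimate_autocorrelation",
    "prewhiten_and_fit",
    "compute_contrast",
    "fit_first_level",
]

N_FIR = 7
MAX_AR_LAG = 10
N_DISCARD = 6


@dataclass
class DesignMatrix:
    """Volumes x columns matrix with labeled columns and run structure."""

    matrix: np.ndarray
    labels: list[str]
    run_slices: list[slice]  # row ranges per run (post-discard grid)
    n_fir: int = N_FIR

    @property
    def task_columns(self) -> list[int]:
        return [i for i, l in enumerate(self.labels) if l.startswith("fir:")]

    def fir_column(self, trial_type: str, lag: int) -> int:
        """Column index of FIR predictor for a type at lag (1-based)."""
        try:
            return self.labels.index(f"fir:{trial_type}:{lag}")
        except ValueError:
            raise KeyError(f"no FIR column for {trial_type} lag {lag}") from None


@dataclass
class FirstLevelFit:
    """Per-voxel GLS estimates under the per-slice AR noise model."""

    betas: np.ndarray  # (n_vox, n_col)
    resid_var: np.ndarray  # (n_vox,)
    cov_unscaled: np.ndarray  # (n_vox_groups, n_col, n_col) per slice group
    slice_of_voxel: np.ndarray  # (n_vox,) index into cov_unscaled
    ar_coefficients: np.ndarray  # (n_slices, <=MAX_AR_LAG)
    df: int
    design: DesignMatrix
    voxel_index: np.ndarray | None = None  # coordinates of rows, optional


@dataclass(frozen=True)
class ContrastDef:
    """Weights over trial types, applied to mean FIR betas at timepoints."""

    name: str
    weights: dict[str, float]
    timepoints: tuple[int, ...] = (3, 4)
    combine: str = "mean"  # or "sum"

    def __post_init__(self) -> None:
        if any(tp < 1 or tp > N_FIR for tp in self.timepoints):
            raise ValueError(f"timepoints must be within 1..{N_FIR}")
        if self.combine not in ("mean", "sum"):
            raise ValueError("combine must be 'mean' or 'sum'")


BUILTIN_CONTRASTS = {
    "response_inhibition": ContrastDef(
        "response_inhibition",
        {"aversive-nogo": 1.0, "neutral-nogo": 1.0, "aversive-go": -1.0, "neutral-go": -1.0},
    ),
    "emotional_valence": ContrastDef(
        "emotional_valence",
        {"aversive-nogo": 1.0, "aversive-go": 1.0, "neutral-nogo": -1.0, "neutral-go": -1.0},
    ),
    "interaction": ContrastDef(
        "interaction",
        {"aversive-nogo": 1.0, "aversive-go": -1.0, "neutral-nogo": -1.0, "neutral-go": 1.0},
    ),
}


@dataclass
class ContrastMap:
    """Per-voxel effect, SE, and two-tailed t for one contrast."""

    name: str
    effect: np.ndarray
    se: np.ndarray
    t: np.ndarray
    df: int
    voxel_index: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

def build_design_matrix(
    design: SessionDesign,
    error_onsets: list[tuple[int, float]] | None = None,
    nuisance: list[np.ndarray] | None = None,
    tr: float = 2.0,
    n_discard: int = N_DISCARD,
    n_fir: int = N_FIR,
) -> DesignMatrix:
    """Build the FIR design matrix on the post-discard volume grid.

    ``error_onsets`` is a list of (run index, onset seconds); error trials
    get their own FIR set and are removed from their type's set.
    ``nuisance`` supplies one (volumes_per_run x k) array per run of extra
    columns (e.g. motion parameters, noise-ROI means); standard nuisance
    (offset, drift, cosine, sine) is always included per run and zero
    outside its run.
    """
    n_per_run = int(round(design.run_duration / tr))
    n_keep = n_per_run - n_discard
    n_runs = len(design.runs)
    error_set = set()
    for r, onset in error_onsets or []:
        if abs(onset / tr - round(onset / tr)) > 1e-9:
            raise ValueError(f"error onset {onset} not on the TR grid")
        error_set.add((r, round(onset / tr)))

    has_errors = bool(error_set)
    fir_types = list(TRIAL_TYPES) + (["error"] if has_errors else [])
    n_task = len(fir_types) * n_fir

    rows_total = n_keep * n_runs
    X_task = np.zeros((rows_total, n_task))
    run_slices = [slice(r * n_keep, (r + 1) * n_keep) for r in range(n_runs)]

    def add_impulses(r: int, vol: int, type_idx: int) -> None:
        base = r * n_keep
        for k in range(n_fir):
            row = vol + k - n_discard
            if 0 <= row < n_keep:
                X_task[base + row, type_idx * n_fir + k] = 1.0

    for r, run in enumerate(design.runs):
        for trial in run:
            if abs(trial.onset / tr - round(trial.onset / tr)) > 1e-9:
                raise ValueError(f"onset {trial.onset} not on the TR grid")
            vol = round(trial.onset / tr)
            if vol < n_discard:
                raise ValueError(
                    f"trial onset {trial.onset}s falls in the {n_discard}-volume lead-in"
                )
            if (r, vol) in error_set:
                add_impulses(r, vol, fir_types.index("error"))
            else:
                add_impulses(r, vol, TRIAL_TYPES.index(trial.type))

    labels = [f"fir:{t}:{k + 1}" for t in fir_types for k in range(n_fir)]

    # per-run nuisance block
    tgrid = (np.arange(n_discard, n_per_run) * tr).astype(float)
    period = 2.0 * design.run_duration
    nuis_cols = []
    nuis_labels = []
    for r in range(n_runs):
        base = np.zeros((rows_total, 4))
        base[run_slices[r], 0] = 1.0
        base[run_slices[r], 1] = np.linspace(-1, 1, n_keep)
        base[run_slices[r], 2] = np.cos(2 * np.pi * tgrid / period)
        base[run_slices[r], 3] = np.sin(2 * np.pi * tgrid / period)
        nuis_cols.append(base)
        nuis_labels += [f"run{r}:{n}" for n in ("offset", "drift", "cos", "sin")]
        if nuisance is not None:
            extra = np.asarray(nuisance[r], dtype=float)
            if extra.ndim == 1:
                extra = extra[:, None]
            if extra.shape[0] == n_per_run:
                extra = extra[n_discard:]
            if extra.shape[0] != n_keep:
                raise ValueError(
                    f"nuisance run {r}: {extra.shape[0]} rows != {n_keep} kept volumes"
                )
            block = np.zeros((rows_total, extra.shape[1]))
            block[run_slices[r]] = extra
            nuis_cols.append(block)
            nuis_labels += [f"run{r}:extra{j}" for j in range(extra.shape[1])]

    X = np.hstack([X_task] + nuis_cols)
    all_labels = labels + nuis_labels
    if len(set(all_labels)) != len(all_labels):
        raise ValueError("duplicate design-matrix column labels")
    return DesignMatrix(matrix=X, labels=all_labels, run_slices=run_slices, n_fir=n_fir)


# ---------------------------------------------------------------------------
# Autocorrelation estimation
# ---------------------------------------------------------------------------

def estimate_autocorrelation(
    residuals: np.ndarray,
    run_slices: list[slice],
    max_lag: int = MAX_AR_LAG,
) -> np.ndarray:
    """Pooled sample autocorrelations (lags 1..max_lag) of residuals.

    ``residuals`` is (n_vox, n_t) for the voxels of one slice; lagged
    products are computed within runs and pooled across voxels, normalized
    by the pooled lag-0 power.
    """
    residuals = np.atleast_2d(np.asarray(residuals, dtype=float))
    n_run_min = min(s.stop - s.start for s in run_slices)
    if n_run_min <= max_lag:
        raise ValueError(f"runs of {n_run_min} volumes cannot support lag {max_lag}")
    num = np.zeros(max_lag)
    den = 0.0
    for s in run_slices:
        r = residuals[:, s]
        r = r - r.mean(axis=1, keepdims=True)
        den += float((r * r).sum())
        for k in range(1, max_lag + 1):
            num[k - 1] += float((r[:, k:] * r[:, :-k]).sum())
    if den <= 0:
        return np.zeros(max_lag)
    return num / den


def _levinson_durbin(rho: np.ndarray) -> np.ndarray:
    """AR coefficients from an autocorrelation sequence (lags 1..p).

    Standard Levinson-Durbin recursion; reflection coefficients clipped to
    (-1, 1) so the returned model is always stationary.
    """
    p = len(rho)
    a = np.zeros(p)
    e = 1.0
    a_prev = np.zeros(p)
    for k in range(p):
        acc = rho[k] - np.dot(a_prev[:k], rho[k - 1 :: -1][:k]) if k else rho[0]
        kappa = acc / e if e > 1e-12 else 0.0
        kappa = float(np.clip(kappa, -0.999, 0.999))
        a = a_prev.copy()
        a[k] = kappa
        for j in range(k):
            a[j] = a_prev[j] - kappa * a_prev[k - 1 - j]
        e *= 1 - kappa**2
        a_prev = a
    return a


def _ar_acf(ar: np.ndarray, n: int) -> np.ndarray:
    """Autocorrelation function of an AR(p) process out to lag n.

    The first p autocorrelations solve the Yule-Walker equations
    rho_i = sum_j a_j rho_{|i-j|}; later lags follow the AR recursion.
    """
    p = len(ar)
    rho = np.zeros(max(n, p) + 1)
    rho[0] = 1.0
    if p == 0:
        return rho[: n + 1]
    M = np.eye(p)
    rhs = np.zeros(p)
    for i in range(1, p + 1):
        for j in range(1, p + 1):
            lag = abs(i - j)
            if lag == 0:
                rhs[i - 1] += ar[j - 1]
            else:
                M[i - 1, lag - 1] -= ar[j - 1]
    rho[1 : p + 1] = np.linalg.solve(M, rhs)
    for k in range(p + 1, len(rho)):
        rho[k] = np.dot(ar, rho[k - p : k][::-1])
    return rho[: n + 1]


# ---------------------------------------------------------------------------
# Pre-whitened (GLS) fit
# ---------------------------------------------------------------------------

def _whitener_from_acf(rho: np.ndarray, n: int) -> np.ndarray:
    """Inverse Cholesky factor W with W C W' = I for Toeplitz correlation C."""
    full = np.zeros(n)
    m = min(len(rho), n)
    full[:m] = rho[:m]
    C = toeplitz(full)
    L = cholesky(C, lower=True)
    return solve_triangular(L, np.eye(n), lower=True)


def prewhiten_and_fit(
    data: np.ndarray,
    design: DesignMatrix,
    ar: np.ndarray | None = None,
    slice_of_voxel: np.ndarray | None = None,
) -> FirstLevelFit:
    """Generalized least squares under per-slice AR noise models.

    ``data`` is (n_vox, n_t) on the post-discard grid; ``ar`` is
    (n_slices, p) AR coefficients (all-zero rows reduce to OLS);
    ``slice_of_voxel`` maps each voxel row to its slice (default: one
    slice for all voxels).  The whitening transform is the exact inverse
    Cholesky factor of the AR-process correlation matrix applied per run,
    so with ar=0 the result equals ordinary least squares.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n_vox, n_t = data.shape
    X = design.matrix
    if X.shape[0] != n_t:
        raise ValueError(f"data has {n_t} volumes but design has {X.shape[0]} rows")
    if ar is None:
        ar = np.zeros((1, 1))
    ar = np.atleast_2d(np.asarray(ar, dtype=float))
    if slice_of_voxel is None:
        slice_of_voxel = np.zeros(n_vox, dtype=int)
    n_slices = ar.shape[0]

    n_col = X.shape[1]
    betas = np.empty((n_vox, n_col))
    resid_var = np.empty(n_vox)
    cov_unscaled = np.empty((n_slices, n_col, n_col))
    rank = np.linalg.matrix_rank(X)
    df = n_t - rank
    if df <= 0:
        raise ValueError("non-positive residual degrees of freedom")

    for s in range(n_slices):
        vox = np.flatnonzero(slice_of_voxel == s)
        if len(vox) == 0:
            cov_unscaled[s] = np.nan
            continue
        nz = np.flatnonzero(np.abs(ar[s]) > 0)
        coefs = ar[s][: nz[-1] + 1] if len(nz) else np.empty(0)
        Xw = X.copy()
        Yw = data[vox].T.copy()
        if len(coefs):
            # spectral-radius guard: reduce order until stationary
            a = np.asarray(coefs, dtype=float)
            while len(a) and np.any(np.abs(np.roots(np.r_[1.0, -a])) >= 1.0):
                a = a[:-1]
            if len(a):
                for rs in design.run_slices:
                    n_run = rs.stop - rs.start
                    rho = _ar_acf(a, n_run - 1)
                    W = _whitener_from_acf(rho, n_run)
                    Xw[rs] = W @ X[rs]
                    Yw[rs] = W @ Yw[rs]
        XtX = Xw.T @ Xw
        XtX_inv = np.linalg.pinv(XtX)
        B = XtX_inv @ (Xw.T @ Yw)
        resid = Yw - Xw @ B
        rss = (resid**2).sum(axis=0)
        betas[vox] = B.T
        resid_var[vox] = rss / df
        cov_unscaled[s] = XtX_inv

    return FirstLevelFit(
        betas=betas,
        resid_var=resid_var,
        cov_unscaled=cov_unscaled,
        slice_of_voxel=slice_of_voxel,
        ar_coefficients=ar,
        df=df,
        design=design,
    )


def fit_first_level(
    data: np.ndarray,
    design: DesignMatrix,
    slice_of_voxel: np.ndarray | None = None,
    max_lag: int = MAX_AR_LAG,
    ar_correction: bool = True,
) -> FirstLevelFit:
    """Two-pass fit: OLS residuals -> per-slice AR estimate -> GLS refit.

    Autocorrelations are pooled per slice over voxels; Levinson-Durbin
    converts them to a stationary AR(max_lag) model.  When residual power
    is negligible (noise-free data) the AR step is skipped.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if slice_of_voxel is None:
        slice_of_voxel = np.zeros(data.shape[0], dtype=int)
    n_slices = int(slice_of_voxel.max()) + 1

    ols = prewhiten_and_fit(data, design, ar=np.zeros((1, 1)), slice_of_voxel=None)
    if not ar_correction:
        return ols
    resid = data - ols.betas @ design.matrix.T
    scale = np.sqrt(np.mean(data**2)) + 1e-12
    ar = np.zeros((n_slices, max_lag))
    for s in range(n_slices):
        vox = np.flatnonzero(slice_of_voxel == s)
        if len(vox) == 0:
            continue
        r = resid[vox]
        if np.sqrt(np.mean(r**2)) / scale < 1e-8:
            continue  # noise-free: keep OLS
        rho = estimate_autocorrelation(r, design.run_slices, max_lag=max_lag)
        ar[s] = _levinson_durbin(rho)
    return prewhiten_and_fit(data, design, ar=ar, slice_of_voxel=slice_of_voxel)


# ---------------------------------------------------------------------------
# Contrasts
# ---------------------------------------------------------------------------

def contrast_vector(design: DesignMatrix, cdef: ContrastDef) -> np.ndarray:
    """Linear weight vector over design columns implementing a contrast."""
    c = np.zeros(design.matrix.shape[1])
    k = len(cdef.timepoints)
    tp_weight = 1.0 / k if cdef.combine == "mean" else 1.0
    for trial_type, w in cdef.weights.items():
        for tp in cdef.timepoints:
            c[design.fir_column(trial_type, tp)] = w * tp_weight
    return c


def compute_contrast(fit: FirstLevelFit, cdef: ContrastDef | str) -> ContrastMap:
    """Effect, SE, and two-tailed t of a trial-type contrast.

    The effect is the contrast of per-type FIR betas combined over the
    configured timepoints (default: mean of timepoints 3 and 4, i.e. 4 and
    6 s post-onset).
    """
    if isinstance(cdef, str):
        cdef = BUILTIN_CONTRASTS[cdef]
    c = contrast_vector(fit.design, cdef)
    effect = fit.betas @ c
    var_factor = np.array(
        [float(c @ fit.cov_unscaled[s] @ c) for s in range(fit.cov_unscaled.shape[0])]
    )
    se = np.sqrt(np.maximum(fit.resid_var * var_factor[fit.slice_of_voxel], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / se, 0.0)
    return ContrastMap(
        name=cdef.name, effect=effect, se=se, t=t, df=fit.df, voxel_index=fit.voxel_index
    )
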