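"""Region-by-contrast correlation patterns and the similarity statistic.

For each atlas region and each first-level contrast, the per-participant
mean contrast value is correlated with an instrument's scores (risk or
impulsivity), yielding a correlation pattern (default 26 regions x 3
contrasts = 78 entries per instrument).  Two patterns are compared with

    S(a, b) = 1 - ||a - b||^2 / L,

one minus the mean squared entrywise difference: S = 1 iff the patterns
are identical, S = 0 when e.g. one pattern is all ones and the other all
zeros, and S >= -3 for correlation-valued entries.  The literal
Euclidean-distance form (1 - ||a - b|| / L) is available via
``norm="euclidean"``.  The stratified split-resampling test repeatedly
splits participants into two groups (balancing low/mid/high risk strata),
computes instrument A's pattern from one group and instrument B's from the
other, and reports the distribution of S against the 0.3 ("substantially
different") and 0.7 ("very similar") cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glm import ContrastMap

__all__ = [
    "RegionContrastValues",
    "CorrelationPattern",
    "SimilarityResult",
    "region_contrast_values",
    "compute_pattern",
    "similarity",
    "split_similarity_test",
]

DEFAULT_CUTOFFS = (0.3, 0.7)


@dataclass
class RegionContrastValues:
    """Participants x (region x contrast) matrix of mean contrast values."""

    values: np.ndarray  # (n_participants, n_regions * n_contrasts)
    region_labels: list[int]
    contrast_names: list[str]
    participant_ids: list[str] = field(default_factory=list)

    @property
    def n_columns(self) -> int:
        return len(self.region_labels) * len(self.contrast_names)

    def to_frame(self) -> pd.DataFrame:
        cols = [
            f"region{r}:{c}" for r in self.region_labels for c in self.contrast_names
        ]
        idx = self.participant_ids or list(range(self.values.shape[0]))
        return pd.DataFrame(self.values, columns=cols, index=idx)


@dataclass
class CorrelationPattern:
    """One instrument's vector of per-(region, contrast) correlations."""

    values: np.ndarray
    instrument: str
    n_participants: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any(np.abs(v) > 1 + 1e-9):
            raise ValueError("correlation entries must lie in [-1, 1]")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class SimilarityResult:
    mean: float
    sd: float
    prop_below_low: float
    prop_above_high: float
    n_iter: int
    cutoffs: tuple[float, float] = DEFAULT_CUTOFFS
    similarities: np.ndarray | None = None


# ---------------------------------------------------------------------------


def region_contrast_values(
    contrast_maps: list[dict[str, ContrastMap]],
    atlas_labels: np.ndarray,
    mask: np.ndarray | None = None,
    voxel_coords: np.ndarray | None = None,
    contrast_names: tuple[str, ...] | None = None,
    participant_ids: list[str] | None = None,
) -> RegionContrastValues:
    """Mean first-level contrast value per (participant, region, contrast).

    ``contrast_maps`` holds, per participant, a mapping contrast-name ->
    ContrastMap whose ``effect`` is either a 3D volume on the atlas grid or
    a flat vector indexed by ``voxel_coords``.
    """
    if mask is None:
        mask = atlas_labels > 0
    labels = sorted(int(l) for l in np.unique(atlas_labels) if l != 0)
    if contrast_names is None:
        contrast_names = tuple(contrast_maps[0].keys())

    # region voxel indices on the flat or 3D representation
    region_index: dict[int, np.ndarray] = {}
    if voxel_coords is not None:
        lbl_of_voxel = atlas_labels[tuple(np.asarray(voxel_coords).T)]
        msk_of_voxel = mask[tuple(np.asarray(voxel_coords).T)]
        for lbl in labels:
            region_index[lbl] = np.flatnonzero((lbl_of_voxel == lbl) & msk_of_voxel)
    else:
        for lbl in labels:
            region_index[lbl] = None  # use boolean 3D indexing below
    for lbl in labels:
        if voxel_coords is not None and len(region_index[lbl]) == 0:
            raise ValueError(f"region {lbl} empty within mask")
        if voxel_coords is None and not ((atlas_labels == lbl) & mask).any():
            raise ValueError(f"region {lbl} empty within mask")

    rows = []
    for sub in contrast_maps:
        row = []
        for lbl in labels:
            for c in contrast_names:
                eff = np.asarray(sub[c].effect)
                if voxel_coords is not None:
                    row.append(float(eff[region_index[lbl]].mean()))
                else:
                    row.append(float(eff[(atlas_labels == lbl) & mask].mean()))
        rows.append(row)
    # column order must be region-major to match (region, contrast) indexing
    values = np.asarray(rows, dtype=float)
    return RegionContrastValues(
        values=values,
        region_labels=labels,
        contrast_names=list(contrast_names),
        participant_ids=participant_ids or [],
    )


def compute_pattern(
    values: RegionContrastValues | np.ndarray,
    scores: np.ndarray,
    instrument: str = "score",
    participant_subset: np.ndarray | None = None,
) -> CorrelationPattern:
    """Pearson correlation of each (region, contrast) column with scores."""
    V = values.values if isinstance(values, RegionContrastValues) else np.asarray(values)
    s = np.asarray(scores, dtype=float)
    if participant_subset is not None:
        V = V[participant_subset]
        s = s[participant_subset]
    if V.shape[0] < 3:
        raise ValueError("need at least 3 participants")
    if s.std() == 0:
        raise ValueError("constant scores: correlation undefined")
    col_sd = V.std(axis=0)
    if np.any(col_sd == 0):
        bad = np.flatnonzero(col_sd == 0)
        raise ValueError(f"constant contrast-value column(s) {bad.tolist()}")
    Vc = V - V.mean(axis=0)
    sc = s - s.mean()
    r = (Vc.T @ sc) / (np.sqrt((Vc**2).sum(axis=0)) * np.sqrt((sc**2).sum()))
    r = np.clip(r, -1.0, 1.0)
    return CorrelationPattern(values=r, instrument=instrument, n_participants=V.shape[0])


def similarity(
    c_a: CorrelationPattern | np.ndarray,
    c_b: CorrelationPattern | np.ndarray,
    norm: str = "squared",
) -> float:
    """Similarity between two correlation patterns.

    ``norm="squared"`` (default): S = 1 - mean squared difference;
    ``norm="euclidean"``: S = 1 - Euclidean distance / length.
    """
    a = np.asarray(c_a.values if isinstance(c_a, CorrelationPattern) else c_a, float)
    b = np.asarray(c_b.values if isinstance(c_b, CorrelationPattern) else c_b, float)
    if a.shape != b.shape:
        raise ValueError(f"pattern lengths differ: {a.shape} vs {b.shape}")
    L = a.size
    d = a - b
    if norm == "squared":
        return float(1.0 - (d @ d) / L)
    if norm == "euclidean":
        return float(1.0 - np.sqrt(d @ d) / L)
    raise ValueError("norm must be 'squared' or 'euclidean'")


def _stratified_split(
    risk_classes: list[str] | np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Random split into two near-equal groups, strata as even as possible."""
    rc = np.asarray(risk_classes)
    g1, g2 = [], []
    # odd members of odd-sized strata go to whichever group is currently
    # smaller (random on ties) so total sizes differ by at most 1
    for stratum in np.unique(rc):
        idx = np.flatnonzero(rc == stratum)
        if len(idx) < 2:
            raise ValueError(f"stratum {stratum!r} has fewer than 2 participants")
        idx = rng.permutation(idx)
        half = len(idx) // 2
        g1.extend(idx[:half])
        g2.extend(idx[half : 2 * half])
        if len(idx) % 2 == 1:
            extra = idx[-1]
            if len(g1) < len(g2) or (len(g1) == len(g2) and rng.random() < 0.5):
                g1.append(extra)
            else:
                g2.append(extra)
    return np.sort(np.array(g1)), np.sort(np.array(g2))


def split_similarity_test(
    values: RegionContrastValues | np.ndarray,
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    risk_classes: list[str] | np.ndarray,
    n_iter: int = 10_000,
    cutoffs: tuple[float, float] = DEFAULT_CUTOFFS,
    norm: str = "squared",
    seed: int | None = None,
    instrument_a: str = "ARBS",
    instrument_b: str = "BIS",
    keep_similarities: bool = True,
) -> SimilarityResult:
    """Stratified split-resampling test of pattern similarity.

    Per iteration: participants are split into two near-equal groups with
    low/high (and any mid) risk strata balanced; instrument A's pattern is
    computed from group 1 and instrument B's from group 2; S is recorded.
    Reports mean, SD, and the proportions of iterations with S below the
    low cutoff ("substantially different") and above the high cutoff
    ("very similar").
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    V = values if isinstance(values, RegionContrastValues) else np.asarray(values)
    rng = np.random.default_rng(seed)
    sims = np.empty(n_iter)
    for it in range(n_iter):
        g1, g2 = _stratified_split(risk_classes, rng)
        pa = compute_pattern(V, scores_a, instrument_a, participant_subset=g1)
        pb = compute_pattern(V, scores_b, instrument_b, participant_subset=g2)
        sims[it] = similarity(pa, pb, norm=norm)
    lo, hi = cutoffs
    return SimilarityResult(
        mean=float(sims.mean()),
        sd=float(sims.std(ddof=1)) if n_iter > 1 else 0.0,
        prop_below_low=float(np.mean(sims < lo)),
        prop_above_high=float(np.mean(sims > hi)),
        n_iter=n_iter,
        cutoffs=cutoffs,
        similarities=sims if keep_similarities else None,
    )
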