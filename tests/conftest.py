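"""Shared fixtures: scaled-down designs, cohorts, and BOLD sessions.

Everything is generated programmatically at test time with fixed seeds;
grids and trial counts are far smaller than the published experiment so
the suite stays fast, but the statistical structure (trial mix ratios,
AR + spatially smooth noise, bimodal risk scores) is preserved.
"""

from __future__ import annotations

import numpy as np
import pytest

import emogonogo as eg
from emogonogo.design import DesignConfig

SMALL_GRID = (8, 8, 4)

#: 4:1 Go/NoGo ratio preserved at 1/7 the session size, one run
SMALL_COUNTS = {
    "neutral-go": 12,
    "aversive-go": 12,
    "neutral-nogo": 4,
    "aversive-nogo": 4,
}


@pytest.fixture(scope="session")
def small_design_config() -> DesignConfig:
    return DesignConfig(
        counts=dict(SMALL_COUNTS), n_runs=1, run_duration=220.0, n_attempts=20
    )


@pytest.fixture(scope="session")
def small_design(small_design_config):
    return eg.generate_session_design(small_design_config, seed=7)


@pytest.fixture(scope="session")
def default_design():
    """The full published design: 204 trials over four 330-s runs."""
    return eg.generate_session_design(eg.DesignConfig(), seed=11)


@pytest.fixture(scope="session")
def small_mask():
    return np.ones(SMALL_GRID, dtype=bool)


@pytest.fixture(scope="session")
def moderate_noise() -> eg.NoiseSpec:
    return eg.NoiseSpec(
        ar_coefficients=(0.3,),
        innovation_sd=1.0,
        spatial_fwhm_mm=5.0,
        drift_amplitude=0.2,
        motion_amplitude=0.0,
    )


@pytest.fixture(scope="session")
def quiet_noise() -> eg.NoiseSpec:
    """No noise at all: deterministic signal + baseline."""
    return eg.NoiseSpec(
        ar_coefficients=(),
        innovation_sd=0.0,
        spatial_fwhm_mm=0.0,
        drift_amplitude=0.0,
        motion_amplitude=0.0,
    )


def make_null_cohort_data(
    seed: int,
    n_sub: int = 6,
    design_config: DesignConfig | None = None,
    grid=SMALL_GRID,
    noise: eg.NoiseSpec | None = None,
):
    """Null (no-effect) cohort: per-participant post-discard data matrices."""
    design_config = design_config or DesignConfig(
        counts=dict(SMALL_COUNTS), n_runs=1, run_duration=220.0, n_attempts=20
    )
    noise = noise or eg.NoiseSpec(
        ar_coefficients=(0.3,), innovation_sd=1.0, spatial_fwhm_mm=5.0,
        drift_amplitude=0.2, motion_amplitude=0.0,
    )
    mask = np.ones(grid, dtype=bool)
    atlas = np.ones(grid, dtype=int)
    rng = np.random.default_rng(seed)
    cohort = eg.generate_cohort(n=n_sub, n_high=n_sub // 2, seed=seed)
    datasets, designs = [], []
    for p in cohort:
        d = eg.generate_session_design(design_config, seed=int(rng.integers(2**31)))
        s = eg.generate_bold_session(
            p, design=d, effects=eg.EffectSpec(), noise=noise,
            grid=grid, atlas=atlas, mask=mask, seed=int(rng.integers(2**31)),
        )
        npr = s.volumes_per_run
        keep = np.concatenate(
            [np.arange(r * npr + 6, (r + 1) * npr) for r in range(s.n_runs)]
        )
        datasets.append(s.data[mask][:, keep])
        designs.append(d)
    arbs = np.array([p.arbs for p in cohort], dtype=float)
    bis = np.array([p.bis for p in cohort], dtype=float)
    return datasets, designs, arbs, bis, mask
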