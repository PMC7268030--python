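"""Shared fixtures: small synthetic cohorts with known ground truth."""

import warnings

import numpy as np
import pytest

from icalearn import (
    ClassifierConfig,
    ComponentTemplate,
    PipelineConfig,
    SiteParams,
    SyntheticConfig,
    VolumeGrid,
    group_ica,
    simulate_cohort,
)


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    # Tiny test decompositions may stop at max_iter; that is a recorded
    # warning state, not a failure mode under test here.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture(scope="session")
def small_grid():
    return VolumeGrid.full((8, 8, 4))


def make_cohort(
    grid,
    n_per_group=8,
    sites=("main",),
    effect_size=1.2,
    noise_sd=0.5,
    seed=0,
    T=(40, 36),
    K_true=4,
    n_affected=2,
    site_params=None,
):
    cfg = SyntheticConfig(
        n_per_group_per_site={s: (n_per_group, n_per_group) for s in sites},
        T_per_site={s: T[i] for i, s in enumerate(sites)},
        K_true=K_true,
        grid=grid,
        effect_size=effect_size,
        n_affected=n_affected,
        site_params=site_params or {s: SiteParams(noise_sd=noise_sd) for s in sites},
        seed=seed,
    )
    return simulate_cohort(cfg)


def small_pipeline_config(d=4, t0_percentiles=(50, 60, 70, 80, 90, 95)):
    return PipelineConfig(
        n_sub_pc=10,
        K=4,
        classifier=ClassifierConfig(d=d, t0_percentiles=t0_percentiles),
    )


@pytest.fixture(scope="session")
def strong_cohort(small_grid):
    """One-site cohort with a strong planted group effect."""
    scans, truth = make_cohort(small_grid, n_per_group=10, effect_size=1.5, seed=11)
    return scans, truth


@pytest.fixture(scope="session")
def strong_decomposition(strong_cohort):
    scans, _ = strong_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        dec = group_ica(scans, n_sub_pc=10, K=4, seed=0)
    return dec


@pytest.fixture(scope="session")
def strong_template(strong_decomposition):
    return ComponentTemplate(
        strong_decomposition.spatial_maps, tuple(range(4)), provenance="test full-set ICA"
    )
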