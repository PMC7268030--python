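"""Simulate a labeled cohort and recover its planted networks by group ICA.

Generates 15 controls and 15 patients whose scans are Laplace time
courses mixing six compact spatial maps, then runs two-stage PCA +
Infomax group ICA and reports how well the estimated spatial components
match the planted ground truth.
"""

import numpy as np

from icalearn import (
    SiteParams,
    SyntheticConfig,
    VolumeGrid,
    group_ica,
    optimal_assignment,
    simulate_cohort,
)

cfg = SyntheticConfig(
    n_per_group_per_site={"main": (15, 15)},
    T_per_site={"main": 60},
    K_true=6,
    grid=VolumeGrid.full((12, 12, 8)),
    effect_size=1.0,
    n_affected=3,
    site_params={"main": SiteParams(noise_sd=0.1)},
    seed=2,
)
scans, truth = simulate_cohort(cfg)
print(f"simulated {len(scans)} subjects, grid {cfg.grid.shape}, K_true=6")

dec = group_ica(scans, n_sub_pc=20, K=6, seed=0)
C = np.corrcoef(dec.spatial_maps, truth.component_maps)[:6, 6:]
assign = optimal_assignment(C)
matched = np.abs(C[np.arange(6), assign])
print("matched |corr| per component:", np.round(matched, 3))
print(f"mean matched |corr| = {matched.mean():.3f}")
print(
    "\nValues near 1 mean the unsupervised decomposition found the"
    "\nplanted resting-state networks despite noise and group effects."
)
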