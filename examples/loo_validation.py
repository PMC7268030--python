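"""Within-site leave-one-out validation of the component-vote classifier.

For each held-out subject the full pipeline is refit from scratch on the
remaining subjects: group ICA, template matching, dual regression,
voxel-wise t maps, nested t0 selection, kernel PCA, Fisher LDA, and
majority voting.  The held-out label never touches any fitted parameter.
"""

from icalearn import (
    ClassifierConfig,
    ComponentTemplate,
    PipelineConfig,
    SiteParams,
    SyntheticConfig,
    VolumeGrid,
    group_ica,
    loo_cross_validate,
    simulate_cohort,
)

cfg = SyntheticConfig(
    n_per_group_per_site={"main": (15, 15)},
    T_per_site={"main": 40},
    K_true=4,
    grid=VolumeGrid.full((8, 8, 4)),
    effect_size=1.5,
    n_affected=2,
    site_params={"main": SiteParams(noise_sd=0.5)},
    seed=11,
)
scans, _ = simulate_cohort(cfg)

pipe = PipelineConfig(
    n_sub_pc=10, K=4,
    classifier=ClassifierConfig(d=4, t0_percentiles=(50, 60, 70, 80, 90, 95)),
)
dec = group_ica(scans, n_sub_pc=10, K=4, seed=0)
template = ComponentTemplate(dec.spatial_maps, tuple(range(4)))

report = loo_cross_validate(scans, template, pipe)
acc, sens, spec = report.ensemble
print(f"LOO ensemble: accuracy={acc:.3f} sensitivity={sens:.3f} specificity={spec:.3f}")
print("per-component accuracy:", report.per_component[:, 0].round(3))
print(
    "\nComponents carrying the planted effect classify well; unaffected"
    "\ncomponents hover near chance, and majority voting combines them."
)
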