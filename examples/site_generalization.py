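"""Direct versus transfer external validation across a scanner change.

A second site acquires the same kind of cohort with a gain change, more
noise and a small spatial displacement.  Direct validation applies the
training-site template unchanged; transfer validation re-estimates the
unsupervised group ICA over both sites' unlabeled scans before refitting
the supervised stages on training labels only.
"""

from icalearn import (
    ClassifierConfig,
    ComponentTemplate,
    PipelineConfig,
    SiteParams,
    SyntheticConfig,
    VolumeGrid,
    external_validate_direct,
    external_validate_transfer,
    group_ica,
    simulate_cohort,
)

cfg = SyntheticConfig(
    n_per_group_per_site={"main": (8, 8), "validated": (8, 8)},
    T_per_site={"main": 40, "validated": 36},
    K_true=4,
    grid=VolumeGrid.full((8, 8, 4)),
    effect_size=1.2,
    n_affected=2,
    site_params={
        "main": SiteParams(noise_sd=0.5),
        "validated": SiteParams(gain=1.3, noise_sd=0.75, displacement=(2, 0, 0)),
    },
    seed=3,
)
scans, _ = simulate_cohort(cfg)
train = [s for s in scans if s.site == "main"]
test = [s for s in scans if s.site == "validated"]

pipe = PipelineConfig(
    n_sub_pc=10, K=4,
    classifier=ClassifierConfig(d=4, t0_percentiles=(50, 60, 70, 80, 90, 95)),
)
dec = group_ica(train, n_sub_pc=10, K=4, seed=0)
template = ComponentTemplate(dec.spatial_maps, tuple(range(4)))

direct, _ = external_validate_direct(train, test, template, pipe)
transfer, _ = external_validate_transfer(train, test, template, pipe)
print(f"direct   external accuracy: {direct.ensemble[0]:.3f}")
print(f"transfer external accuracy: {transfer.ensemble[0]:.3f}")
print(
    "\nSite effects break the frozen template (accuracy falls toward"
    "\nchance); re-estimating the unsupervised decomposition over both"
    "\nsites restores much of the within-site performance without ever"
    "\nusing a test label."
)
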