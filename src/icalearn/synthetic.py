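"""Synthetic multi-site labeled cohorts with known spatial components.

The generator emulates the data model that group ICA assumes: each
subject's scan is a linear mixture of shared spatial component maps with
subject-specific super-Gaussian time courses, plus Gaussian sensor noise.
A diagnosis effect is planted by scaling the loading of a subset of
components for the patient (SZ) group; site effects are a multiplicative
gain, a different noise level, and an integer-voxel displacement of the
component maps.  The returned :class:`TruthRecord` carries the planted
ground truth for test oracles only — no pipeline stage consumes it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import SubjectScan, VolumeGrid

DEFAULT_GRID_SHAPE = (12, 12, 8)
#: Retained volumes per site: 200 and 180 acquired minus 5 dummy volumes.
DEFAULT_T = {"main": 195, "validated": 175}


@dataclass(frozen=True)
class SiteParams:
    """Site-specific acquisition effects."""

    gain: float = 1.0
    noise_sd: float = 1.0
    displacement: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class TruthRecord:
    """Planted ground truth of a synthetic cohort (for test oracles only)."""

    grid: VolumeGrid
    component_maps: np.ndarray  # K_true x V, unit-norm rows
    affected_components: tuple[int, ...]
    effect_size: float
    site_params: dict[str, SiteParams]
    subject_loadings: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        K = self.component_maps.shape[0]
        if not all(0 <= c < K for c in self.affected_components):
            raise ValueError("affected_components out of range")

    def site_maps(self, site: str) -> np.ndarray:
        """Truth maps displaced by the site's voxel offset (periodic shift)."""
        disp = self.site_params[site].displacement
        if not any(disp):
            return self.component_maps
        vols = self.grid.unmask(self.component_maps)
        vols = np.roll(vols, disp, axis=(-3, -2, -1))
        return self.grid.apply_mask(vols)


@dataclass
class SyntheticConfig:
    """Configuration of a two-site synthetic cohort.

    ``n_per_group_per_site`` maps site -> (n_HC, n_SZ).  ``T_per_site``
    defaults to 195 and 175 retained volumes for the main and validated
    sites.  A fixed ``seed`` makes the cohort byte-identical across runs.
    """

    n_per_group_per_site: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"main": (51, 51), "validated": (27, 34)}
    )
    K_true: int = 6
    grid: VolumeGrid | None = None
    T_per_site: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_T))
    effect_size: float = 1.0
    n_affected: int = 3
    site_params: dict[str, SiteParams] = field(default_factory=dict)
    loading_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.grid is None:
            self.grid = VolumeGrid.full(DEFAULT_GRID_SHAPE)
        for site, (n_hc, n_sz) in self.n_per_group_per_site.items():
            if n_hc < 0 or n_sz < 0:
                raise ValueError(f"negative subject count for site {site!r}")
            if site not in self.T_per_site:
                raise ValueError(f"no T given for site {site!r}")
            if (n_hc + n_sz) > 0 and self.T_per_site[site] < self.K_true:
                raise ValueError(
                    f"site {site!r}: T={self.T_per_site[site]} < K_true={self.K_true}"
                )
        if all(n_hc + n_sz == 0 for n_hc, n_sz in self.n_per_group_per_site.values()):
            raise ValueError("cohort has zero subjects in every cell")
        if not (0 <= self.n_affected <= self.K_true):
            raise ValueError("n_affected must be in [0, K_true]")
        for site in self.n_per_group_per_site:
            self.site_params.setdefault(site, SiteParams())


def generate_truth_maps(
    grid: VolumeGrid,
    K_true: int,
    seed: int,
    max_abs_corr: float = 0.3,
    max_resample: int = 200,
) -> np.ndarray:
    """Draw K_true spatially compact unit-norm component maps.

    Each map is a sum of one to three 3-D Gaussian bumps at random in-mask
    centers.  Components are resampled until every pairwise absolute
    Pearson correlation is below ``max_abs_corr``; if the grid cannot
    accommodate that many decorrelated blobs a ``ValueError`` is raised.
    """
    if K_true < 1:
        raise ValueError("K_true must be >= 1")
    rng = np.random.default_rng(seed)
    coords = grid.voxel_index.astype(float)  # V x 3
    centers_pool = coords

    def draw_map() -> np.ndarray:
        n_bumps = rng.integers(1, 4)
        m = np.zeros(grid.n_voxels)
        for _ in range(n_bumps):
            center = centers_pool[rng.integers(len(centers_pool))]
            sigma = rng.uniform(1.0, 2.5)
            d2 = ((coords - center) ** 2).sum(axis=1)
            m += np.exp(-d2 / (2.0 * sigma**2))
        return m / np.linalg.norm(m)

    maps: list[np.ndarray] = []
    attempts = 0
    while len(maps) < K_true:
        cand = draw_map()
        if all(_abs_corr(cand, m) < max_abs_corr for m in maps):
            maps.append(cand)
            attempts = 0
        else:
            attempts += 1
            if attempts > max_resample:
                raise ValueError(
                    f"cannot place {K_true} maps with pairwise |corr| < "
                    f"{max_abs_corr} on grid {grid.shape}"
                )
    return np.asarray(maps)


def _abs_corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return abs(float(a @ b) / denom)


def simulate_subject(
    truth: TruthRecord,
    group: str,
    site: str,
    T: int,
    seed: int,
    subject_id: str | None = None,
    loading_sd: float = 0.1,
) -> SubjectScan:
    """Simulate one subject as gain * (TC @ diag(loadings) @ M_site) + noise.

    Time courses are i.i.d. unit-variance Laplace (super-Gaussian, the
    regime Infomax with a logistic nonlinearity assumes).  Loadings are
    1 + N(0, loading_sd^2) per component; for SZ subjects the loadings of
    the affected components are multiplied by ``1 + effect_size``.
    """
    K = truth.component_maps.shape[0]
    if T < K:
        raise ValueError(f"T={T} < K_true={K}")
    params = truth.site_params[site]
    rng = np.random.default_rng(seed)
    loadings = 1.0 + loading_sd * rng.standard_normal(K)
    if group == "SZ":
        loadings = loadings.copy()
        loadings[list(truth.affected_components)] *= 1.0 + truth.effect_size
    # Laplace with scale 1/sqrt(2) has unit variance.
    tc = rng.laplace(0.0, 1.0 / np.sqrt(2.0), size=(T, K))
    maps = truth.site_maps(site)
    data = params.gain * (tc * loadings) @ maps
    if params.noise_sd > 0:
        data = data + params.noise_sd * rng.standard_normal(data.shape)
    sid = subject_id or f"{site}-{group}-{seed}"
    truth.subject_loadings[sid] = loadings
    return SubjectScan(subject_id=sid, group=group, site=site, data=data, grid=truth.grid)


def simulate_cohort(config: SyntheticConfig) -> tuple[list[SubjectScan], TruthRecord]:
    """Simulate the full two-site cohort described by ``config``.

    Returns the subject scans (HC then SZ within each site, sites in
    config order) and the :class:`TruthRecord`; the latter exists for
    test oracles and is never consumed by pipeline stages.
    """
    root = np.random.SeedSequence(config.seed)
    maps_seed, subjects_seed = root.spawn(2)
    maps = generate_truth_maps(
        config.grid, config.K_true, seed=maps_seed.generate_state(1)[0]
    )
    affected = tuple(range(config.n_affected))
    truth = TruthRecord(
        grid=config.grid,
        component_maps=maps,
        affected_components=affected,
        effect_size=config.effect_size,
        site_params=dict(config.site_params),
    )
    scans: list[SubjectScan] = []
    child_seeds = iter(
        s.generate_state(1)[0]
        for s in subjects_seed.spawn(
            sum(n_hc + n_sz for n_hc, n_sz in config.n_per_group_per_site.values())
        )
    )
    for site, (n_hc, n_sz) in config.n_per_group_per_site.items():
        T = config.T_per_site[site]
        for group, n in (("HC", n_hc), ("SZ", n_sz)):
            for i in range(n):
                scans.append(
                    simulate_subject(
                        truth,
                        group,
                        site,
                        T,
                        seed=next(child_seeds),
                        subject_id=f"{site}-{group}-{i:03d}",
                        loading_sd=config.loading_sd,
                    )
                )
    return scans, truth
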