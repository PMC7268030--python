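"""Greedy sequential matching of components to a spatial template.

A new decomposition's components are put in correspondence with a
reference template by repeatedly picking the (template, candidate) pair
with the globally largest absolute spatial correlation among the still
unmatched rows and columns.  The sign of the matched correlation is
recorded so candidate maps can be sign-aligned to the template.  Ties in
|corr| are broken by lower template index, then lower candidate index,
making the output unique.  A globally optimal (Hungarian) assignment is
available for diagnostics only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment


@dataclass
class ComponentTemplate:
    """Selected reference spatial maps (K_sel x V) with their original ids."""

    maps: np.ndarray
    selected_indices: tuple[int, ...]
    provenance: str = ""

    def __post_init__(self):
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2 or self.maps.shape[0] < 1:
            raise ValueError("template needs at least one map")
        if len(set(self.selected_indices)) != len(self.selected_indices):
            raise ValueError("selected_indices must be distinct")
        if len(self.selected_indices) != self.maps.shape[0]:
            raise ValueError("selected_indices length must equal number of maps")
        if not np.isfinite(self.maps).all():
            raise ValueError("non-finite template maps")

    @property
    def n_components(self) -> int:
        return self.maps.shape[0]


@dataclass
class MatchResult:
    """Outcome of matching candidates to a template."""

    assignment: np.ndarray  # template index -> candidate index
    signs: np.ndarray  # +-1 per matched pair
    correlations: np.ndarray  # matched absolute correlations
    report: np.ndarray  # full K_sel x K_cand signed correlation table
    warn_threshold: float = 0.4
    warnings: list[str] = field(default_factory=list)

    def aligned_candidates(self, candidates: np.ndarray) -> np.ndarray:
        """Matched candidate maps, sign-aligned to the template, template order."""
        return self.signs[:, None] * np.asarray(candidates)[self.assignment]


def correlation_table(candidates: np.ndarray, template_maps: np.ndarray) -> np.ndarray:
    """Signed Pearson correlations, template rows x candidate columns."""
    t = np.asarray(template_maps, dtype=float)
    c = np.asarray(candidates, dtype=float)
    tz = t - t.mean(axis=1, keepdims=True)
    cz = c - c.mean(axis=1, keepdims=True)
    tn = np.linalg.norm(tz, axis=1)
    cn = np.linalg.norm(cz, axis=1)
    if np.any(tn == 0) or np.any(cn == 0):
        raise ValueError("zero-variance map encountered in correlation table")
    return (tz @ cz.T) / np.outer(tn, cn)


def match_components(
    candidates: np.ndarray,
    template: ComponentTemplate,
    warn_threshold: float = 0.4,
) -> MatchResult:
    """Sequentially match candidate maps to the template by max |corr|."""
    candidates = np.asarray(candidates, dtype=float)
    K_sel = template.n_components
    K_cand = candidates.shape[0]
    if K_cand < K_sel:
        raise ValueError(f"need >= {K_sel} candidates, got {K_cand}")
    table = correlation_table(candidates, template.maps)
    abs_table = np.abs(table)
    assignment = np.full(K_sel, -1, dtype=int)
    signs = np.zeros(K_sel)
    corrs = np.zeros(K_sel)
    free_t = np.ones(K_sel, dtype=bool)
    free_c = np.ones(K_cand, dtype=bool)
    for _ in range(K_sel):
        masked = np.where(np.outer(free_t, free_c), abs_table, -1.0)
        # argmax scans row-major, so ties fall to lower template then
        # lower candidate index automatically.
        ti, ci = np.unravel_index(np.argmax(masked), masked.shape)
        assignment[ti] = ci
        corrs[ti] = abs_table[ti, ci]
        signs[ti] = 1.0 if table[ti, ci] >= 0 else -1.0
        free_t[ti] = False
        free_c[ci] = False
    warnings_list = [
        f"template component {template.selected_indices[i]}: matched |corr| "
        f"{corrs[i]:.3f} below {warn_threshold}"
        for i in range(K_sel)
        if corrs[i] < warn_threshold
    ]
    return MatchResult(
        assignment=assignment,
        signs=signs,
        correlations=corrs,
        report=table,
        warn_threshold=warn_threshold,
        warnings=warnings_list,
    )


def optimal_assignment(table: np.ndarray) -> np.ndarray:
    """Globally optimal assignment maximizing total |corr| (diagnostics only)."""
    rows, cols = linear_sum_assignment(-np.abs(table))
    out = np.full(table.shape[0], -1, dtype=int)
    out[rows] = cols
    return out


def screening_report(maps: np.ndarray, z_threshold: float = 2.0) -> list[dict]:
    """Automated per-component screening summary.

    Replaces a visual quality check: reports spatial skewness, excess
    kurtosis and the fraction of suprathreshold voxels after z-scoring.
    Compact, focal networks show high kurtosis and a small active
    fraction; low, widespread activation shows the opposite.
    """
    from scipy import stats

    maps = np.asarray(maps, dtype=float)
    out = []
    for i, m in enumerate(maps):
        z = (m - m.mean()) / (m.std() if m.std() else 1.0)
        out.append(
            {
                "component": i,
                "skewness": float(stats.skew(m)),
                "kurtosis": float(stats.kurtosis(m)),
                "active_fraction": float(np.mean(np.abs(z) > z_threshold)),
            }
        )
    return out
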