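"""Spatial-temporal reconstruction (dual regression) of subject maps.

Two least-squares stages recover subject-specific versions of a set of
group spatial maps: stage 1 regresses each time point's voxel pattern on
the group maps to obtain subject time courses; stage 2 regresses each
voxel's time series on the variance-normalized time courses to obtain
subject spatial maps.  Both stages include an intercept, so constant
offsets in the data are absorbed.  Variance-normalizing the time courses
before stage 2 makes subject map amplitudes carry the component's
temporal standard deviation, which is what the downstream group
comparison discriminates on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import SubjectScan


@dataclass
class SubjectComponentMaps:
    """Per-subject spatial maps and time courses for K components."""

    subject_id: str
    maps: np.ndarray  # K x V
    time_courses: np.ndarray  # T x K
    source_decomposition_id: str = ""

    def __post_init__(self):
        if not (np.isfinite(self.maps).all() and np.isfinite(self.time_courses).all()):
            raise ValueError(f"non-finite dual-regression output for {self.subject_id!r}")
        if self.maps.shape[0] != self.time_courses.shape[1]:
            raise ValueError("maps / time_courses component count mismatch")


class SingularDesignError(ValueError):
    """Group maps are (numerically) linearly dependent."""


def _check_design(group_maps: np.ndarray) -> None:
    K = group_maps.shape[0]
    sd = group_maps.std(axis=1)
    degenerate = np.flatnonzero(sd == 0)
    if degenerate.size:
        raise SingularDesignError(
            f"zero-variance group map(s) at index {degenerate.tolist()}"
        )
    if np.linalg.matrix_rank(group_maps) < K:
        C = np.corrcoef(group_maps)
        pairs = [
            (i, j)
            for i in range(K)
            for j in range(i + 1, K)
            if abs(C[i, j]) > 1.0 - 1e-10
        ]
        raise SingularDesignError(
            f"rank-deficient group maps; near-duplicate component pairs: {pairs}"
        )


def dual_regress(
    scan: SubjectScan, group_maps: np.ndarray, decomposition_id: str = ""
) -> SubjectComponentMaps:
    """Recover subject time courses and spatial maps from group maps."""
    M = np.asarray(group_maps, dtype=float)
    _check_design(M)
    X = scan.data  # T x V
    T, V = X.shape
    K = M.shape[0]
    # Stage 1: X[t, :] ~ intercept + M rows  -> time courses.
    D1 = np.column_stack([np.ones(V), M.T])  # V x (1+K)
    beta1, *_ = np.linalg.lstsq(D1, X.T, rcond=None)  # (1+K) x T
    tc = beta1[1:].T  # T x K
    # Stage 2: X[:, v] ~ intercept + variance-normalized time courses.
    sd = tc.std(axis=0, ddof=0)
    if np.any(sd == 0):
        dead = np.flatnonzero(sd == 0).tolist()
        raise SingularDesignError(f"zero-variance time course(s) for component(s) {dead}")
    D2 = np.column_stack([np.ones(T), tc / sd])  # T x (1+K)
    beta2, *_ = np.linalg.lstsq(D2, X, rcond=None)  # (1+K) x V
    maps = beta2[1:]  # K x V
    return SubjectComponentMaps(
        subject_id=scan.subject_id,
        maps=maps,
        time_courses=tc,
        source_decomposition_id=decomposition_id,
    )
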