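"""Two-stage PCA reduction and Infomax ICA for group spatial components.

Multi-subject decomposition follows the temporal-concatenation convention:
each subject's scan is reduced to its top temporal principal modes, the
reduced data are stacked across subjects, reduced again at the group
level, and unmixed with Infomax ICA (natural-gradient updates through a
logistic nonlinearity, which assumes super-Gaussian sources).  Component
sign is fixed by non-negative spatial skewness and each spatial map is
scaled to unit variance, removing the usual ICA scale/sign ambiguity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .grid import SubjectScan


@dataclass
class ICAResult:
    """Unmixing estimate from :func:`infomax_ica`."""

    unmixing: np.ndarray  # K x K, acts on whitened data
    sources: np.ndarray  # K x V, unit-variance rows, skew-positive
    whitening: np.ndarray  # K x P
    converged: bool
    n_iter: int


@dataclass
class GroupDecomposition:
    """Group spatial maps plus every transform that produced them."""

    spatial_maps: np.ndarray  # K x V
    subject_reducers: dict[str, np.ndarray]  # subject_id -> n_sub_pc x T projector
    group_reducer: np.ndarray  # K_group x stacked-P projector
    unmixing: np.ndarray  # K x K (on whitened group data)
    whitening: np.ndarray
    K: int
    training_subject_ids: list[str] = field(default_factory=list)
    converged: bool = True

    def __post_init__(self):
        if not np.isfinite(self.spatial_maps).all():
            raise ValueError("non-finite spatial maps")


def subject_pca(data: np.ndarray, n_pc: int) -> tuple[np.ndarray, float, np.ndarray]:
    """Reduce a T x V scan to its top ``n_pc`` temporal principal modes.

    Data are mean-centered per voxel over time; the eigenvectors of the
    T x T covariance define the temporal modes and the reduced rows are
    those modes applied to the centered data.  Returns the n_pc x V
    reduced matrix, the retained-variance fraction, and the n_pc x T
    projector (rows = temporal eigenvectors).
    """
    X = np.asarray(data, dtype=float)
    T = X.shape[0]
    if n_pc > min(X.shape):
        raise ValueError(f"n_pc={n_pc} exceeds min(T, V)={min(X.shape)}")
    Xc = X - X.mean(axis=0, keepdims=True)
    cov = Xc @ Xc.T
    evals, evecs = linalg.eigh(cov)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    total = evals.sum()
    if total <= 0:
        raise ValueError("zero-variance data (degenerate input)")
    # Mean centering removes one temporal mode, so allow rank + 1 == T.
    effective_rank = int(np.sum(evals > total * 1e-12))
    if n_pc > effective_rank + 1 or (n_pc > effective_rank and n_pc < T):
        raise ValueError(f"data rank {effective_rank} below n_pc={n_pc} (degenerate input)")
    # Deterministic sign: largest-magnitude entry of each mode positive.
    for j in range(n_pc):
        k = np.argmax(np.abs(evecs[:, j]))
        if evecs[k, j] < 0:
            evecs[:, j] = -evecs[:, j]
    projector = evecs[:, :n_pc].T  # n_pc x T
    reduced = projector @ Xc
    retained = float(evals[:n_pc].sum() / total)
    return reduced, retained, projector


def _whiten(X: np.ndarray, K: int) -> tuple[np.ndarray, np.ndarray]:
    """Whiten P x V data to K dimensions; returns (Z, whitening K x P)."""
    Xc = X - X.mean(axis=1, keepdims=True)
    cov = Xc @ Xc.T / X.shape[1]
    evals, evecs = linalg.eigh(cov)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    if evals[K - 1] <= 0 or evals[K - 1] / evals[0] < 1e-14:
        raise ValueError("singular whitening: data rank below K")
    wh = (evecs[:, :K] / np.sqrt(evals[:K])).T
    return wh @ Xc, wh


def infomax_ica(
    X: np.ndarray,
    K: int,
    seed: int = 0,
    learning_rate: float = 1e-3,
    max_iter: int = 1000,
    tol: float = 1e-6,
    anneal: float = 0.98,
    anneal_deg: float = 60.0,
) -> ICAResult:
    """Infomax ICA with natural-gradient block updates.

    ``X`` (P x V) is whitened to K dimensions, then the K x K unmixing
    matrix is learned by stochastic block updates of the natural-gradient
    Infomax rule with a logistic nonlinearity, annealing the learning
    rate when the update direction oscillates (angle > ``anneal_deg``).
    Stops when the squared per-pass weight change drops below ``tol``;
    hitting ``max_iter`` first is recorded as ``converged=False`` (a
    warning state, not an error).  Source rows are scaled to unit
    variance with sign chosen so spatial skewness is non-negative.
    """
    X = np.asarray(X, dtype=float)
    P, V = X.shape
    if K > P:
        raise ValueError(f"K={K} > P={P}")
    Z, wh = _whiten(X, K)
    rng = np.random.default_rng(seed)
    W = np.eye(K)
    block = max(K + 1, int(np.floor(np.sqrt(V / 3.0))))
    lr = learning_rate
    old_delta = None
    converged = False
    n_iter = 0
    BI = block * np.eye(K)
    for it in range(max_iter):
        n_iter = it + 1
        W_old = W.copy()
        perm = rng.permutation(V)
        blowup = False
        for start in range(0, V - block + 1, block):
            u = W @ Z[:, perm[start : start + block]]
            y = 1.0 / (1.0 + np.exp(-u))
            W = W + lr * ((BI + (1.0 - 2.0 * y) @ u.T) @ W)
            if np.max(np.abs(W)) > 1e8:
                blowup = True
                break
        if blowup:
            lr *= 0.5
            W = np.eye(K)
            old_delta = None
            continue
        delta = W - W_old
        wchange = float((delta**2).sum())
        if old_delta is not None:
            denom = np.linalg.norm(delta) * np.linalg.norm(old_delta)
            if denom > 0:
                cosang = float((delta * old_delta).sum() / denom)
                if np.degrees(np.arccos(np.clip(cosang, -1, 1))) > anneal_deg:
                    lr *= anneal
        old_delta = delta
        if wchange < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"Infomax did not converge within {max_iter} passes", RuntimeWarning
        )
    sources = W @ Z
    sd = sources.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    sources = sources / sd[:, None]
    flip = np.where(stats.skew(sources, axis=1) < 0, -1.0, 1.0)
    sources = sources * flip[:, None]
    W = (flip / sd)[:, None] * W
    return ICAResult(unmixing=W, sources=sources, whitening=wh, converged=converged, n_iter=n_iter)


def group_ica(
    scans: list[SubjectScan],
    n_sub_pc: int = 40,
    K: int = 30,
    seed: int = 0,
    **ica_kwargs,
) -> GroupDecomposition:
    """Temporal-concatenation group ICA.

    Per-subject PCA to ``n_sub_pc`` temporal modes, stacking across
    subjects, group PCA to ``K``, then Infomax ICA.  Defaults (40
    subject-level components, 30 group components) follow the GIFT
    convention for resting-state decompositions.
    """
    if not scans:
        raise ValueError("no scans given")
    grid = scans[0].grid
    for s in scans:
        if s.grid != grid:
            raise ValueError(f"subject {s.subject_id!r} is on a different grid")
        if s.n_timepoints < n_sub_pc:
            raise ValueError(
                f"subject {s.subject_id!r} has T={s.n_timepoints} < n_sub_pc={n_sub_pc}"
            )
    if K > n_sub_pc:
        raise ValueError(f"K={K} > n_sub_pc={n_sub_pc}")
    reducers: dict[str, np.ndarray] = {}
    stacked = []
    for s in scans:
        reduced, _, projector = subject_pca(s.data, n_sub_pc)
        reducers[s.subject_id] = projector
        stacked.append(reduced)
    stacked = np.vstack(stacked)  # (n_subjects * n_sub_pc) x V
    if len(scans) == 1:
        group_reduced, group_projector = stacked, np.eye(n_sub_pc)
    else:
        group_reduced, _, group_projector = subject_pca(stacked, min(K, stacked.shape[0]))
    res = infomax_ica(group_reduced, K, seed=seed, **ica_kwargs)
    return GroupDecomposition(
        spatial_maps=res.sources,
        subject_reducers=reducers,
        group_reducer=group_projector,
        unmixing=res.unmixing,
        whitening=res.whitening,
        K=K,
        training_subject_ids=[s.subject_id for s in scans],
        converged=res.converged,
    )
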