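"""Per-component classifiers and their majority-vote ensemble.

For each resting-state component, training subjects' spatial maps go
through four supervised stages: (1) a voxel-wise pooled two-sample t test
(SZ minus HC); (2) selection of a t threshold t0 that keeps only voxels
with |t| > t0, where t0 is chosen from a percentile grid of |t| to
maximize the Fisher separation of the final discriminant on the training
data; (3) kernel PCA of the thresholded feature vectors; (4) a
ridge-stabilized Fisher linear discriminant on the kernel scores.  The
per-component (label, score) predictions are combined by majority voting
with a normalized score-sum tie-break.

Test subjects never influence any fitted parameter: t maps, t0, the
kernel PCA basis and the discriminant are functions of training maps and
training labels alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

POSITIVE_CLASS = "SZ"  # sensitivity refers to SZ, specificity to HC
NEGATIVE_CLASS = "HC"


@dataclass
class ClassifierConfig:
    """Hyperparameters of the per-component stage.

    kernel: "rbf" (bandwidth = median pairwise training distance) or
    "linear".  d: retained kernel-PCA dimensions.  t0 candidates are the
    ``t0_percentiles`` of |t| over voxels.  ``two_sided=False`` thresholds
    signed t > t0 instead of |t| > t0.
    """

    kernel: str = "rbf"
    d: int = 10
    t0_percentiles: tuple[float, ...] = tuple(range(50, 100))
    two_sided: bool = True
    ridge: float = 1e-6

    def __post_init__(self):
        if self.kernel not in ("rbf", "linear"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.d < 1:
            raise ValueError("d must be >= 1")
        if not self.t0_percentiles:
            raise ValueError("empty t0 percentile grid")


def _label_masks(labels) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    sz = labels == POSITIVE_CLASS
    hc = labels == NEGATIVE_CLASS
    if sz.sum() + hc.sum() != labels.size:
        bad = sorted(set(labels) - {POSITIVE_CLASS, NEGATIVE_CLASS})
        raise ValueError(f"unknown labels {bad}")
    return sz, hc


def voxel_t_map(train_maps: np.ndarray, labels) -> tuple[np.ndarray, np.ndarray]:
    """Pooled-variance two-sample t per voxel (SZ minus HC).

    Returns the t map and a boolean mask of zero-variance voxels, whose
    t is set to 0.
    """
    X = np.asarray(train_maps, dtype=float)
    sz, hc = _label_masks(labels)
    n1, n2 = int(sz.sum()), int(hc.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need >= 2 subjects per class, got SZ={n1}, HC={n2}")
    m1, m2 = X[sz].mean(axis=0), X[hc].mean(axis=0)
    v1 = X[sz].var(axis=0, ddof=1)
    v2 = X[hc].var(axis=0, ddof=1)
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    zero_var = pooled == 0
    se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    t = np.zeros(X.shape[1])
    np.divide(m1 - m2, se, out=t, where=~zero_var)
    return t, zero_var


def threshold_features(
    subject_map: np.ndarray, t_map: np.ndarray, t0: float, two_sided: bool = True
) -> np.ndarray:
    """Keep voxels with |t| > t0 (or t > t0 if one-sided), fixed voxel order."""
    if t0 < 0:
        raise ValueError("t0 must be >= 0")
    stat = np.abs(t_map) if two_sided else t_map
    keep = stat > t0
    if not keep.any():
        raise ValueError(f"no voxels survive t0={t0} (model unusable at this threshold)")
    return np.asarray(subject_map)[..., keep]


def feature_voxels(t_map: np.ndarray, t0: float, two_sided: bool = True) -> np.ndarray:
    """Indices of voxels surviving the threshold."""
    stat = np.abs(t_map) if two_sided else t_map
    return np.flatnonzero(stat > t0)


def _kernel_matrix(kernel: str, gamma: float | None, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    if kernel == "linear":
        return A @ B.T
    sq = (
        (A**2).sum(axis=1)[:, None]
        + (B**2).sum(axis=1)[None, :]
        - 2.0 * (A @ B.T)
    )
    np.maximum(sq, 0.0, out=sq)
    return np.exp(-gamma * sq)


@dataclass
class KPCAModel:
    """Fitted kernel PCA with out-of-sample projection.

    The training kernel matrix is double-centered in feature space and
    eigendecomposed; projections are ``K_c @ alphas`` with eigenvectors
    scaled by 1/sqrt(eigenvalue), so in-sample scores have variance
    eigenvalue/N.  New points are centered with the stored training
    row/total kernel means.
    """

    kernel: str
    d: int
    gamma: float | None
    X_fit: np.ndarray = field(repr=False)  # N x F training features
    alphas: np.ndarray = field(repr=False)  # N x d
    eigenvalues: np.ndarray = field(repr=False)  # d, non-increasing
    train_col_means: np.ndarray = field(repr=False)  # N
    total_mean: float = 0.0

    def project(self, features: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(features, dtype=float))
        k = _kernel_matrix(self.kernel, self.gamma, X, self.X_fit)  # M x N
        kc = (
            k
            - k.mean(axis=1, keepdims=True)
            - self.train_col_means[None, :]
            + self.total_mean
        )
        out = kc @ self.alphas
        return out[0] if out.shape[0] == 1 else out


def fit_kpca(
    train_features: np.ndarray,
    kernel: str = "rbf",
    d: int = 10,
    gamma: float | None = None,
) -> KPCAModel:
    """Eigendecompose the double-centered training kernel matrix.

    For the RBF kernel the default bandwidth is the median pairwise
    Euclidean distance among training points (gamma = 1 / (2 h^2)).
    ``d`` must not exceed N - 1 nor the rank of the centered kernel.
    """
    X = np.asarray(train_features, dtype=float)
    N = X.shape[0]
    if d > N - 1:
        raise ValueError(f"d={d} exceeds N-1={N - 1}")
    if kernel == "rbf" and gamma is None:
        from scipy.spatial.distance import pdist

        h = float(np.median(pdist(X)))
        if h == 0:
            h = 1.0
        gamma = 1.0 / (2.0 * h**2)
    K = _kernel_matrix(kernel, gamma, X, X)
    col_means = K.mean(axis=0)
    total = float(K.mean())
    Kc = K - col_means[None, :] - col_means[:, None] + total
    evals, evecs = np.linalg.eigh(Kc)
    evals, evecs = evals[::-1][:d].copy(), evecs[:, ::-1][:, :d].copy()
    if evals.size < d or evals[d - 1] <= max(evals[0], 1.0) * 1e-12:
        raise ValueError(f"centered kernel rank below d={d}")
    # Deterministic sign: largest-|entry| coefficient positive.
    for j in range(d):
        i = np.argmax(np.abs(evecs[:, j]))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    alphas = evecs / np.sqrt(evals)[None, :]
    return KPCAModel(
        kernel=kernel,
        d=d,
        gamma=gamma,
        X_fit=X.copy(),
        alphas=alphas,
        eigenvalues=evals,
        train_col_means=col_means,
        total_mean=total,
    )


@dataclass
class FLDModel:
    """Ridge-stabilized Fisher linear discriminant in kernel-score space."""

    direction: np.ndarray
    threshold: float
    degenerate: bool = False

    def score(self, projection: np.ndarray) -> float:
        return float(np.asarray(projection).ravel() @ self.direction - self.threshold)

    def predict(self, projection: np.ndarray) -> tuple[str, float]:
        s = self.score(projection)
        return (POSITIVE_CLASS if s > 0 else NEGATIVE_CLASS), s


def fit_fld(train_projections: np.ndarray, labels, ridge: float = 1e-6) -> FLDModel:
    """direction = (Sigma_w + lambda I)^-1 (mu_SZ - mu_HC); midpoint threshold."""
    X = np.atleast_2d(np.asarray(train_projections, dtype=float))
    sz, hc = _label_masks(labels)
    if not (sz.any() and hc.any()):
        raise ValueError("both classes must be present")
    mu1, mu2 = X[sz].mean(axis=0), X[hc].mean(axis=0)
    Sw = np.zeros((X.shape[1], X.shape[1]))
    for mask, mu in ((sz, mu1), (hc, mu2)):
        R = X[mask] - mu
        Sw += R.T @ R
    lam = ridge * (np.trace(Sw) / Sw.shape[0] if np.trace(Sw) > 0 else 1.0)
    diff = mu1 - mu2
    if np.allclose(X, X[0]):
        warnings.warn("all projections identical; chance-level discriminant", RuntimeWarning)
        return FLDModel(direction=np.zeros(X.shape[1]), threshold=0.0, degenerate=True)
    w = np.linalg.solve(Sw + lam * np.eye(Sw.shape[0]), diff)
    thr = float(w @ (mu1 + mu2) / 2.0)
    return FLDModel(direction=w, threshold=thr)


def fisher_separation(scores_1d: np.ndarray, labels) -> float:
    """Fisher ratio J = (m1 - m2)^2 / (s1^2 + s2^2) of 1-D projections."""
    s = np.asarray(scores_1d, dtype=float)
    sz, hc = _label_masks(labels)
    m1, m2 = s[sz].mean(), s[hc].mean()
    v = s[sz].var(ddof=1) + s[hc].var(ddof=1)
    if v == 0:
        return np.inf if m1 != m2 else 0.0
    return float((m1 - m2) ** 2 / v)


def select_threshold(
    train_maps: np.ndarray,
    labels,
    config: ClassifierConfig | None = None,
    t_map: np.ndarray | None = None,
) -> tuple[float, list[tuple[float, float]]]:
    """Pick t0 maximizing training Fisher separation of the final FLD.

    Candidates are percentiles of |t| (the map is recomputed here if not
    supplied).  For each feasible candidate the full threshold -> kPCA ->
    FLD chain is fit on the training data and the Fisher ratio J of the
    1-D training scores is recorded; the argmax wins, ties going to the
    smaller t0.  Returns (t0, trace of (t0, J)).
    """
    config = config or ClassifierConfig()
    if t_map is None:
        t_map, _ = voxel_t_map(train_maps, labels)
    stat = np.abs(t_map) if config.two_sided else t_map
    candidates = sorted(set(float(np.percentile(stat, p)) for p in config.t0_percentiles))
    X = np.asarray(train_maps, dtype=float)
    N = X.shape[0]
    d = min(config.d, N - 1)
    trace: list[tuple[float, float]] = []
    best: tuple[float, float] | None = None
    for t0 in candidates:
        keep = feature_voxels(t_map, t0, config.two_sided)
        if keep.size < d + 1:
            continue
        feats = X[:, keep]
        try:
            kp = fit_kpca(feats, kernel=config.kernel, d=d)
        except ValueError:
            continue
        proj = kp.project(feats)
        fld = fit_fld(proj, labels, ridge=config.ridge)
        scores = proj @ fld.direction
        J = fisher_separation(scores, labels)
        trace.append((t0, J))
        if best is None or J > best[1]:
            best = (t0, J)
    if best is None:
        raise ValueError("no feasible t0 candidate (grid empty after constraints)")
    return best[0], trace


@dataclass
class ComponentClassifier:
    """Trained supervised stage for one matched component."""

    component_id: int
    t_map: np.ndarray
    zero_variance_voxels: np.ndarray
    t0: float
    feature_voxel_idx: np.ndarray
    kpca: KPCAModel
    fld: FLDModel
    score_sd: float  # sd of training scores, used to normalize tie-breaks
    two_sided: bool = True
    positive_class: str = POSITIVE_CLASS
    maps_row: int = 0  # row of the K_sel x N x V training array this came from

    def predict(self, subject_map: np.ndarray) -> tuple[str, float]:
        feats = np.asarray(subject_map)[self.feature_voxel_idx]
        proj = self.kpca.project(feats)
        return self.fld.predict(proj)


def train_component_classifier(
    train_maps: np.ndarray,
    labels,
    component_id: int = 0,
    config: ClassifierConfig | None = None,
) -> ComponentClassifier:
    """Fit t map, t0, kernel PCA and FLD for one component."""
    config = config or ClassifierConfig()
    X = np.asarray(train_maps, dtype=float)
    t_map, zero_var = voxel_t_map(X, labels)
    t0, _ = select_threshold(X, labels, config=config, t_map=t_map)
    keep = feature_voxels(t_map, t0, config.two_sided)
    d = min(config.d, X.shape[0] - 1)
    kp = fit_kpca(X[:, keep], kernel=config.kernel, d=d)
    proj = kp.project(X[:, keep])
    fld = fit_fld(proj, labels, ridge=config.ridge)
    scores = proj @ fld.direction - fld.threshold
    sd = float(scores.std(ddof=0))
    return ComponentClassifier(
        component_id=component_id,
        t_map=t_map,
        zero_variance_voxels=zero_var,
        t0=t0,
        feature_voxel_idx=keep,
        kpca=kp,
        fld=fld,
        score_sd=sd if sd > 0 else 1.0,
        two_sided=config.two_sided,
    )


@dataclass
class EnsembleModel:
    """One classifier per selected component, combined by majority vote."""

    classifiers: list[ComponentClassifier]
    excluded_components: list[int] = field(default_factory=list)

    def __post_init__(self):
        if not self.classifiers:
            raise ValueError("ensemble needs at least one component classifier")
        ids = [c.component_id for c in self.classifiers]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate component ids in ensemble")

    @property
    def component_ids(self) -> list[int]:
        return [c.component_id for c in self.classifiers]


@dataclass
class Prediction:
    """Per-component votes and the majority decision for one subject."""

    subject_id: str
    votes: list[str]
    scores: list[float]
    final: str


def majority_vote(votes: list[str], scores: list[float], score_sds: list[float]) -> str:
    """Majority label; ties broken by the sum of sd-normalized scores.

    A positive normalized score sum resolves a tie to SZ; an exact zero
    resolves to HC.
    """
    if not votes:
        raise ValueError("no component predictions")
    n_sz = sum(v == POSITIVE_CLASS for v in votes)
    n_hc = len(votes) - n_sz
    if n_sz > n_hc:
        return POSITIVE_CLASS
    if n_hc > n_sz:
        return NEGATIVE_CLASS
    total = sum(s / sd for s, sd in zip(scores, score_sds))
    return POSITIVE_CLASS if total > 0 else NEGATIVE_CLASS


def train_ensemble(
    subject_maps: np.ndarray,
    labels,
    config: ClassifierConfig | None = None,
    component_ids: list[int] | None = None,
) -> EnsembleModel:
    """Train one classifier per component.

    ``subject_maps`` is K_sel x N x V (component, subject, voxel); all
    components share the same subjects and labels.  A component whose fit
    fails is excluded with a warning rather than aborting the ensemble.
    """
    maps = np.asarray(subject_maps, dtype=float)
    if maps.ndim != 3:
        raise ValueError("subject_maps must be K_sel x N x V")
    labels = np.asarray(labels)
    sz, hc = _label_masks(labels)
    if not (sz.any() and hc.any()):
        raise ValueError("training labels contain a single class")
    ids = component_ids if component_ids is not None else list(range(maps.shape[0]))
    classifiers, excluded = [], []
    for row, (cid, comp_maps) in enumerate(zip(ids, maps)):
        try:
            clf = train_component_classifier(comp_maps, labels, component_id=cid, config=config)
            clf.maps_row = row
            classifiers.append(clf)
        except ValueError as exc:
            warnings.warn(f"component {cid} excluded from ensemble: {exc}", RuntimeWarning)
            excluded.append(cid)
    return EnsembleModel(classifiers=classifiers, excluded_components=excluded)


def predict_subject(
    ensemble: EnsembleModel, subject_maps: np.ndarray, subject_id: str = ""
) -> Prediction:
    """Predict one subject from their K_sel x V matched component maps."""
    maps = np.asarray(subject_maps, dtype=float)
    votes, scores, sds = [], [], []
    for clf in ensemble.classifiers:
        label, score = clf.predict(maps[clf.maps_row])
        votes.append(label)
        scores.append(score)
        sds.append(clf.score_sd)
    final = majority_vote(votes, scores, sds)
    return Prediction(subject_id=subject_id, votes=votes, scores=scores, final=final)
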