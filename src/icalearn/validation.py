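"""Validation settings: within-site LOO, direct and transfer external.

Three evaluation regimes for the component-ensemble classifier:

* **internal** — leave-one-out cross-validation in which *every* fitted
  quantity, including the group ICA decomposition, is recomputed from the
  training subjects of each split; the held-out subject contributes data
  to nothing but its own dual regression and prediction.
* **external_1 (direct)** — the template and all classifier parameters
  come from the training site alone; the second site's scans are dual
  regressed against the training-site template maps and scored by the
  frozen ensemble.
* **external_2 (transfer)** — an unsupervised joint group ICA is run over
  both sites' *unlabeled* scans, its components are greedily matched to
  the training-site template, and the supervised stages are refit on
  training labels only.  Test labels are used solely for scoring, which
  is enforced by stripping them before any fitting step.

Statistical significance of an observed accuracy is assessed by a label
permutation test with the add-one p-value formula.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import hashlib

import numpy as np

from .classifier import (
    ClassifierConfig,
    EnsembleModel,
    Prediction,
    predict_subject,
    train_ensemble,
)
from .dual_regression import dual_regress
from .grid import SubjectScan
from .ica import group_ica
from .matching import ComponentTemplate, match_components

POSITIVE = "SZ"
NEGATIVE = "HC"


@dataclass
class PipelineConfig:
    """Parameters shared by the validation drivers."""

    n_sub_pc: int = 40
    K: int = 30
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    ica_seed: int = 0
    match_warn_threshold: float = 0.4


@dataclass
class ValidationReport:
    """Per-component and ensemble performance for one validation setting."""

    setting: str  # internal | external_1 | external_2
    component_ids: list[int]
    subject_ids: list[str]
    true_labels: list[str]
    vote_matrix: np.ndarray  # subjects x components, "SZ"/"HC"/"" (missing)
    predictions: list[Prediction]

    @property
    def final_labels(self) -> list[str]:
        return [p.final for p in self.predictions]

    @property
    def ensemble(self) -> tuple[float, float, float]:
        return classification_rates(self.true_labels, self.final_labels)

    @property
    def per_component(self) -> np.ndarray:
        """K_sel x 3 array of (accuracy, sensitivity, specificity)."""
        out = np.full((len(self.component_ids), 3), np.nan)
        truth = np.asarray(self.true_labels)
        for j in range(len(self.component_ids)):
            votes = self.vote_matrix[:, j]
            present = votes != ""
            if present.any():
                out[j] = classification_rates(truth[present], votes[present])
        return out


def classification_rates(true_labels, predicted) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity); SZ is the positive class."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted)
    sz = t == POSITIVE
    hc = t == NEGATIVE
    acc = float(np.mean(p == t))
    sens = float(np.mean(p[sz] == POSITIVE)) if sz.any() else np.nan
    spec = float(np.mean(p[hc] == NEGATIVE)) if hc.any() else np.nan
    return acc, sens, spec


@dataclass
class PermutationResult:
    """Observed accuracy against a permuted-label null distribution."""

    observed_accuracy: float
    null_accuracies: np.ndarray
    n_perm: int
    p_value: float
    seed: int


def _subject_component_maps(scan: SubjectScan, maps: np.ndarray) -> np.ndarray:
    return dual_regress(scan, maps).maps


def _train_test_maps(
    scans: Sequence[SubjectScan], maps: np.ndarray
) -> np.ndarray:
    """Stack dual-regression maps as K_sel x N x V."""
    per_subject = [_subject_component_maps(s, maps) for s in scans]
    return np.stack(per_subject, axis=1)


def _check_two_per_class(scans: Sequence[SubjectScan]) -> None:
    labels = [s.group for s in scans]
    if labels.count(POSITIVE) < 2 or labels.count(NEGATIVE) < 2:
        raise ValueError(
            f"need >= 2 subjects per class, got SZ={labels.count(POSITIVE)}, "
            f"HC={labels.count(NEGATIVE)}"
        )


def loo_single_split(
    scans: Sequence[SubjectScan],
    held_out: int,
    template: ComponentTemplate,
    config: PipelineConfig | None = None,
) -> tuple[EnsembleModel, Prediction]:
    """Run one LOO split: fit everything without subject ``held_out``.

    The held-out subject's data enter only their own dual regression and
    prediction; their label enters nothing.
    """
    config = config or PipelineConfig()
    train = [s for i, s in enumerate(scans) if i != held_out]
    test = scans[held_out]
    dec = group_ica(train, n_sub_pc=config.n_sub_pc, K=config.K, seed=config.ica_seed)
    match = match_components(
        dec.spatial_maps, template, warn_threshold=config.match_warn_threshold
    )
    aligned = match.aligned_candidates(dec.spatial_maps)
    train_maps = _train_test_maps(train, aligned)
    ensemble = train_ensemble(
        train_maps,
        [s.group for s in train],
        config=config.classifier,
        component_ids=list(template.selected_indices),
    )
    test_maps = _subject_component_maps(test, aligned)
    pred = predict_subject(ensemble, test_maps, subject_id=test.subject_id)
    return ensemble, pred


def _report_from_predictions(
    setting: str,
    component_ids: list[int],
    scans_or_labels,
    predictions: list[Prediction],
    n_components: int,
) -> ValidationReport:
    if isinstance(scans_or_labels[0], SubjectScan):
        subject_ids = [s.subject_id for s in scans_or_labels]
        true_labels = [s.group for s in scans_or_labels]
    else:
        subject_ids = [p.subject_id for p in predictions]
        true_labels = list(scans_or_labels)
    votes = np.full((len(predictions), n_components), "", dtype=object)
    return ValidationReport(
        setting=setting,
        component_ids=component_ids,
        subject_ids=subject_ids,
        true_labels=true_labels,
        vote_matrix=votes,
        predictions=predictions,
    )


def _fill_votes(report: ValidationReport, ensembles: list[EnsembleModel]) -> None:
    for i, (pred, ens) in enumerate(zip(report.predictions, ensembles)):
        for clf, vote in zip(ens.classifiers, pred.votes):
            report.vote_matrix[i, clf.maps_row] = vote


def loo_cross_validate(
    scans: Sequence[SubjectScan],
    template: ComponentTemplate,
    config: PipelineConfig | None = None,
) -> ValidationReport:
    """Leave-one-out cross-validation with per-split group ICA."""
    config = config or PipelineConfig()
    _check_two_per_class(scans)
    predictions: list[Prediction] = []
    ensembles: list[EnsembleModel] = []
    for i, scan in enumerate(scans):
        try:
            ens, pred = loo_single_split(scans, i, template, config)
        except Exception as exc:
            raise RuntimeError(
                f"LOO split for subject {scan.subject_id!r} failed: {exc}"
            ) from exc
        ensembles.append(ens)
        predictions.append(pred)
    report = _report_from_predictions(
        "internal",
        list(template.selected_indices),
        list(scans),
        predictions,
        template.n_components,
    )
    _fill_votes(report, ensembles)
    return report


def external_validate_direct(
    train_scans: Sequence[SubjectScan],
    test_scans: Sequence[SubjectScan],
    template: ComponentTemplate,
    config: PipelineConfig | None = None,
    test_labels: Sequence[str] | None = None,
) -> tuple[ValidationReport, EnsembleModel]:
    """Apply a training-site model to a second site with no adaptation.

    Apart from replacing the cross-validation loop with a cross-sample
    one, all classification parameters and procedures are those of the
    training site: test scans are dual regressed on the training-site
    template maps and scored by the frozen ensemble.
    """
    config = config or PipelineConfig()
    _check_two_per_class(train_scans)
    if train_scans[0].grid != test_scans[0].grid:
        raise ValueError("train and test sites are on different grids (resample first)")
    train_maps = _train_test_maps(train_scans, template.maps)
    ensemble = train_ensemble(
        train_maps,
        [s.group for s in train_scans],
        config=config.classifier,
        component_ids=list(template.selected_indices),
    )
    predictions = [
        predict_subject(
            ensemble, _subject_component_maps(s, template.maps), subject_id=s.subject_id
        )
        for s in test_scans
    ]
    labels = list(test_labels) if test_labels is not None else [s.group for s in test_scans]
    report = _report_from_predictions(
        "external_1", list(template.selected_indices), labels, predictions,
        template.n_components,
    )
    report.subject_ids = [s.subject_id for s in test_scans]
    _fill_votes(report, [ensemble] * len(predictions))
    return report, ensemble


def _strip_labels(scans: Sequence[SubjectScan]) -> list[SubjectScan]:
    return [
        SubjectScan(s.subject_id, "unknown", s.site, s.data, s.grid) for s in scans
    ]


def external_validate_transfer(
    train_scans: Sequence[SubjectScan],
    test_scans: Sequence[SubjectScan],
    template: ComponentTemplate,
    config: PipelineConfig | None = None,
    test_labels: Sequence[str] | None = None,
) -> tuple[ValidationReport, EnsembleModel]:
    """Unsupervised transfer variant of external validation.

    A joint group ICA is fit over the training scans plus *unlabeled*
    copies of the test scans, matched greedily to the template; the
    supervised stages then use training labels only.  Test labels (from
    ``test_labels`` or the scans themselves) are touched only at scoring.
    """
    config = config or PipelineConfig()
    _check_two_per_class(train_scans)
    if train_scans[0].grid != test_scans[0].grid:
        raise ValueError("train and test sites are on different grids (resample first)")
    unlabeled_test = _strip_labels(test_scans)
    joint = group_ica(
        list(train_scans) + unlabeled_test,
        n_sub_pc=config.n_sub_pc,
        K=config.K,
        seed=config.ica_seed,
    )
    match = match_components(
        joint.spatial_maps, template, warn_threshold=config.match_warn_threshold
    )
    aligned = match.aligned_candidates(joint.spatial_maps)
    train_maps = _train_test_maps(train_scans, aligned)
    ensemble = train_ensemble(
        train_maps,
        [s.group for s in train_scans],
        config=config.classifier,
        component_ids=list(template.selected_indices),
    )
    predictions = [
        predict_subject(
            ensemble, _subject_component_maps(s, aligned), subject_id=s.subject_id
        )
        for s in unlabeled_test
    ]
    labels = list(test_labels) if test_labels is not None else [s.group for s in test_scans]
    report = _report_from_predictions(
        "external_2", list(template.selected_indices), labels, predictions,
        template.n_components,
    )
    report.subject_ids = [s.subject_id for s in test_scans]
    _fill_votes(report, [ensemble] * len(predictions))
    return report, ensemble


def permutation_test(
    procedure: Callable[[np.ndarray], float],
    labels: Sequence[str],
    n_perm: int = 2000,
    seed: int = 0,
) -> PermutationResult:
    """Label-permutation significance test with the add-one p-value.

    ``procedure`` maps a training-label vector to an accuracy; it is
    called once with the true labels (observed) and ``n_perm`` times with
    uniformly permuted labels to form the empirical null.  p = (1 +
    #{null >= observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(labels)
    observed = float(procedure(labels))
    rng = np.random.default_rng(seed)
    null = np.array(
        [float(procedure(rng.permutation(labels))) for _ in range(n_perm)]
    )
    p = (1.0 + int(np.sum(null >= observed))) / (1.0 + n_perm)
    return PermutationResult(
        observed_accuracy=observed,
        null_accuracies=null,
        n_perm=n_perm,
        p_value=p,
        seed=seed,
    )


def ensemble_digest(ensemble: EnsembleModel) -> str:
    """SHA-256 digest of every trained parameter (leakage audits)."""
    h = hashlib.sha256()
    for clf in ensemble.classifiers:
        h.update(np.asarray(clf.t_map, dtype=float).tobytes())
        h.update(np.float64(clf.t0).tobytes())
        h.update(np.asarray(clf.feature_voxel_idx, dtype=np.int64).tobytes())
        h.update(np.asarray(clf.kpca.eigenvalues, dtype=float).tobytes())
        h.update(np.asarray(clf.kpca.alphas, dtype=float).tobytes())
        h.update(np.asarray(clf.kpca.X_fit, dtype=float).tobytes())
        h.update(np.asarray(clf.kpca.train_col_means, dtype=float).tobytes())
        h.update(np.float64(clf.kpca.gamma if clf.kpca.gamma else 0.0).tobytes())
        h.update(np.asarray(clf.fld.direction, dtype=float).tobytes())
        h.update(np.float64(clf.fld.threshold).tobytes())
        h.update(np.float64(clf.score_sd).tobytes())
    return h.hexdigest()
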