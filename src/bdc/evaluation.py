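"""Classifier evaluation: cross-validation, cross-dataset transfer,
normalization consensus, replicate consistency and canonical-replicate
selection.

The headline metric throughout is the per-class error rate, defined as
``1 - recall`` for the indicated class; transfer performance is measured by
training on one cohort and testing on another after per-dataset
cross-platform normalization. All fold-internal fitting (normalization
statistics, grid search, calibration) happens inside training folds only, so
no information leaks from held-out samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .classifier import (
    ClassificationResult,
    GridConfig,
    SVMHyperparams,
    TrainedModel,
    grid_search,
    predict,
    train,
)
from .expression_io import ExpressionMatrix, SampleAnnotation
from .gene_sets import GeneSet
from .normalization import rank_normalize, zscore_normalize

__all__ = [
    "EvaluationReport",
    "ReplicateReport",
    "PipelineConfig",
    "cross_validate",
    "transfer_test",
    "normalization_consensus",
    "replicate_consistency",
    "select_canonical_replicate",
]

CLASSES = ("BL", "DLBCL")


@dataclass
class EvaluationReport:
    """Confusion counts and the derived per-class / overall rates.

    ``per_class_error[c]`` is exactly ``1 - recall[c]``; ``overall_error`` is
    the fraction of misclassified samples.
    """

    confusion: dict[str, dict[str, int]]  # confusion[true][predicted]
    overall_error: float
    precision: dict[str, float]
    recall: dict[str, float]
    per_class_error: dict[str, float]
    n_samples: int
    metadata: dict = field(default_factory=dict)

    @classmethod
    def from_predictions(
        cls,
        y_true: Sequence[str],
        y_pred: Sequence[str],
        metadata: Optional[dict] = None,
    ) -> "EvaluationReport":
        y_true = list(y_true)
        y_pred = list(y_pred)
        if len(y_true) != len(y_pred):
            raise ValueError("label/prediction length mismatch")
        confusion = {t: {p: 0 for p in CLASSES} for t in CLASSES}
        for t, p in zip(y_true, y_pred):
            confusion[t][p] += 1
        n = len(y_true)
        wrong = sum(confusion[t][p] for t in CLASSES for p in CLASSES if t != p)
        precision, recall, per_class_error = {}, {}, {}
        for c in CLASSES:
            tp = confusion[c][c]
            fn = sum(confusion[c][p] for p in CLASSES if p != c)
            fp = sum(confusion[t][c] for t in CLASSES if t != c)
            recall[c] = tp / (tp + fn) if tp + fn else float("nan")
            precision[c] = tp / (tp + fp) if tp + fp else float("nan")
            per_class_error[c] = 1.0 - recall[c]
        return cls(
            confusion=confusion,
            overall_error=wrong / n if n else float("nan"),
            precision=precision,
            recall=recall,
            per_class_error=per_class_error,
            n_samples=n,
            metadata=metadata or {},
        )

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion,
            "overall_error": self.overall_error,
            "precision": self.precision,
            "recall": self.recall,
            "per_class_error": self.per_class_error,
            "n_samples": self.n_samples,
            "metadata": self.metadata,
        }


@dataclass
class ReplicateReport:
    """Within-patient BL-probability spread and cross-method consensus.

    ``per_patient`` maps patient id to the (sample_id, bl_probability) pairs;
    ``variance`` holds the sample (n-1) variance for groups of size >= 2 and
    omits singletons. ``consensus_fraction``, when computed, is the proportion
    of samples whose predicted class agrees across all tested normalization
    methods.
    """

    per_patient: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    variance: dict[str, float] = field(default_factory=dict)
    consensus_fraction: Optional[float] = None
    per_sample_classes: Optional[pd.DataFrame] = None


@dataclass
class PipelineConfig:
    """What a fold-internal training run looks like.

    ``hyperparams`` fixed to a (c, gamma) pair skips the grid search —
    useful when the grid has already been selected on the full training
    cohort or when runtime matters more than the last percent of accuracy.
    """

    gene_set: Optional[GeneSet] = None
    normalization: str = "zscore"
    grid: Optional[GridConfig] = None
    hyperparams: Optional["SVMHyperparams"] = None


def _normalize_for_mode(matrix: ExpressionMatrix, mode: str) -> ExpressionMatrix:
    """Per-dataset independent normalization, the transfer-experiment default."""
    if mode == "raw" or matrix.normalization_state != "raw":
        return matrix
    if mode == "zscore":
        out, _ = zscore_normalize(matrix)
        return out
    if mode == "rank":
        return rank_normalize(matrix)
    raise ValueError(f"unknown normalization mode {mode!r}")


def cross_validate(
    x: ExpressionMatrix,
    y: Sequence[str],
    k: int = 10,
    config: Optional[PipelineConfig] = None,
    seed: int = 0,
) -> EvaluationReport:
    """Stratified k-fold cross-validation of the full training pipeline.

    Within each training fold the classifier genes are restricted,
    normalization statistics computed, hyperparameters grid-searched (unless
    fixed in ``config``) and the calibrated SVM fitted; held-out samples are
    normalized by projection onto the fold's statistics (z-score) or by
    their own ranks. The report aggregates all held-out predictions.
    """
    config = config or PipelineConfig()
    y_arr = np.asarray(list(y))
    n = len(y_arr)
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if k < 2:
        raise ValueError("k must be >= 2")
    min_class = min((y_arr == c).sum() for c in np.unique(y_arr))
    n_splits = k
    if min_class < k:
        import warnings

        n_splits = max(2, int(min_class))
        warnings.warn(
            f"minority class has {min_class} samples < k={k}; "
            f"using {n_splits} folds",
            stacklevel=2,
        )
    genes = (
        [g for g in config.gene_set.symbols if g in x.data.index]
        if config.gene_set is not None
        else x.gene_ids
    )
    sub = x.subset_genes(genes)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    sample_ids = np.asarray(sub.sample_ids)
    y_true_all: list[str] = []
    y_pred_all: list[str] = []
    for train_idx, test_idx in skf.split(sample_ids, y_arr):
        tr = replace(sub, data=sub.data.iloc[:, train_idx])
        te = replace(sub, data=sub.data.iloc[:, test_idx])
        frozen = None
        if config.normalization == "zscore":
            tr_n, stats = zscore_normalize(tr)
            frozen = stats
        elif config.normalization == "rank":
            tr_n = rank_normalize(tr)
        elif config.normalization == "raw":
            tr_n = tr
        else:
            raise ValueError(f"unknown normalization {config.normalization!r}")
        y_tr = y_arr[train_idx]
        hp = config.hyperparams
        if hp is None:
            hp = grid_search(tr_n, y_tr, config.grid or GridConfig(seed=seed))
        model = train(
            tr_n,
            y_tr,
            hp,
            seed=seed,
            normalization_mode=config.normalization,
            frozen_stats=frozen,
        )
        results = predict(model, te)
        y_true_all.extend(y_arr[test_idx])
        y_pred_all.extend(r.predicted_class for r in results)
    return EvaluationReport.from_predictions(
        y_true_all,
        y_pred_all,
        metadata={
            "mode": "cross_validation",
            "folds": n_splits,
            "seed": seed,
            "normalization": config.normalization,
            "gene_set": config.gene_set.name if config.gene_set else "all",
        },
    )


def transfer_test(
    model: TrainedModel,
    test: ExpressionMatrix,
    test_labels: Sequence[str],
    normalization: Optional[str] = None,
) -> EvaluationReport:
    """Apply a trained model to another cohort and report per-class errors.

    The test cohort is normalized independently with its own per-gene
    statistics (the cross-platform transfer design); ``normalization``
    defaults to the model's recorded mode.
    """
    mode = normalization or model.normalization_mode
    labels = pd.Series(np.asarray(list(test_labels)), index=test.sample_ids)
    available = [g for g in model.gene_order.symbols if g in test.data.index]
    missing = [g for g in model.gene_order.symbols if g not in test.data.index]
    if missing:
        raise ValueError(
            f"test matrix {test.dataset_tag} lacks classifier gene(s): {missing}"
        )
    sub = test.subset_genes(available)
    normalized = _normalize_for_mode(sub, mode)
    results = predict(model, normalized)
    y_pred = [r.predicted_class for r in results]
    y_true = labels.loc[[r.sample_id for r in results]].tolist()
    return EvaluationReport.from_predictions(
        y_true,
        y_pred,
        metadata={
            "mode": "transfer",
            "train_dataset": model.provenance.get("dataset_tag"),
            "test_dataset": test.dataset_tag,
            "normalization": mode,
        },
    )


def normalization_consensus(
    x: ExpressionMatrix,
    models: Sequence[tuple[str, TrainedModel]],
) -> ReplicateReport:
    """Fraction of samples classified identically under every normalization.

    ``models`` pairs a method name with the model trained under it; each
    model classifies the raw cohort after its own per-dataset normalization.
    """
    if len(models) < 2:
        raise ValueError("consensus requires at least 2 methods")
    calls: dict[str, list[str]] = {}
    for method, model in models:
        sub = x.subset_genes(
            [g for g in model.gene_order.symbols if g in x.data.index]
        )
        normalized = _normalize_for_mode(sub, model.normalization_mode)
        results = predict(model, normalized)
        calls[method] = [r.predicted_class for r in results]
        sample_ids = [r.sample_id for r in results]
    frame = pd.DataFrame(calls, index=sample_ids)
    agree = frame.nunique(axis=1) == 1
    report = ReplicateReport(
        consensus_fraction=float(agree.mean()), per_sample_classes=frame
    )
    return report


def replicate_consistency(
    results: Sequence[ClassificationResult],
    annotations: Sequence[SampleAnnotation],
) -> ReplicateReport:
    """Within-patient sample variance of the BL probability across replicates.

    Groups of size >= 2 get an (n-1)-denominator variance; singleton patients
    are listed without one.
    """
    patient_of = {a.sample_id: a.patient_id for a in annotations}
    missing = [r.sample_id for r in results if not patient_of.get(r.sample_id)]
    if missing:
        raise ValueError(f"missing patient_id for sample(s): {missing}")
    per_patient: dict[str, list[tuple[str, float]]] = {}
    for r in results:
        per_patient.setdefault(patient_of[r.sample_id], []).append(
            (r.sample_id, r.bl_probability)
        )
    variance = {
        pid: float(np.var([p for _, p in group], ddof=1))
        for pid, group in per_patient.items()
        if len(group) >= 2
    }
    return ReplicateReport(per_patient=per_patient, variance=variance)


def _canonical_sort_key(a: SampleAnnotation):
    # version 4 over version 3, micro-dissected over usual sampling,
    # then newest array date (absent dates sort last), then sample id.
    version_rank = {"v4": 0, "v3": 1}.get(a.platform_version, 2)
    dissection_rank = {"micro": 0, "normal": 1}.get(a.dissection, 2)
    date_rank = (
        (0, -a.array_date.toordinal()) if a.array_date is not None else (1, 0)
    )
    return (version_rank, dissection_rank, date_rank, a.sample_id)


def select_canonical_replicate(
    annotations: Sequence[SampleAnnotation],
) -> dict[str, str]:
    """Pick one representative sample per patient.

    Ordered criteria: platform version 4 before version 3, micro-dissected
    tissue before usual sampling, then the newest array date; any remaining
    tie goes to the lexicographically smallest sample id.
    """
    missing = [a.sample_id for a in annotations if not a.patient_id]
    if missing:
        raise ValueError(f"missing patient_id for sample(s): {missing}")
    groups: dict[str, list[SampleAnnotation]] = {}
    for a in annotations:
        groups.setdefault(a.patient_id, []).append(a)
    return {
        pid: min(group, key=_canonical_sort_key).sample_id
        for pid, group in groups.items()
    }
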