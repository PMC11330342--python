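"""Multi-label evaluation: Chou-style set metrics, per-label curves, 10-fold
cross-validation, feature-subset ablation and association-strength group
analysis.

With true label sets Y_i, predicted sets Y*_i and M labels:

    aiming         = mean_i |Y_i ∩ Y*_i| / |Y*_i|      (0 when Y*_i is empty)
    coverage       = mean_i |Y_i ∩ Y*_i| / |Y_i|
    accuracy       = mean_i |Y_i ∩ Y*_i| / |Y_i ∪ Y*_i|
    absolute_true  = fraction of i with Y*_i == Y_i
    absolute_false = mean_i (|Y_i ∪ Y*_i| - |Y_i ∩ Y*_i|) / M

Per-label ranking quality uses ROC AUC (ties get half credit) and the area
under the precision-recall step curve; out-of-fold scores are pooled over all
samples before metrics and curves are computed, so each label gets a single
curve.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import KFold

from .config import PipelineConfig
from .datatypes import FeatureBundle, MIRNA_LOCALIZATIONS, ValidationError
from .model import LocalizationClassifier, binarize_predictions

logger = logging.getLogger("miloc")


@dataclass
class MultiLabelMetrics:
    aiming: float
    coverage: float
    accuracy: float
    absolute_true: float
    absolute_false: float

    def as_dict(self) -> dict[str, float]:
        return {
            "aiming": self.aiming,
            "coverage": self.coverage,
            "accuracy": self.accuracy,
            "absolute_true": self.absolute_true,
            "absolute_false": self.absolute_false,
        }


@dataclass
class EvaluationReport:
    """Pooled cross-validation results."""

    metrics: MultiLabelMetrics
    auc: dict[str, float | None]
    aupr: dict[str, float | None]
    average_auc: float
    average_aupr: float
    fold_assignment: np.ndarray
    scores: np.ndarray
    seed: int

    def as_dict(self) -> dict:
        return {
            **self.metrics.as_dict(),
            "auc": self.auc,
            "aupr": self.aupr,
            "average_auc": self.average_auc,
            "average_aupr": self.average_aupr,
        }


def set_metrics(
    true_sets: list[set[str]],
    pred_sets: list[set[str]],
    n_labels: int = len(MIRNA_LOCALIZATIONS),
    vocabulary: tuple[str, ...] = MIRNA_LOCALIZATIONS,
) -> MultiLabelMetrics:
    """Chou-style set-based multi-label metrics."""
    if len(true_sets) != len(pred_sets):
        raise ValidationError("true and predicted set lists differ in length")
    vocab = set(vocabulary[:n_labels])
    aim = cov = acc = at = af = 0.0
    for y, y_star in zip(true_sets, pred_sets):
        stray = (y | y_star) - vocab
        if stray:
            raise ValidationError(f"label(s) outside vocabulary: {sorted(stray)}")
        if not y:
            raise ValidationError("every sample must carry at least one true label")
        inter = len(y & y_star)
        union = len(y | y_star)
        aim += inter / len(y_star) if y_star else 0.0
        cov += inter / len(y)
        acc += inter / union
        at += 1.0 if y == y_star else 0.0
        af += (union - inter) / n_labels
    n = len(true_sets)
    return MultiLabelMetrics(aim / n, cov / n, acc / n, at / n, af / n)


def set_metrics_from_matrices(
    Y: np.ndarray, Y_pred: np.ndarray,
    labels: tuple[str, ...] = MIRNA_LOCALIZATIONS,
) -> MultiLabelMetrics:
    to_sets = lambda M: [
        {labels[j] for j in np.flatnonzero(row)} for row in np.asarray(M)
    ]
    return set_metrics(to_sets(Y), to_sets(Y_pred), n_labels=len(labels),
                       vocabulary=labels)


def auc_aupr(scores: np.ndarray, y: np.ndarray) -> tuple[float | None, float | None]:
    """ROC AUC (tie-aware rank statistic) and PR-curve area for one label.

    Returns ``(None, None)`` when ``y`` is single-class: both areas are
    undefined and the caller excludes the label from averages.
    """
    y = np.asarray(y)
    if len(set(y.tolist())) < 2:
        logger.warning("single-class label column; AUC/AUPR undefined")
        return None, None
    return (
        float(roc_auc_score(y, scores)),
        float(average_precision_score(y, scores)),
    )


def per_label_curves(
    Y: np.ndarray, scores: np.ndarray,
    labels: tuple[str, ...] = MIRNA_LOCALIZATIONS,
) -> tuple[dict[str, float | None], dict[str, float | None], float, float]:
    auc, aupr = {}, {}
    for j, name in enumerate(labels):
        auc[name], aupr[name] = auc_aupr(scores[:, j], Y[:, j])
    defined_auc = [v for v in auc.values() if v is not None]
    defined_aupr = [v for v in aupr.values() if v is not None]
    avg_auc = float(np.mean(defined_auc)) if defined_auc else float("nan")
    avg_aupr = float(np.mean(defined_aupr)) if defined_aupr else float("nan")
    return auc, aupr, avg_auc, avg_aupr


def cross_validate(
    X: np.ndarray,
    Y: np.ndarray,
    config: PipelineConfig | None = None,
    block_dims: tuple[int, ...] | None = None,
    k: int | None = None,
    seed: int | None = None,
) -> EvaluationReport:
    """Shuffled k-fold CV; out-of-fold scores are pooled before scoring."""
    config = config or PipelineConfig()
    k = k or config.cv_folds
    seed = config.stage_seed("cv") if seed is None else seed
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y)
    if len(X) < k:
        raise ValidationError(f"need at least k={k} samples")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    scores = np.zeros((len(X), Y.shape[1]))
    fold_assignment = np.zeros(len(X), dtype=int)
    for fold, (train_idx, test_idx) in enumerate(kf.split(X)):
        clf = LocalizationClassifier.from_params(
            config.classifier, block_dims=block_dims,
            random_state=(seed + fold) & 0x7FFFFFFF,
        )
        clf.fit(X[train_idx], Y[train_idx])
        scores[test_idx] = clf.predict_proba(X[test_idx])
        fold_assignment[test_idx] = fold
    pred = binarize_predictions(scores, config.classifier.threshold)
    metrics = set_metrics_from_matrices(Y, pred)
    auc, aupr, avg_auc, avg_aupr = per_label_curves(Y, scores)
    return EvaluationReport(
        metrics, auc, aupr, avg_auc, avg_aupr, fold_assignment, scores, seed
    )


def feature_subsets() -> list[tuple[str, ...]]:
    """All 31 non-empty combinations of the five feature types."""
    names = FeatureBundle.BLOCK_ORDER
    subsets = []
    for r in range(1, len(names) + 1):
        subsets.extend(itertools.combinations(names, r))
    return subsets


def ablation(
    bundle: FeatureBundle,
    Y: np.ndarray,
    config: PipelineConfig | None = None,
    seeds: tuple[int, ...] = (0,),
) -> list[dict]:
    """Evaluate every feature-type combination by cross-validation.

    Returns one row per (subset, averaged over ``seeds``) with the subset
    flags, feature width, the five set metrics and average AUC/AUPR.
    """
    config = config or PipelineConfig()
    rows = []
    for subset in feature_subsets():
        X = bundle.concat(subset)
        dims = bundle.block_dims(subset)
        reports = []
        for s in seeds:
            cfg_seed = (config.stage_seed("ablation") + s) & 0x7FFFFFFF
            reports.append(
                cross_validate(X, Y, config, block_dims=dims, seed=cfg_seed)
            )
        row = {
            "subset": subset,
            "n_blocks": len(subset),
            "width": X.shape[1],
            "average_auc": float(np.mean([r.average_auc for r in reports])),
            "average_aupr": float(np.mean([r.average_aupr for r in reports])),
        }
        for key in ("aiming", "coverage", "accuracy", "absolute_true", "absolute_false"):
            row[key] = float(np.mean([getattr(r.metrics, key) for r in reports]))
        rows.append(row)
    return rows


def ablation_size_groups(rows: list[dict]) -> dict[int, dict[str, float]]:
    """Mean metrics over subsets grouped by number of feature types (1..5)."""
    groups: dict[int, dict[str, float]] = {}
    for size in range(1, len(FeatureBundle.BLOCK_ORDER) + 1):
        members = [r for r in rows if r["n_blocks"] == size]
        groups[size] = {
            key: float(np.mean([m[key] for m in members]))
            for key in ("aiming", "coverage", "accuracy", "absolute_true",
                        "absolute_false", "average_auc", "average_aupr")
        }
    return groups


def split_strength_groups(
    counts: np.ndarray, ids: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray, float]:
    """Median split of miRNAs by association count.

    miRNAs are ranked by decreasing count (ties broken by position in the
    index, i.e. ID order) and divided in half; with odd n the extra member
    goes to the weakly group.  Returns (strongly idx, weakly idx, threshold),
    the threshold being the smallest count inside the strongly group.
    """
    counts = np.asarray(counts)
    order = np.lexsort((np.arange(len(counts)), -counts))
    n_strong = len(counts) // 2
    strongly = np.sort(order[:n_strong])
    weakly = np.sort(order[n_strong:])
    threshold = float(counts[order[n_strong - 1]]) if n_strong else float("nan")
    return strongly, weakly, threshold


def group_analysis(
    Y: np.ndarray,
    scores: np.ndarray,
    association_counts: dict[str, np.ndarray],
    ids: tuple[str, ...],
    threshold: float = 0.5,
) -> dict[str, dict]:
    """Strongly/weakly group metrics from pooled CV predictions.

    ``association_counts`` maps an object kind (disease/drug/mrna) to the
    per-miRNA association counts from the corresponding network.
    """
    pred = binarize_predictions(scores, threshold)
    out: dict[str, dict] = {}
    for kind, counts in association_counts.items():
        strongly, weakly, count_threshold = split_strength_groups(counts, ids)
        out[kind] = {
            "count_threshold": count_threshold,
            "strongly": set_metrics_from_matrices(Y[strongly], pred[strongly]).as_dict(),
            "weakly": set_metrics_from_matrices(Y[weakly], pred[weakly]).as_dict(),
        }
    return out
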