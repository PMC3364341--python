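"""Prediction-quality metrics, cross-validation, PCA and applicability domain.

Sensitivity (SE), specificity (SP) and concordance (CO) summarize a hard
classification; the ROC curve and its area (AUC, reported on a 0-100 scale:
100 = perfect inference, 50 = random inference) summarize the ranking quality
of a continuous score. Metrics undefined because a class is absent are
reported as NaN, never as 0.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import KFold, StratifiedKFold

from .containers import DescriptorMatrix
from .exceptions import DtiforgeError
from .pairs import PairDataset

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    """True/false interaction and non-interaction counts."""

    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricsReport:
    """SE/SP/CO as percentages, AUC on the 0-100 scale, and the ROC polyline."""

    SE: float
    SP: float
    CO: float
    AUC: float = float("nan")
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    counts: ConfusionCounts | None = None

    def to_dict(self) -> dict:
        out = {"SE": self.SE, "SP": self.SP, "CO": self.CO, "AUC": self.AUC}
        if self.counts is not None:
            out.update(TP=self.counts.TP, FP=self.counts.FP,
                       TN=self.counts.TN, FN=self.counts.FN)
        return out

    def to_json(self, **kw) -> str:
        def clean(v):
            return None if isinstance(v, float) and np.isnan(v) else v

        return json.dumps({k: clean(v) for k, v in self.to_dict().items()},
                          sort_keys=True, **kw)

    def to_markdown(self) -> str:
        def fmt(v, pct=True):
            if np.isnan(v):
                return "NA"
            return f"{v:.2f}%" if pct else f"{v:.2f}"

        return (
            "| SE | SP | CO | AUC |\n|---|---|---|---|\n"
            f"| {fmt(self.SE)} | {fmt(self.SP)} | {fmt(self.CO)} | {fmt(self.AUC, pct=False)} |"
        )


def _check_labels(labels: np.ndarray, name: str) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    bad = set(np.unique(labels)) - {-1, 1}
    if bad:
        raise DtiforgeError(f"{name} labels must be +1/-1, found {sorted(bad)}")
    return labels


def confusion_stats(truth, predicted) -> tuple[ConfusionCounts, MetricsReport]:
    """Confusion counts and SE = TP/(TP+FN), SP = TN/(TN+FP), CO = (TP+TN)/N.

    All three are reported as percentages. If a truth class is absent the
    corresponding rate is NaN (undefined), not 0.
    """
    truth = _check_labels(truth, "truth")
    predicted = _check_labels(predicted, "predicted")
    if truth.shape != predicted.shape:
        raise DtiforgeError("truth and predicted labels differ in length")
    if truth.size == 0:
        raise DtiforgeError("empty evaluation input")
    tp = int(((truth == 1) & (predicted == 1)).sum())
    fn = int(((truth == 1) & (predicted == -1)).sum())
    tn = int(((truth == -1) & (predicted == -1)).sum())
    fp = int(((truth == -1) & (predicted == 1)).sum())
    counts = ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)
    se = 100.0 * tp / (tp + fn) if (tp + fn) else float("nan")
    sp = 100.0 * tn / (tn + fp) if (tn + fp) else float("nan")
    co = 100.0 * (tp + tn) / counts.total
    return counts, MetricsReport(SE=se, SP=sp, CO=co, counts=counts)


def roc_curve_auc(truth, scores) -> MetricsReport:
    """ROC by threshold sweep over unique scores; AUC by trapezoid, x100.

    Tied scores are grouped (one ROC vertex per unique score), which makes the
    AUC identical to the Mann-Whitney statistic with the midrank tie
    convention. Requires both classes present.
    """
    truth = _check_labels(truth, "truth")
    scores = np.asarray(scores, dtype=float)
    if truth.shape != scores.shape:
        raise DtiforgeError("truth and scores differ in length")
    classes = set(np.unique(truth))
    if classes != {-1, 1}:
        raise DtiforgeError(f"ROC needs both classes present, found {sorted(classes)}")
    fpr, tpr, _ = roc_curve(truth, scores, pos_label=1, drop_intermediate=False)
    auc = 100.0 * roc_auc_score(truth, scores)
    return MetricsReport(SE=float("nan"), SP=float("nan"), CO=float("nan"),
                         AUC=auc, roc_points=list(zip(fpr.tolist(), tpr.tolist())))


def evaluate_classifier(results, dataset: PairDataset, threshold: float = 0.5) -> MetricsReport:
    """SE/SP/CO at the threshold plus ranking AUC on one labelled dataset."""
    labels = results.classify(dataset.X, threshold=threshold)
    _, report = confusion_stats(dataset.y, labels)
    if set(np.unique(dataset.y)) == {-1, 1}:
        roc = roc_curve_auc(dataset.y, results.decision_scores(dataset.X))
        report.AUC = roc.AUC
        report.roc_points = roc.roc_points
    return report


def _nanmean(values: list[float]) -> float:
    arr = np.array(values, dtype=float)
    n_na = int(np.isnan(arr).sum())
    if n_na:
        logger.info("averaging over folds skipped %d undefined values", n_na)
    if np.isnan(arr).all():
        return float("nan")
    return float(np.nanmean(arr))


def cross_validate(
    dataset: PairDataset,
    k: int = 5,
    method: str = "rf",
    config=None,
    seed: int = 0,
    threshold: float = 0.5,
) -> dict:
    """Stratified k-fold cross-validation of a pair classifier.

    Each fold serves as the test set once. Returns per-fold metrics, their
    averages (NaN-skipping), and the pooled confusion counts over all folds.
    """
    from .model import DTIModel

    if k < 2:
        raise DtiforgeError("k must be >= 2")
    if k > len(dataset):
        raise DtiforgeError(f"k = {k} exceeds dataset size {len(dataset)}")
    min_class = int(min((dataset.y == 1).sum(), (dataset.y == -1).sum()))
    if k <= min_class:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        # leave-one-out and similar: stratification impossible, fall back
        logger.info("k=%d exceeds smallest class count %d; plain K-fold used", k, min_class)
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    per_fold: list[MetricsReport] = []
    pooled_truth: list[np.ndarray] = []
    pooled_pred: list[np.ndarray] = []
    for tr, te in splitter.split(dataset.X, dataset.y):
        fold_train = dataset.subset(tr, role="train")
        fold_test = dataset.subset(te, role="test")
        res = DTIModel(fold_train, method=method, config=config).fit()
        per_fold.append(evaluate_classifier(res, fold_test, threshold=threshold))
        pooled_truth.append(fold_test.y)
        pooled_pred.append(res.classify(fold_test.X, threshold=threshold))
    counts, pooled = confusion_stats(np.concatenate(pooled_truth), np.concatenate(pooled_pred))
    return {
        "per_fold": per_fold,
        "mean": MetricsReport(
            SE=_nanmean([m.SE for m in per_fold]),
            SP=_nanmean([m.SP for m in per_fold]),
            CO=_nanmean([m.CO for m in per_fold]),
            AUC=_nanmean([m.AUC for m in per_fold]),
        ),
        "pooled": pooled,
        "pooled_counts": counts,
    }


def pca_project(
    matrix: DescriptorMatrix | np.ndarray,
    k: int = 3,
    standardize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """First k principal-component scores and explained-variance fractions.

    Features are centered and (by default) scaled to unit variance before the
    decomposition, since descriptor units are incommensurable; constant
    features are left centered only.
    """
    X = matrix.values if isinstance(matrix, DescriptorMatrix) else np.asarray(matrix, dtype=float)
    if X.shape[0] < 2:
        raise DtiforgeError("PCA needs at least 2 rows")
    Xc = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0)
        nz = sd > 0
        Xc[:, nz] = Xc[:, nz] / sd[nz]
    rank = int(np.linalg.matrix_rank(Xc))
    if k > rank:
        raise DtiforgeError(f"k = {k} exceeds the data rank {rank}")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(Xc)
    return scores, pca.explained_variance_ratio_


def applicability_domain(
    train: DescriptorMatrix,
    queries: DescriptorMatrix,
) -> pd.DataFrame:
    """Per-feature min-max box check of queries against the training set.

    A query is in-domain iff every feature lies within the training range.
    Returns one row per query with the in/out flag and the names of the
    offending features.
    """
    if train.names != queries.names:
        raise DtiforgeError("training and query descriptor spaces differ")
    lo = train.values.min(axis=0)
    hi = train.values.max(axis=0)
    names = np.array(train.names)
    rows = []
    for rid, vec in zip(queries.row_ids, queries.values):
        bad = names[(vec < lo) | (vec > hi)]
        rows.append({
            "id": rid,
            "in_domain": bad.size == 0,
            "offending_features": ";".join(bad.tolist()),
        })
    return pd.DataFrame(rows, columns=["id", "in_domain", "offending_features"])
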