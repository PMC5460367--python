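"""Performance metrics, cross-validation and the significance protocol.

Binary metrics follow the standard confusion-count definitions:
accuracy = (TP+TN)/N, sensitivity = TP/(TP+FN), specificity = TN/(TN+FP)
and MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TN+FN)(TP+FN)(TN+FP)), with MCC
defined as 0 whenever a marginal is zero.  Score-based evaluation uses the
area under the ROC curve.  Method comparison first checks both paired
metric vectors for normality (Shapiro-Wilk, alpha = 0.05) and applies a
paired t-test if both pass, a Wilcoxon signed-rank test otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import model as _model
from . import motifs as _motifs
from .seqio import SequenceDataset, undersample_balanced

METRIC_NAMES = ("sensitivity", "specificity", "accuracy", "mcc", "auc")


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("at least one evaluated record required")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(
            TP=int(np.sum((y_true == 1) & (y_pred == 1))),
            TN=int(np.sum((y_true == 0) & (y_pred == 0))),
            FP=int(np.sum((y_true == 0) & (y_pred == 1))),
            FN=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


def compute_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Accuracy, sensitivity, specificity and MCC from confusion counts."""
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    n = counts.total
    accuracy = (tp + tn) / n
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    denom = (tp + fp) * (tn + fn) * (tp + fn) * (tn + fp)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return {
        "sensitivity": sensitivity,
        "specificity": specificity,
        "accuracy": accuracy,
        "mcc": mcc,
    }


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (rank method; ties contribute one half)."""
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("roc_auc requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


@dataclass
class MetricsReport:
    """Per-fold / per-repeat metric rows with mean +/- sd summaries."""

    table: pd.DataFrame  # one row per fold/repeat, columns = metrics
    kind: str = "cv"  # "cv" or "repeats"
    audit: list = field(default_factory=list)

    @property
    def n_units(self) -> int:
        return len(self.table)

    def mean(self, metric: str) -> float:
        return float(self.table[metric].mean())

    def sd(self, metric: str) -> float:
        if len(self.table) < 2:
            return 0.0
        return float(self.table[metric].std(ddof=1))

    def values(self, metric: str) -> np.ndarray:
        return self.table[metric].to_numpy(dtype=float)

    def summary(self) -> str:
        lines = []
        for metric in self.table.columns:
            lines.append(f"{metric}: {self.mean(metric):.3f} ± "
                         f"{self.sd(metric):.3f}")
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        return {
            "kind": self.kind,
            "n_units": self.n_units,
            "per_unit": {m: [float(v) for v in self.table[m]]
                         for m in self.table.columns},
            "mean": {m: self.mean(m) for m in self.table.columns},
            "sd": {m: self.sd(m) for m in self.table.columns},
        }


def _evaluate_model(model, data: SequenceDataset) -> dict[str, float]:
    y_true = np.array([r.label for r in data])
    labels, scores = model.predict_records(data)
    row = compute_metrics(ConfusionCounts.from_predictions(y_true, labels))
    row["auc"] = (roc_auc(scores, y_true)
                  if len(np.unique(y_true)) == 2 else float("nan"))
    return row


def kfold_cv(
    data: SequenceDataset,
    config: _model.PipelineConfig | None = None,
    k: int = 5,
    seed: int = 0,
) -> MetricsReport:
    """Stratified k-fold CV of the full pipeline.

    By default motif discovery and feature selection run inside each fold's
    training split only (no leakage); ``config.in_fold_motifs = False``
    emulates the laxer protocol of discovering motifs once on all data.
    """
    config = config if config is not None else _model.PipelineConfig()
    if k < 2:
        raise ValueError("k must be >= 2")
    y = np.array([r.label for r in data])
    if None in [r.label for r in data]:
        raise ValueError("kfold_cv requires fully labelled data")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    records = list(data)

    shared_catalog = None
    if "MTF" in config.blocks and not config.in_fold_motifs:
        shared_catalog = _motifs.discover_motifs(
            data.positives(), data.negatives(),
            threshold_T=config.threshold_t, top_k=config.top_k_motifs,
        )

    rows, audit = [], []
    for fold, (train_idx, test_idx) in enumerate(skf.split(records, y)):
        train = SequenceDataset([records[i] for i in train_idx])
        test = SequenceDataset([records[i] for i in test_idx])
        if len(np.unique([r.label for r in test])) < 2:
            raise ValueError(f"fold {fold}: single-class validation split")
        fitted = _model.fit_pipeline(
            train, config, seed=seed, catalog=shared_catalog,
            catalog_source_ids=(frozenset(data.ids())
                                if shared_catalog is not None else None),
        )
        rows.append(_evaluate_model(fitted, test))
        audit.append(
            {"fold": fold,
             "train_ids": frozenset(train.ids()),
             "test_ids": frozenset(test.ids()),
             "catalog_source_ids": fitted.catalog_source_ids}
        )
    return MetricsReport(pd.DataFrame(rows, columns=list(METRIC_NAMES)),
                         kind="cv", audit=audit)


def repeated_undersample_eval(
    model,
    data: SequenceDataset,
    repeats: int = 10,
    seed: int = 0,
    fraction: float | None = None,
) -> MetricsReport:
    """Evaluate a trained model on repeated balanced (or fractional) draws.

    Default draws all of the minority class and an equal-size random sample
    of the majority class per repeat; ``fraction`` instead draws that
    fraction of each class (the 80%-draw protocol).  Per-repeat rows are
    retained for significance testing.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    seeds = np.random.SeedSequence(seed).generate_state(repeats) % (2**31)
    rows = []
    for r in range(repeats):
        rng = np.random.default_rng(seeds[r])
        if fraction is None:
            sample = undersample_balanced(data, int(seeds[r]))
        else:
            ids = []
            for subset in (data.positives(), data.negatives()):
                all_ids = subset.ids()
                n = max(1, round(fraction * len(all_ids)))
                ids.extend(rng.choice(all_ids, size=n, replace=False))
            sample = data.subset(ids)
        rows.append(_evaluate_model(model, sample))
    return MetricsReport(pd.DataFrame(rows, columns=list(METRIC_NAMES)),
                         kind="repeats")


@dataclass
class SignificanceResult:
    test_used: str  # "t_test" or "wilcoxon"
    normality_p: float
    p_value: float
    significant: bool
    alpha: float = 0.05


def compare_methods(metric_a, metric_b, alpha: float = 0.05) -> SignificanceResult:
    """Paired comparison of two per-repeat metric vectors.

    Shapiro-Wilk on both vectors at ``alpha``; a paired t-test if both look
    normal, a two-sided Wilcoxon signed-rank test otherwise.  Identical
    vectors report p = 1 and no significance.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors of equal length required")
    if len(a) < 5:
        raise ValueError("need at least 5 paired values")
    if np.array_equal(a, b):
        return SignificanceResult("t_test", 1.0, 1.0, False, alpha)

    def shapiro_p(x: np.ndarray) -> float:
        if np.ptp(x) == 0:  # constant sample: certainly not normal
            return 0.0
        return float(stats.shapiro(x).pvalue)

    norm_a, norm_b = shapiro_p(a), shapiro_p(b)
    normal = norm_a > alpha and norm_b > alpha
    if normal:
        p = float(stats.ttest_rel(a, b).pvalue)
        test = "t_test"
    else:
        p = float(stats.wilcoxon(a, b, alternative="two-sided").pvalue)
        test = "wilcoxon"
    return SignificanceResult(test, min(norm_a, norm_b), p, p < alpha, alpha)
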