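"""RBF-SVM training, the end-to-end pipeline and the lineage ensemble.

``grid_search_train`` fits a standardized RBF-SVM over a (C, gamma) grid,
choosing the pair that maximises cross-validated mean MCC (ties break
toward smaller C, then smaller gamma).  ``fit_pipeline`` runs the whole
method on one labelled dataset: motif discovery on the training sequences,
feature assembly, optional filter+wrapper feature selection, then the grid
search.  ``train_ensemble`` repeats the pipeline per lineage and wraps the
results in a dispatching ensemble: a universal model is always present and
lineage-specific models (bacteria / eukaryota / archaea) are used for
queries carrying a matching lineage tag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import joblib
import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.metrics import matthews_corrcoef
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import features as _features
from . import motifs as _motifs
from . import selection as _selection
from .seqio import SequenceDataset

#: canonical coarse grid (libsvm practical-guide style)
DEFAULT_C_GRID = tuple(2.0 ** np.arange(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0 ** np.arange(-15, 4, 2))

FORMAT_VERSION = 1


@dataclass
class PipelineConfig:
    """Knobs of the full training pipeline.

    Defaults follow the method's stated protocol: occurrence threshold
    T = 10%, top 10 motifs, five-fold cross-validation, all four feature
    blocks, filter gamma 0.
    """

    blocks: tuple = _features.BLOCK_ORDER
    threshold_t: float = 0.10
    top_k_motifs: int = 10
    gamma_fms: float = 0.0
    do_selection: bool = True
    sbs_folds: int = 5
    sbs_patience: int | None = None
    c_grid: tuple = DEFAULT_C_GRID
    gamma_grid: tuple = DEFAULT_GAMMA_GRID
    grid_folds: int = 5
    in_fold_motifs: bool = True
    min_lineage_per_class: int = 10
    property_table_path: str | None = None

    def to_dict(self) -> dict:
        return {
            "blocks": list(self.blocks),
            "threshold_t": self.threshold_t,
            "top_k_motifs": self.top_k_motifs,
            "gamma_fms": self.gamma_fms,
            "do_selection": self.do_selection,
            "sbs_folds": self.sbs_folds,
            "sbs_patience": self.sbs_patience,
            "c_grid": [float(c) for c in self.c_grid],
            "gamma_grid": [float(g) for g in self.gamma_grid],
            "grid_folds": self.grid_folds,
            "in_fold_motifs": self.in_fold_motifs,
            "min_lineage_per_class": self.min_lineage_per_class,
            "property_table_path": self.property_table_path,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        for key in ("blocks", "c_grid", "gamma_grid"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass
class TrainedModel:
    """A fitted RBF-SVM with its feature mask and featurization state."""

    feature_mask: list[str]
    pipeline: Pipeline  # StandardScaler + probability SVC
    C: float
    gamma: float
    cv_mcc: float
    lineage_scope: str = "universal"
    catalog: _motifs.MotifCatalog | None = None
    property_table: _features.PropertyTable | None = None
    blocks: tuple = _features.BLOCK_ORDER
    selection: _selection.SelectionResult | None = None
    catalog_source_ids: frozenset = frozenset()
    config: PipelineConfig | None = None

    def predict(self, X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Binary labels and calibrated scores in [0, 1] for a feature matrix."""
        missing = [f for f in self.feature_mask if f not in X.columns]
        if missing:
            raise ValueError(f"missing features: {missing[:10]}"
                             + ("..." if len(missing) > 10 else ""))
        sub = X[self.feature_mask].to_numpy(dtype=float)
        scores = self.pipeline.predict_proba(sub)[:, 1]
        labels = (scores >= 0.5).astype(int)
        return labels, scores

    def predict_records(self, data: SequenceDataset) -> tuple[np.ndarray, np.ndarray]:
        """Featurize raw records with the stored catalog/table and predict."""
        X = _features.feature_matrix(data, self.catalog, self.property_table,
                                     self.blocks)
        return self.predict(X)

    def save(self, path) -> None:
        joblib.dump({"format_version": FORMAT_VERSION, "kind": "model",
                     "payload": self}, path)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        blob = joblib.load(path)
        if blob.get("format_version") != FORMAT_VERSION:
            raise ValueError(
                f"incompatible model archive version {blob.get('format_version')!r}"
            )
        if blob.get("kind") != "model":
            raise ValueError("archive does not contain a single model")
        return blob["payload"]


def grid_search_train(
    X,
    y,
    grid: tuple | None = None,
    folds: int = 5,
    seed: int = 0,
) -> TrainedModel:
    """Pick (C, gamma) by CV mean MCC, refit on all data with calibration.

    Standardization is learned inside each training fold (and finally on the
    full data) so no test information leaks into scaling.  Probability
    scores come from Platt-style sigmoid calibration fitted on internal
    training folds (``SVC(probability=True)``).
    """
    frame = X if isinstance(X, pd.DataFrame) else pd.DataFrame(
        np.asarray(X, dtype=float),
        columns=[f"f{i}" for i in range(np.asarray(X).shape[1])],
    )
    y = np.asarray(y)
    c_grid, gamma_grid = grid if grid is not None else (DEFAULT_C_GRID,
                                                       DEFAULT_GAMMA_GRID)
    if len(c_grid) == 0 or len(gamma_grid) == 0:
        raise ValueError("grid must be non-empty")
    counts = np.bincount(y.astype(int), minlength=2)
    if counts.min() < folds:
        raise ValueError(
            "too few samples in one class for stratified CV "
            f"(min class {counts.min()} < folds {folds})"
        )
    values = frame.to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(values, y))

    best = None  # (mcc, C, gamma); iteration order gives the tie-break
    for C in sorted(float(c) for c in c_grid):
        for gamma in sorted(float(g) for g in gamma_grid):
            fold_scores = []
            for train_idx, test_idx in splits:
                model = Pipeline(
                    [("scale", StandardScaler()),
                     ("svc", SVC(kernel="rbf", C=C, gamma=gamma))]
                )
                model.fit(values[train_idx], y[train_idx])
                pred = model.predict(values[test_idx])
                fold_scores.append(matthews_corrcoef(y[test_idx], pred))
            mean_mcc = float(np.mean(fold_scores))
            if best is None or mean_mcc > best[0]:
                best = (mean_mcc, C, gamma)

    cv_mcc, C, gamma = best
    # Platt-style sigmoid calibration fitted on internal training folds,
    # then the margin SVM refitted on all data (ensemble=False).
    calib_folds = int(min(5, counts.min()))
    final = Pipeline(
        [("scale", StandardScaler()),
         ("svc", CalibratedClassifierCV(
             SVC(kernel="rbf", C=C, gamma=gamma, random_state=seed),
             method="sigmoid", cv=calib_folds, ensemble=False))]
    )
    final.fit(values, y)
    return TrainedModel(
        feature_mask=[str(c) for c in frame.columns],
        pipeline=final, C=C, gamma=gamma, cv_mcc=cv_mcc,
    )


def predict(model: TrainedModel, X: pd.DataFrame):
    """Functional alias for :meth:`TrainedModel.predict`."""
    return model.predict(X)


def fit_pipeline(
    train: SequenceDataset,
    config: PipelineConfig | None = None,
    seed: int = 0,
    lineage_scope: str = "universal",
    catalog: _motifs.MotifCatalog | None = None,
    catalog_source_ids=None,
) -> TrainedModel:
    """Run the full method on one labelled training set.

    Stages: motif discovery (unless a catalog is supplied), feature
    assembly, Fisher-Markov ranking + SBS (optional), grid-search SVM.
    """
    config = config if config is not None else PipelineConfig()
    if train.positive_count == 0 or train.negative_count == 0:
        raise ValueError("training data must contain both classes")

    if "MTF" in config.blocks and catalog is None:
        catalog = _motifs.discover_motifs(
            train.positives(), train.negatives(),
            threshold_T=config.threshold_t, top_k=config.top_k_motifs,
        )
        catalog_source_ids = frozenset(train.ids())
    blocks = config.blocks
    if catalog is not None and len(catalog) == 0:
        warnings.warn("empty motif catalog; dropping the MTF block",
                      stacklevel=2)
        blocks = tuple(b for b in blocks if b != "MTF")

    table = (_features.load_property_table(config.property_table_path)
             if "PCP" in blocks else None)
    X = _features.feature_matrix(train, catalog, table, blocks)
    y = np.array([r.label for r in train])

    sel = None
    if config.do_selection and X.shape[1] > 1:
        ranking = _selection.fisher_markov_rank(X, y, gamma=config.gamma_fms)
        sel = _selection.sbs_select(
            X, y, ranking, folds=config.sbs_folds, seed=seed,
            patience=config.sbs_patience,
        )
        X = X[sel.selected]

    model = grid_search_train(
        X, y, grid=(config.c_grid, config.gamma_grid),
        folds=config.grid_folds, seed=seed,
    )
    model.lineage_scope = lineage_scope
    model.catalog = catalog if "MTF" in blocks else None
    model.property_table = table
    model.blocks = blocks
    model.selection = sel
    model.catalog_source_ids = (
        frozenset(catalog_source_ids) if catalog_source_ids is not None
        else frozenset(train.ids())
    )
    model.config = config
    return model


@dataclass
class LineageEnsemble:
    """A universal model plus optional lineage-specific models."""

    universal: TrainedModel
    per_lineage: dict = field(default_factory=dict)
    dispatch_policy: str = "lineage_if_available_else_universal"

    def __post_init__(self) -> None:
        if self.dispatch_policy not in (
            "lineage_if_available_else_universal", "universal_only"
        ):
            raise ValueError(f"unknown dispatch policy {self.dispatch_policy!r}")

    def dispatch(self, lineage: str) -> TrainedModel:
        """The single model answering a query with this lineage tag."""
        if (self.dispatch_policy == "lineage_if_available_else_universal"
                and lineage in self.per_lineage):
            return self.per_lineage[lineage]
        return self.universal

    def predict_records(self, data: SequenceDataset) -> pd.DataFrame:
        groups: dict[str, list] = {}
        for record in data:
            scope = self.dispatch(record.lineage).lineage_scope
            groups.setdefault(scope, []).append(record)
        by_id: dict[str, dict] = {}
        for scope, records in groups.items():
            model = (self.universal if scope == "universal"
                     else self.per_lineage[scope])
            labels, scores = model.predict_records(SequenceDataset(records))
            for record, label, score in zip(records, labels, scores):
                by_id[record.id] = {
                    "id": record.id, "score": float(score),
                    "label": int(label), "model_used": scope,
                }
        rows = [by_id[r.id] for r in data]
        return pd.DataFrame(rows, columns=["id", "score", "label", "model_used"])

    def save(self, path) -> None:
        joblib.dump({"format_version": FORMAT_VERSION, "kind": "ensemble",
                     "payload": self}, path)

    @classmethod
    def load(cls, path) -> "LineageEnsemble":
        blob = joblib.load(path)
        if blob.get("format_version") != FORMAT_VERSION:
            raise ValueError(
                f"incompatible model archive version {blob.get('format_version')!r}"
            )
        if blob.get("kind") != "ensemble":
            raise ValueError("archive does not contain an ensemble")
        return blob["payload"]


def train_ensemble(
    datasets: dict,
    config: PipelineConfig | None = None,
    seed: int = 0,
    dispatch_policy: str = "lineage_if_available_else_universal",
) -> LineageEnsemble:
    """Run the pipeline independently per scope and assemble the ensemble.

    ``datasets`` maps scope names to labelled datasets; the key
    ``"universal"`` is required.  Lineages with fewer than
    ``config.min_lineage_per_class`` samples in either class are skipped
    with a warning (queries fall back to the universal model).
    """
    config = config if config is not None else PipelineConfig()
    if "universal" not in datasets:
        raise ValueError("train_ensemble requires a 'universal' dataset")
    universal = fit_pipeline(datasets["universal"], config, seed=seed,
                             lineage_scope="universal")
    per_lineage: dict = {}
    for offset, (lineage, data) in enumerate(sorted(datasets.items()), start=1):
        if lineage == "universal":
            continue
        if min(data.positive_count, data.negative_count) < config.min_lineage_per_class:
            warnings.warn(
                f"lineage {lineage!r}: fewer than "
                f"{config.min_lineage_per_class} samples per class; skipped",
                stacklevel=2,
            )
            continue
        per_lineage[lineage] = fit_pipeline(
            data, config, seed=seed + offset, lineage_scope=lineage
        )
    return LineageEnsemble(universal, per_lineage, dispatch_policy)
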