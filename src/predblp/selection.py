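"""Filter + wrapper feature selection.

A Fisher-Markov-style filter first ranks every feature by class relevance;
sequential backward selection (SBS) then walks the ranking from the least
relevant feature upward, removing one feature at a time and scoring each
remaining subset by cross-validated mean MCC.  The subset with the best
criterion wins (ties prefer the smaller subset); a removed feature is never
reconsidered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import matthews_corrcoef
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC


@dataclass
class FeatureRanking:
    """Features ordered by relevance score, descending."""

    feature_names: list[str]
    scores: np.ndarray
    gamma: float

    def __post_init__(self) -> None:
        if len(self.feature_names) != len(self.scores):
            raise ValueError("names and scores must align")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"feature": self.feature_names, "score": self.scores})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class SelectionResult:
    """Outcome of SBS: the kept features and the elimination trajectory."""

    selected: list[str]
    trajectory: list[tuple[int, float]] = field(default_factory=list)
    criterion: str = "cv_mean_mcc"

    @property
    def final_score(self) -> float:
        n_sel = len(self.selected)
        for n, score in self.trajectory:
            if n == n_sel:
                return score
        raise ValueError("selected size missing from trajectory")

    def to_json_dict(self) -> dict:
        return {
            "selected": self.selected,
            "trajectory": [[int(n), float(s)] for n, s in self.trajectory],
            "criterion": self.criterion,
        }


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])


def fisher_markov_rank(X, y, gamma: float = 0.0) -> FeatureRanking:
    """Rank features by a two-class Fisher-Markov-style relevance score.

    Each column is standardized; its score is the squared difference of
    standardized class means minus ``gamma`` times the pooled within-class
    variance.  Constant columns score ``-gamma`` times their (zero-mean)
    spread term rather than NaN.  Ties break by feature name.
    """
    frame = _as_frame(X)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("fisher_markov_rank requires exactly two classes")
    mask0 = y == classes[0]
    mask1 = ~mask0
    if mask0.sum() < 2 or mask1.sum() < 2:
        raise ValueError("need at least two samples per class")

    values = frame.to_numpy(dtype=float)
    mean = values.mean(axis=0)
    std = values.std(axis=0)
    nonconstant = std > 0
    z = np.zeros_like(values)
    z[:, nonconstant] = (values[:, nonconstant] - mean[nonconstant]) / std[nonconstant]

    diff = z[mask1].mean(axis=0) - z[mask0].mean(axis=0)
    n0, n1 = mask0.sum(), mask1.sum()
    within = (n0 * z[mask0].var(axis=0) + n1 * z[mask1].var(axis=0)) / (n0 + n1)
    scores = diff**2 - gamma * within

    order = sorted(range(len(frame.columns)),
                   key=lambda j: (-scores[j], str(frame.columns[j])))
    return FeatureRanking(
        [str(frame.columns[j]) for j in order], scores[order], gamma
    )


def default_trainer(seed: int = 0):
    """Fixed-hyperparameter linear-SVM wrapper surrogate used inside SBS.

    A linear kernel is deliberately used here even though the final
    classifier is an RBF-SVM: the wrapper needs a criterion that degrades
    when irrelevant columns are present (linear SVMs overfit noise
    directions, so removing them measurably improves CV MCC), whereas an
    RBF kernel with dimension-adaptive bandwidth is almost insensitive to
    pure-noise features and yields a flat, uninformative trajectory.  Any
    other trainer can be injected via the ``trainer`` argument.
    """

    def train(X, y):
        model = Pipeline(
            [
                ("scale", StandardScaler()),
                ("svc", SVC(kernel="linear", C=1.0, random_state=seed)),
            ]
        )
        model.fit(X, y)
        return model

    return train


def _cv_mcc(X: pd.DataFrame, y, columns, trainer, splits) -> float:
    sub = X[columns].to_numpy(dtype=float)
    scores = []
    for train_idx, test_idx in splits:
        model = trainer(sub[train_idx], y[train_idx])
        pred = model.predict(sub[test_idx])
        scores.append(matthews_corrcoef(y[test_idx], pred))
    return float(np.mean(scores))


def sbs_select(
    X,
    y,
    ranking: FeatureRanking,
    trainer=None,
    folds: int = 5,
    seed: int = 0,
    patience: int | None = None,
    min_features: int = 1,
) -> SelectionResult:
    """Sequential backward selection along the filter ranking.

    Features are removed lowest-ranked first; each candidate subset is
    scored by ``folds``-fold stratified CV mean MCC with folds fixed across
    steps.  The subset maximising the criterion is returned (ties prefer
    fewer features, so removals that leave the criterion unchanged are
    kept).  ``patience`` stops the walk after that many consecutive steps
    without improving the best criterion; None walks the whole trajectory.
    """
    frame = _as_frame(X)
    y = np.asarray(y)
    if set(ranking.feature_names) != set(map(str, frame.columns)):
        raise ValueError("ranking must cover exactly the feature columns")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    trainer = trainer if trainer is not None else default_trainer(seed)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(frame, y))

    removal_order = list(reversed(ranking.feature_names))  # worst first
    current = list(ranking.feature_names)

    def evaluate(columns):
        try:
            return _cv_mcc(frame, y, columns, trainer, splits)
        except Exception as exc:  # pragma: no cover - propagation contract
            raise RuntimeError(
                f"trainer failed on subset of {len(columns)} features"
            ) from exc

    best_cols = list(current)
    best_score = evaluate(current)
    trajectory = [(len(current), best_score)]
    stale = 0
    for feature in removal_order:
        if len(current) <= min_features:
            break
        current = [c for c in current if c != feature]
        score = evaluate(current)
        trajectory.append((len(current), score))
        if score >= best_score:  # equality prefers the smaller subset
            best_score = score
            best_cols = list(current)
            stale = 0
        else:
            stale += 1
            if patience is not None and stale >= patience:
                break

    selected = [str(c) for c in frame.columns if str(c) in set(best_cols)]
    return SelectionResult(selected, trajectory)
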