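"""Five one-vs-rest probabilistic base classifiers with fixed search grids.

The classifier roster and its fusion indices are fixed: 1 = random forest
(RF), 2 = support vector machine (SVM), 3 = logistic regression (LR),
4 = linear discriminant analysis (LDA), 5 = adaptive boosting trees (ABT).
Multi-class prediction always uses the one-vs-rest (OvR) decomposition so
that each classifier emits a per-class score that can be renormalized into
a probability vector — the basic probability assignment consumed by the
evidence-fusion stage.

Hyper-parameters are chosen by exhaustive grid search scored by mean
five-fold stratified cross-validation accuracy; ties go to the earlier grid
point.  The grids:

* RF — number of trees 10..100 step 10; split criterion gini or entropy.
* ABT — number of base learners 10..100 step 10.
* SVM — penalty C = 1..10 (integers); kernel polynomial (degree 3 by
  default) or radial-basis.
* LR — liblinear solver; C in {1e-4, 1e-3, 1e-2, 0.1, 1, 10}.
* LDA — default parameters, no grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

# the sklearn-1.9 deprecation of SVC(probability=True); the replacement
# (CalibratedClassifierCV) cannot calibrate the very small OvR positive
# classes this pipeline routinely sees, so we keep libsvm's built-in
# sigmoid calibration and silence the notice.
warnings.filterwarnings(
    "ignore", message="The `probability` parameter was deprecated", category=FutureWarning
)
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC

from .errors import ContractError, ParameterError, SchemaError, StratificationError
from .featurize import FeatureMatrix
from .molecules import ClassFrame

log = logging.getLogger(__name__)

CLASSIFIER_KINDS = ("RF", "SVM", "LR", "LDA", "ABT")

#: Fusion-name digit for each classifier kind.
CLASSIFIER_INDEX: dict[str, int] = {"RF": 1, "SVM": 2, "LR": 3, "LDA": 4, "ABT": 5}
KIND_BY_INDEX: dict[int, str] = {v: k for k, v in CLASSIFIER_INDEX.items()}


def _grids(spec: "ClassifierSpec") -> dict[str, list]:
    return {
        "RF": {
            "estimator__n_estimators": list(range(10, 101, 10)),
            "estimator__criterion": ["gini", "entropy"],
        },
        "ABT": {"estimator__n_estimators": list(range(10, 101, 10))},
        "SVM": {
            "estimator__C": list(range(1, 11)),
            "estimator__kernel": ["poly", "rbf"],
        },
        "LR": {"estimator__C": [0.0001, 0.001, 0.01, 0.1, 1, 10]},
        "LDA": {},
    }[spec.kind]


@dataclass(frozen=True)
class ClassifierSpec:
    """One base classifier: kind, CV settings, seed and probability mode.

    `probability_mode` controls how OvR scores become probabilities:
    ``"calibrated"`` uses each algorithm's native probability output (for the
    SVM, the built-in sigmoid calibration fitted inside cross-validation);
    ``"softmax"`` pushes raw decision scores through a softmax instead.
    """

    kind: str
    cv_folds: int = 5
    seed: int = 0
    probability_mode: str = "calibrated"
    svm_poly_degree: int = 3

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ParameterError(f"unknown classifier kind {self.kind!r}")
        if self.probability_mode not in ("calibrated", "softmax"):
            raise ParameterError(f"unknown probability mode {self.probability_mode!r}")

    @property
    def index(self) -> int:
        return CLASSIFIER_INDEX[self.kind]

    @property
    def grid(self) -> dict[str, list]:
        return _grids(self)

    def build(self, with_probability: bool = True):
        """Construct the unfitted OvR estimator for this spec."""
        if self.kind == "RF":
            base = RandomForestClassifier(random_state=self.seed)
        elif self.kind == "ABT":
            base = AdaBoostClassifier(random_state=self.seed)
        elif self.kind == "SVM":
            base = SVC(
                degree=self.svm_poly_degree,
                probability=with_probability and self.probability_mode == "calibrated",
                random_state=self.seed,
            )
        elif self.kind == "LR":
            base = LogisticRegression(solver="liblinear", max_iter=1000)
        else:
            base = LinearDiscriminantAnalysis()
        return OneVsRestClassifier(base)


@dataclass
class FittedModel:
    """A grid-tuned, refitted OvR classifier plus the metadata to reuse it."""

    spec: ClassifierSpec
    chosen_params: dict
    estimator: OneVsRestClassifier
    feature_columns: tuple[str, ...]
    train_ids: tuple[str, ...]
    frame: ClassFrame


@dataclass
class ProbabilityMatrix:
    """Rows of class probabilities (columns in frame order, each row sums to 1)."""

    data: pd.DataFrame
    classifier_index: int
    report: pd.DataFrame | None = None  # per-row fusion trace (kc, fallback), if fused

    def __post_init__(self) -> None:
        vals = self.data.to_numpy(dtype=float)
        if (vals < -1e-12).any():
            raise ContractError("probability matrix contains negative entries")
        if not np.allclose(vals.sum(axis=1), 1.0, atol=1e-9):
            raise ContractError("probability matrix rows must sum to 1")

    @property
    def ids(self) -> list[str]:
        return list(self.data.index)

    def argmax_labels(self) -> pd.Series:
        return self.data.idxmax(axis=1)


def _check_classes(labels: Sequence[str], cv_folds: int) -> int:
    counts = pd.Series(list(labels)).value_counts()
    if len(counts) < 2:
        raise StratificationError("training labels cover fewer than 2 classes")
    if (counts < 2).any():
        ones = list(counts.index[counts < 2])
        raise StratificationError(
            f"class(es) {ones} have a single training member; merge or drop them"
        )
    folds = min(cv_folds, int(counts.min()))
    if folds < cv_folds:
        log.warning("reducing CV folds from %d to %d (smallest class has %d members)",
                    cv_folds, folds, int(counts.min()))
    return folds


_TREE_COUNTS = list(range(10, 101, 10))


def _staged_ensemble_search(
    spec: ClassifierSpec, X: np.ndarray, y: np.ndarray, cv: StratifiedKFold
) -> dict:
    """Exhaustive CV search over the RF/ABT grids without redundant fits.

    Both grids nest in the ensemble size: a warm-started forest grown to
    10, 20, ..., 100 trees consumes the same RNG stream as fresh fits at
    each size, and the first k stages of a 100-stage AdaBoost equal the
    k-stage fit, so one incremental fit per (fold, class[, criterion])
    yields every grid point's validation accuracy exactly.  Grid order (and
    hence the tie-break) matches the exhaustive search: criterion varies
    slowest, ensemble size fastest.
    """
    classes = np.unique(y)
    criteria = ["gini", "entropy"] if spec.kind == "RF" else [None]
    # scores[criterion][count] accumulates correct counts over folds
    correct = {(cr, k): 0 for cr in criteria for k in _TREE_COUNTS}
    total = 0
    for tr_idx, va_idx in cv.split(X, y):
        Xtr, Xva, ytr, yva = X[tr_idx], X[va_idx], y[tr_idx], y[va_idx]
        total += len(va_idx)
        for cr in criteria:
            # pos[count][i, j] = P(class j | sample i) before OvR renorm
            pos = {k: np.zeros((len(va_idx), len(classes))) for k in _TREE_COUNTS}
            for j, cls in enumerate(classes):
                ybin = (ytr == cls).astype(int)
                if spec.kind == "RF":
                    est = RandomForestClassifier(
                        n_estimators=0, warm_start=True, criterion=cr, random_state=spec.seed
                    )
                    for k in _TREE_COUNTS:
                        est.set_params(n_estimators=k)
                        est.fit(Xtr, ybin)
                        pos[k][:, j] = _positive_proba(est, Xva)
                else:
                    est = AdaBoostClassifier(n_estimators=_TREE_COUNTS[-1], random_state=spec.seed)
                    est.fit(Xtr, ybin)
                    staged = list(est.staged_predict_proba(Xva))
                    for k in _TREE_COUNTS:
                        stage = staged[min(k, len(staged)) - 1]  # early-stop pads with last
                        pos[k][:, j] = stage[:, list(est.classes_).index(1)]
            for k in _TREE_COUNTS:
                pred = classes[np.argmax(pos[k], axis=1)]
                correct[(cr, k)] += int((pred == yva).sum())
    best = max(
        ((cr, k) for cr in criteria for k in _TREE_COUNTS),
        key=lambda ck: (correct[ck], -criteria.index(ck[0]), -ck[1]),
    )
    chosen = {"estimator__n_estimators": best[1]}
    if spec.kind == "RF":
        chosen["estimator__criterion"] = best[0]
    return chosen


def _positive_proba(est, X: np.ndarray) -> np.ndarray:
    proba = est.predict_proba(X)
    cols = list(est.classes_)
    return proba[:, cols.index(1)] if 1 in cols else np.zeros(len(X))


def grid_fit(
    spec: ClassifierSpec,
    train: FeatureMatrix,
    labels: Sequence[str],
    frame: ClassFrame | None = None,
) -> FittedModel:
    """Exhaustive grid search by stratified CV accuracy, then refit on all rows.

    The search estimator skips SVM probability calibration for speed; the
    winning parameters are refitted once with calibration enabled so that
    `predict_probabilities` sees calibrated outputs.
    """
    y = np.asarray(list(labels), dtype=object)
    if len(y) != train.n:
        raise ContractError("label vector length does not match the feature matrix")
    folds = _check_classes(y, spec.cv_folds)
    X = train.data.to_numpy(dtype=float)

    grid = spec.grid
    if not grid:
        chosen = {}
    elif spec.kind in ("RF", "ABT"):
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=spec.seed)
        chosen = _staged_ensemble_search(spec, X, y, cv)
    else:
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=spec.seed)
        search = GridSearchCV(
            spec.build(with_probability=False),
            grid,
            scoring="accuracy",
            cv=cv,
            refit=False,
            n_jobs=None,
        )
        search.fit(X, y)
        chosen = dict(search.cv_results_["params"][search.best_index_])

    final = spec.build(with_probability=True)
    final.set_params(**chosen)
    final.fit(X, y)
    if frame is None:
        frame = ClassFrame(tuple(str(c) for c in final.classes_))
    return FittedModel(
        spec=spec,
        chosen_params=chosen,
        estimator=final,
        feature_columns=tuple(train.data.columns),
        train_ids=tuple(train.ids),
        frame=frame,
    )


def predict_probabilities(
    model: FittedModel, fm: FeatureMatrix, frame: ClassFrame | None = None
) -> ProbabilityMatrix:
    """Per-row OvR class probabilities over `frame` (defaults to the frame
    observed at fit time), renormalized to sum 1; an all-zero score row maps
    to the uniform vector.  Classes absent from training get probability 0.
    """
    if tuple(fm.data.columns) != model.feature_columns:
        raise SchemaError("feature columns do not match the model's training columns")
    frame = frame or model.frame
    X = fm.data.to_numpy(dtype=float)
    est = model.estimator
    fitted_classes = [str(c) for c in est.classes_]

    if model.spec.probability_mode == "softmax" and model.spec.kind == "SVM":
        scores = np.atleast_2d(est.decision_function(X))
        if scores.shape[1] == 1:  # binary OvR collapses to one column
            scores = np.hstack([-scores, scores])
        scores = scores - scores.max(axis=1, keepdims=True)
        pos = np.exp(scores)
    else:
        cols = [e.predict_proba(X)[:, list(e.classes_).index(1)] for e in est.estimators_]
        if len(cols) == 1 and len(fitted_classes) == 2:
            cols = [1.0 - cols[0], cols[0]]  # binary OvR keeps a single estimator
        pos = np.column_stack(cols)

    full = np.zeros((len(X), frame.c))
    for j, cls in enumerate(fitted_classes):
        full[:, frame.index_of(cls)] = pos[:, j]
    row_sums = full.sum(axis=1, keepdims=True)
    zero = row_sums[:, 0] <= 0
    full[zero] = 1.0 / frame.c
    row_sums[zero] = 1.0
    full = full / full.sum(axis=1, keepdims=True)
    df = pd.DataFrame(full, index=fm.ids, columns=list(frame.labels))
    return ProbabilityMatrix(df, classifier_index=model.spec.index)
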