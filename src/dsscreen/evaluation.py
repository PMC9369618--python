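"""Prediction accuracy Q, Cohen's kappa, and the repeated-split protocols.

Two figures of merit summarise a multi-class run.  Prediction accuracy is
the fraction of correctly classified samples, Q = n_correct / n.  Cohen's
kappa corrects Q for chance agreement computed from the marginals,

    p_e = sum_k (n_true,k * n_pred,k) / n**2,      K = (Q - p_e) / (1 - p_e),

so K = 1 means perfect agreement and K near 0 means chance-level output —
the more honest statistic when class sizes are uneven, as drug-category
data invariably are.

`repeated_evaluate` runs the full protocol: Kennard-Stone division,
grid-search fitting of the required base classifiers on the training set,
probability prediction on the test set, evidence fusion for each requested
fusion spec, and Q/kappa per model, repeated over seeded splits (the study
default is 100 repeats) to yield means and standard deviations.

`external_validate` is the second flow: per run it draws a per-class random
holdout out of the training pool, fits on the remainder, predicts the
holdout plus the multi-role molecules, and averages the predicted
probabilities over runs (default 3).  A single-role molecule is counted
correct when the averaged top-1 class equals its label; a multi-role
molecule when the top-1 class is among its roles (top-2 overlap is reported
alongside, since a multi-role drug's second activity often surfaces as the
second-ranked class).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classifiers import (
    CLASSIFIER_KINDS,
    ClassifierSpec,
    FittedModel,
    ProbabilityMatrix,
    grid_fit,
    predict_probabilities,
)
from .errors import ContractError, ParameterError, UndefinedKappaError
from .featurize import FeatureMatrix
from .fusion import FusionSpec, fuse_predictions
from .ks import ks_split
from .molecules import ClassFrame

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Metrics


def accuracy_q(truth: Sequence[str], predicted: Sequence[str]) -> float:
    """Fraction of samples predicted correctly."""
    if len(truth) != len(predicted):
        raise ContractError("truth and prediction lengths differ")
    if len(truth) == 0:
        raise ContractError("cannot score an empty label vector")
    t = np.asarray(list(truth), dtype=object)
    p = np.asarray(list(predicted), dtype=object)
    return float((t == p).mean())


def cohens_kappa(truth: Sequence[str], predicted: Sequence[str]) -> float:
    """Chance-corrected agreement K = (Q - p_e) / (1 - p_e)."""
    if len(truth) != len(predicted):
        raise ContractError("truth and prediction lengths differ")
    n = len(truth)
    if n < 2:
        raise ContractError("kappa needs at least 2 samples")
    t = pd.Series(list(truth), dtype=object)
    p = pd.Series(list(predicted), dtype=object)
    q = float((t == p).mean())
    classes = sorted(set(t) | set(p))
    tc = t.value_counts().reindex(classes, fill_value=0)
    pc = p.value_counts().reindex(classes, fill_value=0)
    pe = float((tc * pc).sum()) / n**2
    if pe >= 1.0:
        raise UndefinedKappaError("both label vectors are constant; kappa is undefined")
    return float((q - pe) / (1.0 - pe))


@dataclass(frozen=True)
class ConfusionMatrix:
    """c x c counts, rows = true class, columns = predicted class."""

    counts: pd.DataFrame

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())

    @classmethod
    def from_labels(
        cls, truth: Sequence[str], predicted: Sequence[str], frame: ClassFrame
    ) -> "ConfusionMatrix":
        labels = list(frame.labels)
        mat = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
        for t, p in zip(truth, predicted):
            mat.loc[t, p] += 1
        return cls(mat)


@dataclass(frozen=True)
class PerClassReport:
    """Diagonal read-off of the confusion matrix: per-class correct / size."""

    correct: Mapping[str, int]
    sizes: Mapping[str, int]

    @property
    def total_correct(self) -> int:
        return sum(self.correct.values())

    @property
    def total(self) -> int:
        return sum(self.sizes.values())


def per_class_correct(
    truth: Sequence[str], predicted: Sequence[str], frame: ClassFrame
) -> PerClassReport:
    """Per-class correct counts and group sizes; empty classes are kept as 0/0."""
    cm = ConfusionMatrix.from_labels(truth, predicted, frame)
    diag = {c: int(cm.counts.loc[c, c]) for c in frame.labels}
    sizes = {c: int(cm.counts.loc[c].sum()) for c in frame.labels}
    return PerClassReport(correct=diag, sizes=sizes)


# ---------------------------------------------------------------------------
# Model-name handling: "RF" ... "ABT" are single classifiers, "DS..." fusions.


def required_kinds(models: Sequence[str]) -> tuple[str, ...]:
    kinds: list[str] = []
    for name in models:
        if name.startswith("DS"):
            for k in FusionSpec.from_name(name).kinds:
                if k not in kinds:
                    kinds.append(k)
        elif name in CLASSIFIER_KINDS:
            if name not in kinds:
                kinds.append(name)
        else:
            raise ContractError(f"unknown model name {name!r}")
    return tuple(kinds)


def _model_probabilities(
    name: str, per_kind: Mapping[str, ProbabilityMatrix]
) -> ProbabilityMatrix:
    if name.startswith("DS"):
        spec = FusionSpec.from_name(name)
        return fuse_predictions(spec, [per_kind[k] for k in spec.kinds])
    return per_kind[name]


def _safe_kappa(truth, predicted) -> float:
    try:
        return cohens_kappa(truth, predicted)
    except UndefinedKappaError:
        log.warning("degenerate marginals in a repeat; recording kappa = 0")
        return 0.0


# ---------------------------------------------------------------------------
# Repeated-split protocol


@dataclass(frozen=True)
class EvaluationSummary:
    """Mean/sd of Q and kappa per model over the repeated splits."""

    raw: pd.DataFrame  # columns: repeat, model, q, kappa
    n_repeats: int

    def table(self) -> pd.DataFrame:
        g = self.raw.groupby("model", sort=False)
        out = pd.DataFrame(
            {
                "q_mean": g["q"].mean(),
                "q_std": g["q"].std(ddof=0),
                "kappa_mean": g["kappa"].mean(),
                "kappa_std": g["kappa"].std(ddof=0),
            }
        )
        out["n_repeats"] = self.n_repeats
        return out

    def best_model(self) -> str:
        """Kappa-first selection, Q as tie-break."""
        t = self.table().sort_values(["kappa_mean", "q_mean"], ascending=False)
        return str(t.index[0])


def fit_kinds(
    kinds: Sequence[str],
    train: FeatureMatrix,
    labels: Sequence[str],
    frame: ClassFrame,
    seed: int,
    cv_folds: int = 5,
) -> dict[str, FittedModel]:
    return {
        kind: grid_fit(ClassifierSpec(kind, cv_folds=cv_folds, seed=seed), train, labels, frame)
        for kind in kinds
    }


_REDRAW_STRIDE = 10_000_019  # seed offset between redraw attempts


def _stratifiable_split(data, y: pd.Series, fraction: float, seed: int, repeat_index: int):
    """Draw a random-start KS split whose training set keeps >= 2 members of
    every class (required by stratified CV); a violating split is rejected
    and redrawn deterministically from the next derived seed."""
    for attempt in range(50):
        split = ks_split(
            data, fraction, policy="random_start",
            seed=seed + attempt * _REDRAW_STRIDE, repeat_index=repeat_index,
        )
        if y.loc[list(split.train_ids)].value_counts().min() >= 2:
            if attempt:
                log.warning("repeat %d: redrew the KS split %d time(s) to keep every "
                            "class stratifiable", repeat_index, attempt)
            return split
    raise ContractError(
        "could not draw a training set with >= 2 members of every class; "
        "the smallest class is too small for this train fraction"
    )


def repeated_evaluate(
    data: FeatureMatrix,
    labels: Sequence[str],
    models: Sequence[str],
    frame: ClassFrame,
    n_repeats: int = 100,
    fraction: float = 0.75,
    base_seed: int = 0,
    cv_folds: int = 5,
) -> EvaluationSummary:
    """KS-split, fit, fuse and score every model over seeded repeats.

    `data` must already be cleaned and standardized; repeat i derives its
    split seed and CV seed from base_seed + i, so the whole summary is a
    pure function of its arguments.
    """
    if not models:
        raise ContractError("no models requested")
    kinds = required_kinds(models)
    y = pd.Series(list(labels), index=data.ids, dtype=object)

    rows = []
    for i in range(n_repeats):
        seed = base_seed + i
        split = _stratifiable_split(data, y, fraction, seed, i)
        train = data.subset(split.train_ids)
        test = data.subset(split.test_ids)
        fitted = fit_kinds(kinds, train, y.loc[list(split.train_ids)], frame, seed, cv_folds)
        per_kind = {k: predict_probabilities(m, test, frame) for k, m in fitted.items()}
        truth = list(y.loc[list(split.test_ids)])
        for name in models:
            pred = list(_model_probabilities(name, per_kind).argmax_labels())
            rows.append(
                {
                    "repeat": i,
                    "model": name,
                    "q": accuracy_q(truth, pred),
                    "kappa": _safe_kappa(truth, pred),
                }
            )
    raw = pd.DataFrame(rows)
    return EvaluationSummary(raw=raw, n_repeats=n_repeats)


# ---------------------------------------------------------------------------
# External validation (flow b)


@dataclass(frozen=True)
class ValidationReport:
    """Averaged probabilities and correctness counts for the validation flow."""

    probabilities: Mapping[str, pd.DataFrame]  # model -> molecule x class (run-averaged)
    per_class: Mapping[str, PerClassReport]    # model -> single-role counts
    multi_role_top1: Mapping[str, int]         # model -> top-1-in-roles count
    multi_role_top2: Mapping[str, int]         # model -> |top-2 ∩ roles| >= 1 count
    n_single: int
    n_multi: int
    n_runs: int


def external_validate(
    pool: FeatureMatrix,
    pool_labels: Sequence[str],
    holdout_counts: Mapping[str, int],
    multi: FeatureMatrix | None,
    multi_roles: Mapping[str, Sequence[str]] | None,
    models: Sequence[str],
    frame: ClassFrame,
    n_runs: int = 3,
    seed: int = 0,
    cv_folds: int = 5,
) -> ValidationReport:
    """Three-run external validation with per-run random per-class holdouts.

    Run r (seeded seed + 1000*r) draws `holdout_counts[k]` molecules of each
    class k out of the pool, fits the required base classifiers on the
    remainder, and predicts the holdout plus every multi-role molecule.
    Probabilities are averaged per molecule over the runs in which it was
    predicted (multi-role molecules appear in every run).
    """
    y = pd.Series(list(pool_labels), index=pool.ids, dtype=object)
    counts = y.value_counts()
    for cls, k in holdout_counts.items():
        if cls not in frame.labels:
            raise ParameterError(f"holdout class {cls!r} is not in the frame")
        if k > int(counts.get(cls, 0)):
            raise ParameterError(
                f"holdout of {k} exceeds the {int(counts.get(cls, 0))} pool members of class {cls!r}"
            )
    kinds = required_kinds(models)

    sums: dict[str, pd.DataFrame] = {}
    seen: dict[str, pd.Series] = {}
    for r in range(n_runs):
        rng = np.random.default_rng(seed + 1000 * r)
        held: list[str] = []
        for cls in frame.labels:
            k = int(holdout_counts.get(cls, 0))
            if k == 0:
                continue
            members = [i for i in pool.ids if y[i] == cls]
            held.extend(np.asarray(members, dtype=object)[rng.choice(len(members), size=k, replace=False)])
        rest_ids = [i for i in pool.ids if i not in set(held)]
        train = pool.subset(rest_ids)
        fitted = fit_kinds(kinds, train, y.loc[rest_ids], frame, seed + 1000 * r, cv_folds)

        target = pool.subset(held)
        if multi is not None and multi.n:
            target = FeatureMatrix(pd.concat([target.data, multi.data]), pool.family)
        per_kind = {k_: predict_probabilities(m, target, frame) for k_, m in fitted.items()}
        for name in models:
            probs = _model_probabilities(name, per_kind).data
            if name not in sums:
                cols = list(frame.labels)
                all_ids = list(pool.ids) + (list(multi.ids) if multi is not None else [])
                sums[name] = pd.DataFrame(0.0, index=all_ids, columns=cols)
                seen[name] = pd.Series(0, index=all_ids, dtype=int)
            sums[name].loc[probs.index] += probs
            seen[name].loc[probs.index] += 1

    probabilities: dict[str, pd.DataFrame] = {}
    per_class: dict[str, PerClassReport] = {}
    top1: dict[str, int] = {}
    top2: dict[str, int] = {}
    n_single = 0
    multi_ids = list(multi.ids) if multi is not None else []
    for name in models:
        mask = seen[name] > 0
        avg = sums[name].loc[mask].div(seen[name].loc[mask], axis=0)
        probabilities[name] = avg

        single_ids = [i for i in avg.index if i not in set(multi_ids)]
        n_single = len(single_ids)
        truth = list(y.loc[single_ids])
        pred = list(avg.loc[single_ids].idxmax(axis=1))
        per_class[name] = per_class_correct(truth, pred, frame)

        t1 = t2 = 0
        for mid in multi_ids:
            roles = set(multi_roles[mid])
            ranked = list(avg.loc[mid].sort_values(ascending=False).index)
            if ranked[0] in roles:
                t1 += 1
            if roles & set(ranked[:2]):
                t2 += 1
        top1[name] = t1
        top2[name] = t2

    return ValidationReport(
        probabilities=probabilities,
        per_class=per_class,
        multi_role_top1=top1,
        multi_role_top2=top2,
        n_single=n_single,
        n_multi=len(multi_ids),
        n_runs=n_runs,
    )
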