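"""RBF-SVM classification of skill level from distal force signals.

Each trial's whole-run, baseline-subtracted force modulus is decimated to
a fixed length n (n ∈ {32, 64, 128} by default) by keeping every
floor(k·T/n)-th sample, giving one feature vector per trial with its
expert/novice label.  A binary SVM with radial-basis-function kernel is
tuned by exhaustive grid search over C and gamma (standard libsvm-guide
ranges) and evaluated by repeated stratified k-fold cross-validation.
Per repeat, fold confusions are pooled before computing

    precision = tp / (tp + fp)
    recall    = tp / (tp + fn)
    accuracy  = (tp + tn) / (tp + tn + fp + fn)

with *expert* as the positive class (tp = experts classified as experts).
Zero-denominator measures are reported as NaN (missing), never as 0.
Feature columns are z-scored with statistics fit on training folds only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .distal_metrics import baseline_subtract, force_modulus
from .trial_model import Trial

__all__ = [
    "FeatureMatrix",
    "ConfusionCounts",
    "ClassificationReport",
    "resample_signal",
    "build_feature_matrix",
    "grid_search",
    "cross_validate",
    "performance_measures",
    "C_GRID",
    "GAMMA_GRID",
]

POSITIVE_CLASS = "expert"

#: libsvm-guide grids: C = 2^-5 .. 2^15, gamma = 2^-15 .. 2^3, steps of 2^2
C_GRID = tuple(2.0**e for e in range(-5, 16, 2))
GAMMA_GRID = tuple(2.0**e for e in range(-15, 4, 2))


@dataclass(frozen=True)
class FeatureMatrix:
    """Fixed-size resampled force vectors with skill labels."""

    features: np.ndarray  # (n_trials, n)
    labels: tuple[str, ...]
    n: int
    task: str | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.features, dtype=float)
        object.__setattr__(self, "features", f)
        object.__setattr__(self, "labels", tuple(self.labels))
        if f.ndim != 2 or f.shape[1] != self.n:
            raise ValueError(f"features must be (trials, {self.n})")
        if len(self.labels) != f.shape[0]:
            raise ValueError("label count must match row count")


@dataclass(frozen=True)
class ConfusionCounts:
    """Pooled binary confusion counts; expert is the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class ClassificationReport:
    """Repeated cross-validation performance with chosen hyperparameters."""

    per_repeat_accuracy: tuple[float, ...]
    per_repeat_precision: tuple[float, ...]
    per_repeat_recall: tuple[float, ...]
    mean_accuracy: float
    std_accuracy: float
    mean_precision: float
    std_precision: float
    mean_recall: float
    std_recall: float
    C: float
    gamma: float
    k: int
    n: int


def resample_signal(series: Sequence[float], n: int) -> np.ndarray:
    """Decimate a series of length T to exactly n values by keeping
    samples at indices floor(k·T/n), k = 0..n-1.  No upsampling."""
    x = np.asarray(series, dtype=float)
    T = x.shape[0]
    if n < 1:
        raise ValueError("n must be >= 1")
    if T < n:
        raise ValueError(f"series length {T} is shorter than n={n}; cannot upsample")
    idx = np.floor(np.arange(n) * T / n).astype(int)
    return x[idx]


def build_feature_matrix(trials: Sequence[Trial], n: int) -> FeatureMatrix:
    """One feature row per distal trial: the whole-run baseline-subtracted
    force modulus resampled to length n, labels attached."""
    if not trials:
        raise ValueError("no trials given")
    tasks = {t.task for t in trials}
    if len(tasks) > 1:
        raise ValueError(f"trials mix tasks {sorted(tasks)}; classify per task")
    rows, labels = [], []
    for trial in trials:
        ch = trial.channels.get("contact_force_xyz")
        if ch is None:
            raise ValueError(f"trial {trial.trial_id!r} is not a distal trial")
        mod = baseline_subtract(
            force_modulus(
                ch.values[:, 0], ch.values[:, 1], ch.values[:, 2], ch.timestamps
            )
        )
        rows.append(resample_signal(mod.modulus, n))
        labels.append(trial.skill)
    return FeatureMatrix(
        features=np.vstack(rows), labels=tuple(labels), n=n, task=tasks.pop()
    )


def _as_binary(labels: Sequence[str]) -> np.ndarray:
    return np.asarray([1 if lab == POSITIVE_CLASS else 0 for lab in labels])


def _make_model(C: float, gamma: float, standardize: bool) -> Pipeline:
    steps = []
    if standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(("svm", SVC(C=C, gamma=gamma, kernel="rbf")))
    return Pipeline(steps)


def _check_classes(y: np.ndarray, k: int) -> None:
    counts = np.bincount(y, minlength=2)
    if counts.min() == 0:
        raise ValueError("both classes must be present")
    if counts.min() < k:
        raise ValueError(
            f"need at least k={k} trials per class, got {counts.min()}"
        )


def grid_search(
    matrix: FeatureMatrix | np.ndarray,
    labels: Sequence[str] | None = None,
    k: int = 6,
    seed: int = 0,
    standardize: bool = True,
) -> tuple[float, float]:
    """Exhaustive (C, gamma) search maximizing mean stratified k-fold CV
    accuracy; ties break to the smallest C, then the smallest gamma."""
    X, y = _unpack(matrix, labels)
    _check_classes(y, k)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % 2**31)
    splits = list(skf.split(X, y))
    best: tuple[float, float, float] = (-1.0, math.nan, math.nan)
    for C in C_GRID:
        for gamma in GAMMA_GRID:
            correct = 0
            for train, test in splits:
                model = _make_model(C, gamma, standardize)
                model.fit(X[train], y[train])
                correct += int((model.predict(X[test]) == y[test]).sum())
            acc = correct / len(y)
            if acc > best[0]:
                best = (acc, C, gamma)
    return best[1], best[2]


def _unpack(
    matrix: FeatureMatrix | np.ndarray, labels: Sequence[str] | None
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(matrix, FeatureMatrix):
        return matrix.features, _as_binary(matrix.labels)
    if labels is None:
        raise ValueError("labels required when passing a bare feature array")
    return np.asarray(matrix, dtype=float), _as_binary(labels)


def performance_measures(
    counts: ConfusionCounts,
) -> tuple[float, float, float]:
    """(precision, recall, accuracy); undefined measures are NaN."""
    precision = (
        counts.tp / (counts.tp + counts.fp)
        if counts.tp + counts.fp > 0
        else math.nan
    )
    recall = (
        counts.tp / (counts.tp + counts.fn)
        if counts.tp + counts.fn > 0
        else math.nan
    )
    accuracy = (
        (counts.tp + counts.tn) / counts.total if counts.total > 0 else math.nan
    )
    return float(precision), float(recall), float(accuracy)


def cross_validate(
    matrix: FeatureMatrix | np.ndarray,
    labels: Sequence[str] | None = None,
    k: int = 6,
    repeats: int = 10,
    seed: int = 0,
    C: float | None = None,
    gamma: float | None = None,
    standardize: bool = True,
) -> ClassificationReport:
    """Repeated stratified k-fold cross-validation.

    If (C, gamma) are not given they are chosen by ``grid_search`` on the
    same data first.  Each repeat re-randomizes the fold partition, pools
    the k fold confusions and computes precision/recall/accuracy; the
    report carries per-repeat values and their means/standard deviations
    (NaN-aware, so undefined measures do not drag the mean to 0).
    """
    X, y = _unpack(matrix, labels)
    _check_classes(y, k)
    if C is None or gamma is None:
        C, gamma = grid_search(matrix, labels, k=k, seed=seed,
                               standardize=standardize)
    accs, precs, recs = [], [], []
    for r in range(repeats):
        skf = StratifiedKFold(
            n_splits=k, shuffle=True, random_state=(int(seed) + 1000 * (r + 1)) % 2**31
        )
        tp = tn = fp = fn = 0
        for train, test in skf.split(X, y):
            model = _make_model(C, gamma, standardize)
            model.fit(X[train], y[train])
            pred = model.predict(X[test])
            truth = y[test]
            tp += int(((pred == 1) & (truth == 1)).sum())
            tn += int(((pred == 0) & (truth == 0)).sum())
            fp += int(((pred == 1) & (truth == 0)).sum())
            fn += int(((pred == 0) & (truth == 1)).sum())
        p, rcl, acc = performance_measures(ConfusionCounts(tp, tn, fp, fn))
        precs.append(p)
        recs.append(rcl)
        accs.append(acc)
    n = X.shape[1]
    return ClassificationReport(
        per_repeat_accuracy=tuple(accs),
        per_repeat_precision=tuple(precs),
        per_repeat_recall=tuple(recs),
        mean_accuracy=float(np.nanmean(accs)),
        std_accuracy=float(np.nanstd(accs)),
        mean_precision=float(np.nanmean(precs)),
        std_precision=float(np.nanstd(precs)),
        mean_recall=float(np.nanmean(recs)),
        std_recall=float(np.nanstd(recs)),
        C=float(C),
        gamma=float(gamma),
        k=k,
        n=n,
    )
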