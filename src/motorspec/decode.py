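"""Decoding tasks: movement detection vs rest and 5-finger classification.

The classifier is a soft-margin SVM with Gaussian RBF kernel.  The penalty C
and kernel width gamma are picked by grid search over base-2 exponent grids
(C: 2^-10..2^20, gamma: 2^-15..2^10, unit steps -> 31 x 26 = 806 candidates)
using inner cross-validated accuracy on the training portion only.  Features
are linearly rescaled to [-1, +1] with training-fold minima/maxima.
Multiclass decoding uses one-vs-one majority voting with a deterministic tie
rule.  The outer protocol is seeded stratified 5-fold cross-validation
repeated 30 times; channel selection, scaling and grid search are refit
inside every training fold unless a fixed selection is supplied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .discrim import ChannelSelection, _rsq_channels, mu_beta_channels, select_channels, RsqMap
from .montage import Montage
from .spectral import BandPowerTable
from .specpca import ProjectionTable
from .synth import REST_LABEL

MOVEMENT_LABEL = "movement"

#: feature kinds whose channels come from C3 + neighbors instead of r² ranking
BAND_KINDS = ("alpha", "beta")


@dataclass(frozen=True)
class GridSpec:
    """Base-2 exponent grids for the SVM penalty C and RBF gamma."""

    c_exponents: tuple[int, ...] = tuple(range(-10, 21))
    gamma_exponents: tuple[int, ...] = tuple(range(-15, 11))
    base: float = 2.0

    @property
    def size(self) -> int:
        return len(self.c_exponents) * len(self.gamma_exponents)

    def candidates(self):
        for ce in self.c_exponents:
            for ge in self.gamma_exponents:
                yield self.base ** ce, self.base ** ge

    @classmethod
    def with_step(cls, step: int) -> "GridSpec":
        """Coarsened grid keeping the printed exponent ranges (desk-scale runs)."""
        return cls(c_exponents=tuple(range(-10, 21, step)),
                   gamma_exponents=tuple(range(-15, 11, step)))


@dataclass
class FeatureBank:
    """Per-kind (segments x channels) feature values plus segment labels."""

    values: dict[str, np.ndarray]
    labels: np.ndarray
    channel_labels: tuple[str, ...]
    montage: Montage | None = None

    @property
    def n_segments(self) -> int:
        return next(iter(self.values.values())).shape[0]

    def kinds(self) -> tuple[str, ...]:
        return tuple(self.values)


@dataclass
class FeatureMatrix:
    """Segments x features matrix with (kind, channel) provenance per column."""

    x: np.ndarray
    labels: np.ndarray
    provenance: tuple[tuple[str, str], ...]


@dataclass
class ScalerParams:
    """Per-feature training minima/maxima for the [-1, +1] linear rescaling."""

    minimum: np.ndarray
    maximum: np.ndarray


@dataclass
class Task:
    """One decoding problem: segment row indices, labels, ordered classes."""

    name: str
    indices: np.ndarray
    y: np.ndarray
    classes: tuple[str, ...]


@dataclass
class CvResult:
    """Repeated cross-validation outcome for one task and feature set."""

    task: str
    accuracies: np.ndarray  # (repeats, folds)
    confusion: np.ndarray  # (L, L), rows = predicted, columns = actual
    classes: tuple[str, ...]
    seed: int
    feature_kinds: tuple[str, ...] = ()

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def per_repeat_means(self) -> np.ndarray:
        return self.accuracies.mean(axis=1)

    @property
    def pooled_accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.sum())


@dataclass
class TTestResult:
    statistic: float
    pvalue: float
    df: int
    kind: str


def make_feature_bank(projections: ProjectionTable,
                      alpha: BandPowerTable | None = None,
                      beta: BandPowerTable | None = None,
                      montage: Montage | None = None) -> FeatureBank:
    """Bundle projection-weight and band-power features into one bank."""
    values = {f"PC{k + 1}": projections.weights[:, :, k]
              for k in range(projections.n_components)}
    for table in (alpha, beta):
        if table is not None:
            values[table.band] = table.values
    return FeatureBank(values=values, labels=projections.labels,
                       channel_labels=projections.channel_labels, montage=montage)


def build_tasks(labels: np.ndarray, fingers: tuple[str, ...]) -> tuple[Task, Task]:
    """Detection (all fingers pooled vs rest) and 5-finger tasks from segment labels."""
    labels = np.asarray(labels)
    if not (labels == REST_LABEL).any():
        raise ValueError("no rest segments present")
    for fin in fingers:
        if not (labels == fin).any():
            raise ValueError(f"no segments for finger {fin!r}")
    y_det = np.where(labels == REST_LABEL, REST_LABEL, MOVEMENT_LABEL).astype(object)
    detection = Task(name="detection", indices=np.arange(labels.size), y=y_det,
                     classes=(MOVEMENT_LABEL, REST_LABEL))
    move_idx = np.nonzero(labels != REST_LABEL)[0]
    finger = Task(name="fingers", indices=move_idx, y=labels[move_idx],
                  classes=tuple(fingers))
    return detection, finger


def assemble_features(bank: FeatureBank,
                      selection: dict[str, ChannelSelection | tuple[str, ...]],
                      kinds: tuple[str, ...],
                      rows: np.ndarray | None = None) -> FeatureMatrix:
    """Column-stack the selected channels of each kind (kind-major order)."""
    if not kinds:
        raise ValueError("no feature kinds requested")
    cols, prov = [], []
    ch_index = {ch: i for i, ch in enumerate(bank.channel_labels)}
    for kind in kinds:
        if kind not in bank.values:
            raise ValueError(f"feature kind {kind!r} not in the bank")
        sel = selection.get(kind)
        channels = sel.channels if isinstance(sel, ChannelSelection) else tuple(sel or ())
        if not channels:
            raise ValueError(f"empty channel selection for kind {kind!r}")
        vals = bank.values[kind]
        if rows is not None:
            vals = vals[rows]
        for ch in channels:
            cols.append(vals[:, ch_index[ch]])
            prov.append((kind, ch))
    labels = bank.labels if rows is None else bank.labels[rows]
    return FeatureMatrix(x=np.column_stack(cols), labels=labels,
                         provenance=tuple(prov))


def fit_scaler(x: np.ndarray) -> ScalerParams:
    if x.shape[0] < 1:
        raise ValueError("need at least one training row")
    return ScalerParams(minimum=x.min(axis=0), maximum=x.max(axis=0))


def apply_scaler(x: np.ndarray, params: ScalerParams) -> np.ndarray:
    """x' = 2 (x - min) / (max - min) - 1; constant features map to 0."""
    span = params.maximum - params.minimum
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(span > 0, 2.0 * (x - params.minimum) / span - 1.0, 0.0)
    return out


#: deterministic libsvm iteration cap; generous for separable problems while
#: bounding the pathological large-C corners of the grid on inseparable data
MAX_ITER = 10_000


def train_binary(x: np.ndarray, y: np.ndarray, grid: GridSpec | None = None,
                 seed: int = 0, inner_folds: int = 5) -> tuple[SVC, dict]:
    """Grid-searched RBF SVM; hyperparameters by inner cross-validated accuracy.

    Ties prefer the first candidate in grid order (C ascending, then gamma),
    so results are deterministic for a given seed.
    """
    grid = grid or GridSpec()
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data contains a single class")
    folds = min(inner_folds, int(min(np.sum(y == c) for c in classes)))
    if folds < 2:
        raise ValueError("too few samples per class for inner cross-validation")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % 2**31)
    splits = list(skf.split(x, y))
    best_acc, best_params = -1.0, None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for c_val, g_val in grid.candidates():
            correct = 0
            for tr, te in splits:
                clf = SVC(C=c_val, gamma=g_val, kernel="rbf", max_iter=MAX_ITER)
                clf.fit(x[tr], y[tr])
                correct += int((clf.predict(x[te]) == y[te]).sum())
            acc = correct / x.shape[0]
            if acc > best_acc:
                best_acc, best_params = acc, (c_val, g_val)
        clf = SVC(C=best_params[0], gamma=best_params[1], kernel="rbf",
                  max_iter=MAX_ITER)
        clf.fit(x, y)
    info = {"C": best_params[0], "gamma": best_params[1], "inner_accuracy": best_acc}
    return clf, info


def train_ovo(x: np.ndarray, y: np.ndarray, classes: tuple[str, ...],
              grid: GridSpec | None = None, seed: int = 0,
              inner_folds: int = 5) -> dict[tuple[str, str], SVC]:
    """One binary classifier per class pair (C(L, 2) in total)."""
    classifiers: dict[tuple[str, str], SVC] = {}
    for a, b in combinations(classes, 2):
        mask = (y == a) | (y == b)
        clf, _ = train_binary(x[mask], y[mask], grid=grid, seed=seed,
                              inner_folds=inner_folds)
        classifiers[(a, b)] = clf
    return classifiers


def ovo_predict(classifiers: dict[tuple[str, str], SVC], x: np.ndarray,
                classes: tuple[str, ...]) -> np.ndarray:
    """Majority vote over all pairwise classifiers.

    Ties break by the summed signed decision values over the tied labels,
    then by the smallest class index in ``classes``.
    """
    pairs = list(combinations(classes, 2))
    missing = [p for p in pairs if p not in classifiers]
    if missing:
        raise ValueError(f"missing pairwise classifiers: {missing}")
    n = x.shape[0]
    votes = np.zeros((n, len(classes)), dtype=int)
    margin = np.zeros((n, len(classes)))
    idx = {c: i for i, c in enumerate(classes)}
    for (a, b), clf in ((p, classifiers[p]) for p in pairs):
        dec = clf.decision_function(x)  # positive -> clf.classes_[1]
        pos = str(clf.classes_[1])
        # signed decision value toward each of the pair's labels
        sign = 1.0 if pos == b else -1.0
        votes[np.arange(n), np.where(sign * dec > 0, idx[b], idx[a])] += 1
        margin[:, idx[b]] += sign * dec
        margin[:, idx[a]] -= sign * dec
    out = np.empty(n, dtype=object)
    for i in range(n):
        top = votes[i].max()
        tied = np.nonzero(votes[i] == top)[0]
        if tied.size > 1:
            best = margin[i, tied].max()
            tied = tied[margin[i, tied] == best]
        out[i] = classes[int(tied.min())]
    return out


def _fold_selection(bank: FeatureBank, y_train: np.ndarray, train_rows: np.ndarray,
                    kinds: tuple[str, ...], classes: tuple[str, ...],
                    top_n: int) -> dict[str, ChannelSelection]:
    """Per-kind channels from training data only: r² ranking for PC kinds,
    C3 neighborhood for band kinds."""
    selection: dict[str, ChannelSelection] = {}
    pairs = list(combinations(classes, 2))
    for kind in kinds:
        if kind in BAND_KINDS:
            if bank.montage is None:
                raise ValueError("band-power kinds need a montage for C3 selection")
            selection[kind] = mu_beta_channels(bank.montage)
            continue
        vals = bank.values[kind][train_rows]
        maps = []
        for a, b in pairs:
            r = _rsq_channels(vals, y_train == a, y_train == b)
            maps.append(RsqMap(r=r, r2=r * r, channel_labels=bank.channel_labels,
                               montage_xy=np.zeros((len(bank.channel_labels), 2)),
                               pair=(a, b), feature=kind))
        selection[kind] = select_channels(maps, top_n=top_n)
    return selection


def cross_validate(bank: FeatureBank, task: Task, kinds: tuple[str, ...],
                   folds: int = 5, repeats: int = 30, seed: int = 0,
                   grid: GridSpec | None = None,
                   selection: dict[str, ChannelSelection] | None = None,
                   top_n: int = 10, inner_folds: int = 5) -> CvResult:
    """Seeded stratified k-fold CV repeated ``repeats`` times.

    Per outer fold: channel selection (unless ``selection`` fixes it), scaler
    fitting and hyperparameter grid search all use the training portion only;
    accuracy and the pooled predicted-by-actual confusion matrix come from
    the held-out fold.
    """
    grid = grid or GridSpec()
    y = task.y
    classes = task.classes
    counts = {c: int(np.sum(y == c)) for c in classes}
    small = [c for c, cnt in counts.items() if cnt < folds]
    if small:
        raise ValueError(f"classes smaller than the fold count: {small}")
    n = y.size
    acc = np.zeros((repeats, folds))
    conf = np.zeros((len(classes), len(classes)), dtype=int)
    cls_idx = {c: i for i, c in enumerate(classes)}
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=(seed * 1009 + rep) % 2**31)
        for fold, (tr, te) in enumerate(skf.split(np.zeros(n), y)):
            rows_tr = task.indices[tr]
            rows_te = task.indices[te]
            sel = selection or _fold_selection(bank, y[tr], rows_tr, kinds,
                                               classes, top_n)
            fm_tr = assemble_features(bank, sel, kinds, rows=rows_tr)
            fm_te = assemble_features(bank, sel, kinds, rows=rows_te)
            scaler = fit_scaler(fm_tr.x)
            x_tr = apply_scaler(fm_tr.x, scaler)
            x_te = apply_scaler(fm_te.x, scaler)
            fold_seed = (seed * 1009 + rep) * 31 + fold
            if len(classes) == 2:
                clf, _ = train_binary(x_tr, y[tr], grid=grid, seed=fold_seed,
                                      inner_folds=inner_folds)
                pred = clf.predict(x_te)
            else:
                classifiers = train_ovo(x_tr, y[tr], classes, grid=grid,
                                        seed=fold_seed, inner_folds=inner_folds)
                pred = ovo_predict(classifiers, x_te, classes)
            truth = y[te]
            acc[rep, fold] = float(np.mean(pred == truth))
            for p, a in zip(pred, truth):
                conf[cls_idx[str(p)], cls_idx[str(a)]] += 1
    return CvResult(task=task.name, accuracies=acc, confusion=conf,
                    classes=classes, seed=seed, feature_kinds=tuple(kinds))


def compare_accuracies(a: CvResult, b: "CvResult | float") -> TTestResult:
    """Two-sided t-test on per-repeat mean accuracies.

    Against a chance level (float): one-sample t-test.  Against another
    CvResult: paired t-test (repeat counts must match; run both results with
    the same seed so partitions pair up).
    """
    x = a.per_repeat_means
    if isinstance(b, CvResult):
        yv = b.per_repeat_means
        if yv.size != x.size:
            raise ValueError("paired test needs matching repeat counts")
        diff = x - yv
        kind = "paired"
    else:
        diff = x - float(b)
        kind = "one-sample"
    df = diff.size - 1
    if df < 1:
        raise ValueError("need at least two repeats for a t-test")
    if np.all(diff == diff[0]):
        if diff[0] == 0.0:
            return TTestResult(statistic=0.0, pvalue=1.0, df=df, kind=kind)
        return TTestResult(statistic=float(np.sign(diff[0]) * np.inf),
                           pvalue=0.0, df=df, kind=kind)
    t, p = stats.ttest_1samp(diff, 0.0)
    return TTestResult(statistic=float(t), pvalue=float(p), df=df, kind=kind)
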