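"""The three classification regimes with leave-one-run-out cross-validation.

* ``within_subject_cv`` — train and test on one subject's own runs.
* ``between_subject_cv`` — train on the actor's runs, test on the paired
  observer's held-out run, with no realignment.
* ``hyperclassify_cv`` — per fold, fit the two-view BCCA model on four
  paired unlabeled runs, realign the observer's held-out run into the
  actor's space, train the decoder on the actor's four runs only, and test
  on the realigned run.  The BCCA step never sees the test run or any label.

Hyperparameters (BCCA component count and classifier prior scale) are
selected leave-pair-out: each pair adopts the grid point maximizing mean
accuracy over all *other* pairs, so a pair's own data never influence its
own selection.  Empirical chance comes from relabeling permutations, and
means are reported with Student-t confidence intervals.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .bcca import fit_bcca, realign
from .classifier import predict_class, train_decoder
from .data_model import ACTIONS, DesignError, SampleSet

#: The candidate hyperparameter values scanned by default.
DEFAULT_PRIOR_SCALES = (0.01, 0.04, 0.21, 1.0, 4.64, 21.54, 100.0)
DEFAULT_COMPONENT_COUNTS = (20, 30, 40, 50, 60, 70, 80, 90, 100)


@dataclass(frozen=True)
class HyperparamGrid:
    prior_scales: tuple[float, ...] = DEFAULT_PRIOR_SCALES
    component_counts: tuple[int, ...] = DEFAULT_COMPONENT_COUNTS

    def points(self) -> list[tuple[int, float]]:
        """All (K, prior_scale) grid points, component-count major."""
        return list(itertools.product(self.component_counts, self.prior_scales))

    def midpoint(self) -> tuple[int, float]:
        return (
            self.component_counts[len(self.component_counts) // 2],
            self.prior_scales[len(self.prior_scales) // 2],
        )


@dataclass
class CvResult:
    """Cross-validated decoding outcome for one subject or pair."""

    fold_accuracy: list[float]
    fold_sizes: list[int]
    confusion: np.ndarray            # 4x4, rows = true class, in percent
    params: dict = field(default_factory=dict)
    n_correct: int = 0
    n_total: int = 0

    @property
    def accuracy(self) -> float:
        """Primary accuracy: mean over folds, in percent."""
        return float(np.mean(self.fold_accuracy))

    @property
    def pooled_accuracy(self) -> float:
        """Alternative accuracy pooled over all test samples, in percent."""
        return 100.0 * self.n_correct / self.n_total if self.n_total else np.nan

    def to_dict(self) -> dict:
        return {
            "accuracy_percent": round(self.accuracy, 1),
            "pooled_accuracy_percent": round(self.pooled_accuracy, 1),
            "fold_accuracy_percent": [round(a, 1) for a in self.fold_accuracy],
            "fold_sizes": self.fold_sizes,
            "confusion_percent": np.round(self.confusion, 1).tolist(),
            "params": self.params,
        }


def _check_runs_have_all_classes(s: SampleSet) -> None:
    for r in s.runs:
        present = set(s.y[s.run == r])
        missing = set(ACTIONS) - present
        if missing:
            raise DesignError(f"run {r} is missing classes {sorted(missing)}")


def _check_paired(actor: SampleSet, observer: SampleSet) -> None:
    if actor.n_samples != observer.n_samples:
        raise DesignError("actor/observer sample counts differ")
    if not np.array_equal(actor.run, observer.run) or not np.array_equal(
        actor.y, observer.y
    ):
        raise DesignError("actor/observer designs are not paired")


def _confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    idx = {a: i for i, a in enumerate(ACTIONS)}
    c = np.zeros((4, 4))
    for t, p in zip(y_true, y_pred):
        c[idx[t], idx[p]] += 1
    return c


def _finalize(fold_acc, fold_sizes, counts, params) -> CvResult:
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        confusion = np.where(row_sums > 0, 100.0 * counts / row_sums, 0.0)
    return CvResult(
        fold_accuracy=fold_acc,
        fold_sizes=fold_sizes,
        confusion=confusion,
        params=params,
        n_correct=int(np.trace(counts)),
        n_total=int(counts.sum()),
    )


# ---------------------------------------------------------------------------
# Regimes
# ---------------------------------------------------------------------------

def within_subject_cv(
    s: SampleSet, prior_scale: float = 1.0, seed: int = 0
) -> CvResult:
    """Leave-one-run-out decoding within a single subject."""
    runs = s.runs
    if len(runs) < 2:
        raise DesignError("within-subject CV needs at least 2 runs")
    _check_runs_have_all_classes(s)
    fold_acc, fold_sizes = [], []
    counts = np.zeros((4, 4))
    for r in runs:
        train, test = s.split_run(r)
        dec = train_decoder(train, prior_scale, seed)
        pred, _ = predict_class(dec, test)
        fold_acc.append(100.0 * float(np.mean(pred == test.y)))
        fold_sizes.append(test.n_samples)
        counts += _confusion_counts(test.y, pred)
    return _finalize(fold_acc, fold_sizes, counts, {"prior_scale": prior_scale})


def between_subject_cv(
    actor: SampleSet,
    observer: SampleSet,
    prior_scale: float = 1.0,
    seed: int = 0,
) -> CvResult:
    """Train on the actor's runs, test on the observer's held-out run.

    No realignment: this measures whether the raw voxel patterns already
    line up anatomically between the two brains.
    """
    _check_paired(actor, observer)
    _check_runs_have_all_classes(actor)
    fold_acc, fold_sizes = [], []
    counts = np.zeros((4, 4))
    for r in actor.runs:
        a_train, _ = actor.split_run(r)
        _, o_test = observer.split_run(r)
        dec = train_decoder(a_train, prior_scale, seed)
        pred, _ = predict_class(dec, o_test)
        fold_acc.append(100.0 * float(np.mean(pred == o_test.y)))
        fold_sizes.append(o_test.n_samples)
        counts += _confusion_counts(o_test.y, pred)
    return _finalize(fold_acc, fold_sizes, counts, {"prior_scale": prior_scale})


def hyperclassify_cv(
    actor: SampleSet,
    observer: SampleSet,
    K: int = 20,
    prior_scale: float = 1.0,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> CvResult:
    """Brain-to-brain decoding with per-fold functional realignment.

    Per fold: BCCA is fitted on the four paired training runs (unlabeled),
    the held-out observer run is realigned into actor space, the decoder is
    trained on the actor's (standardized) four runs, and tested on the
    realigned run.
    """
    _check_paired(actor, observer)
    _check_runs_have_all_classes(actor)
    fold_acc, fold_sizes, n_shared = [], [], []
    counts = np.zeros((4, 4))
    for r in actor.runs:
        try:
            a_train, _ = actor.split_run(r)
            o_train, o_test = observer.split_run(r)
            model = fit_bcca(a_train, o_train, K=K, seed=seed,
                             max_iter=max_iter, tol=tol)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # zero-shared warning: chance fold
                realigned = realign(model, o_test)
            a_train_std = SampleSet(
                model.standardize_actor(a_train.x), a_train.y,
                a_train.run, a_train.trial,
            )
            dec = train_decoder(a_train_std, prior_scale, seed)
            pred, _ = predict_class(dec, realigned)
        except Exception as exc:
            raise RuntimeError(f"hyperclassification failed in fold run={r}") from exc
        fold_acc.append(100.0 * float(np.mean(pred == realigned.y)))
        fold_sizes.append(realigned.n_samples)
        n_shared.append(model.n_shared)
        counts += _confusion_counts(realigned.y, pred)
    return _finalize(
        fold_acc, fold_sizes, counts,
        {"K": K, "prior_scale": prior_scale, "n_shared_per_fold": n_shared},
    )


def realigned_timeseries(
    actor: SampleSet,
    observer: SampleSet,
    K: int = 20,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> SampleSet:
    """Cross-validated realignment of the observer's full session.

    Each run is realigned by a model fitted on the other four runs, and the
    realigned runs are reassembled in original sample order.  Output is in
    standardized actor units (per-voxel correlations are scale-invariant,
    so ISC computations can compare it directly against the actor).
    """
    _check_paired(actor, observer)
    out = np.zeros((observer.n_samples, actor.n_voxels))
    for r in actor.runs:
        a_train, _ = actor.split_run(r)
        o_train, o_test = observer.split_run(r)
        model = fit_bcca(a_train, o_train, K=K, seed=seed,
                         max_iter=max_iter, tol=tol)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            realigned = realign(model, o_test)
        out[observer.run == r] = realigned.x
    return SampleSet(out, observer.y, observer.run, observer.trial,
                     voxel_index=actor.voxel_index)


# ---------------------------------------------------------------------------
# Hyperparameter optimization (leave-pair-out)
# ---------------------------------------------------------------------------

def optimize_hyperparams(
    pairs: Sequence[tuple[SampleSet, SampleSet]],
    grid: HyperparamGrid = HyperparamGrid(),
    seed: int = 0,
    **cv_kwargs,
) -> list[tuple[int, float]]:
    """Select (K, prior_scale) per pair by leave-pair-out accuracy.

    Every grid point is scored once per pair with ``hyperclassify_cv``
    (fixed seed for comparability); pair *i* then adopts the point with the
    best mean score over all other pairs, so its own data never influence
    its own selection.  With a single pair the grid midpoint is returned
    with a warning.
    """
    points = grid.points()
    if len(pairs) < 2:
        warnings.warn(
            "leave-pair-out selection needs >= 2 pairs; using grid midpoint",
            stacklevel=2,
        )
        return [grid.midpoint() for _ in pairs]
    if len(points) == 1:
        return [points[0] for _ in pairs]

    scores = np.empty((len(pairs), len(points)))
    for i, (a, o) in enumerate(pairs):
        for g, (k, ps) in enumerate(points):
            scores[i, g] = hyperclassify_cv(
                a, o, K=k, prior_scale=ps, seed=seed, **cv_kwargs
            ).accuracy
    chosen = []
    for i in range(len(pairs)):
        others = np.delete(scores, i, axis=0).mean(axis=0)
        chosen.append(points[int(np.argmax(others))])
    return chosen


def optimize_prior_scale(
    subjects: Sequence[SampleSet],
    prior_scales: Sequence[float] = DEFAULT_PRIOR_SCALES,
    seed: int = 0,
) -> list[float]:
    """Within-subject analogue: leave-subject-out prior-scale selection."""
    if len(subjects) < 2:
        warnings.warn(
            "leave-subject-out selection needs >= 2 subjects; using midpoint",
            stacklevel=2,
        )
        return [prior_scales[len(prior_scales) // 2] for _ in subjects]
    scores = np.empty((len(subjects), len(prior_scales)))
    for i, s in enumerate(subjects):
        for g, ps in enumerate(prior_scales):
            scores[i, g] = within_subject_cv(s, prior_scale=ps, seed=seed).accuracy
    chosen = []
    for i in range(len(subjects)):
        others = np.delete(scores, i, axis=0).mean(axis=0)
        chosen.append(prior_scales[int(np.argmax(others))])
    return chosen


# ---------------------------------------------------------------------------
# Chance and confidence intervals
# ---------------------------------------------------------------------------

def _permute_within_run(y: np.ndarray, run: np.ndarray, rng) -> np.ndarray:
    out = y.copy()
    for r in np.unique(run):
        idx = np.flatnonzero(run == r)
        out[idx] = y[idx[rng.permutation(len(idx))]]
    return out


def empirical_chance(
    regime_fn: Callable[..., CvResult],
    data: SampleSet | tuple[SampleSet, SampleSet],
    n_perm: int = 100,
    seed: int = 0,
    **kwargs,
) -> tuple[np.ndarray, float]:
    """Empirical chance distribution via training-label permutations.

    For each permutation the training-side labels (the single subject's
    labels, or the actor's labels for paired regimes) are permuted within
    run — preserving per-fold class balance — and the regime re-run.
    Returns ``(accuracies, mean)`` in percent.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    accs = np.empty(n_perm)
    for p in range(n_perm):
        if isinstance(data, tuple):
            actor, observer = data
            y_perm = _permute_within_run(actor.y, actor.run, rng)
            a = SampleSet(actor.x, y_perm, actor.run, actor.trial,
                          voxel_index=actor.voxel_index)
            o = SampleSet(observer.x, y_perm, observer.run, observer.trial,
                          voxel_index=observer.voxel_index)
            accs[p] = regime_fn(a, o, **kwargs).accuracy
        else:
            y_perm = _permute_within_run(data.y, data.run, rng)
            s = SampleSet(data.x, y_perm, data.run, data.trial,
                          voxel_index=data.voxel_index)
            accs[p] = regime_fn(s, **kwargs).accuracy
    return accs, float(accs.mean())


def mean_accuracy_ci(
    acc: Sequence[float], level: float = 0.95
) -> tuple[float, float, float]:
    """Student-t confidence interval for a mean accuracy: (mean, lo, hi)."""
    acc = np.asarray(acc, dtype=float)
    n = len(acc)
    if n < 2:
        raise ValueError("need at least 2 accuracy values for a CI")
    mean = float(acc.mean())
    sem = float(acc.std(ddof=1) / np.sqrt(n))
    t = stats.t.ppf(0.5 + level / 2.0, df=n - 1)
    return mean, mean - t * sem, mean + t * sem


def chance_band(
    n: int, p: float = 0.25, level: float = 0.95
) -> tuple[float, float]:
    """Binomial band (percent) around chance for n test samples."""
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(p * (1 - p) / n)
    return 100.0 * (p - half), 100.0 * (p + half)
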