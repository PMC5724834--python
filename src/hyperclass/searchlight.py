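"""Searchlight kNN diagnostic: localized actor-observer trial similarity.

Within a small spherical voxel neighbourhood (19 voxels for a 6-mm radius on
a 4-mm grid), every actor trial and observer trial is summarized by its
flattened scans x voxels pattern (3 x 19 = 57 points) and all pairwise
Pearson correlations form a trials x trials matrix (120 x 120 canonically).
Each observer trial is then classified by majority vote among its k most
correlated actor trials, averaging accuracy over a k-grid (1 to 120 step 6)
to wash out small-k noise sensitivity.  Comparing accuracy maps before and
after realignment localizes where realignment added action information; the
map contrast uses a sign-flip permutation t-test with BH-FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .data_model import DesignError, SampleSet

DEFAULT_K_VALUES = tuple(range(1, 121, 6))


@dataclass
class SearchlightSpec:
    radius_mm: float
    voxel_size_mm: float
    offsets: np.ndarray

    @property
    def n_voxels(self) -> int:
        return len(self.offsets)

    def to_dict(self) -> dict:
        return {
            "radius_mm": self.radius_mm,
            "voxel_size_mm": self.voxel_size_mm,
            "n_voxels": self.n_voxels,
        }


def make_searchlight(radius_mm: float, voxel_size_mm: float = 4.0) -> SearchlightSpec:
    """All integer-grid offsets within a Euclidean radius (centre included)."""
    if radius_mm < 0 or voxel_size_mm <= 0:
        raise DesignError("radius must be >= 0 and voxel size > 0")
    reach = int(radius_mm // voxel_size_mm)
    offsets = [
        (dx, dy, dz)
        for dx in range(-reach, reach + 1)
        for dy in range(-reach, reach + 1)
        for dz in range(-reach, reach + 1)
        if (dx * dx + dy * dy + dz * dz) * voxel_size_mm**2 <= radius_mm**2 + 1e-9
    ]
    return SearchlightSpec(radius_mm, voxel_size_mm, np.array(offsets, dtype=int))


@dataclass
class TrialCorrelationMatrix:
    """Actor-trials x observer-trials Pearson correlations in one searchlight."""

    c: np.ndarray
    actor_labels: np.ndarray
    observer_labels: np.ndarray
    center: tuple[int, int, int] | None = None
    partial: bool = False
    zero_variance: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.zero_variance is None:
            self.zero_variance = np.zeros_like(self.c, dtype=bool)


def _trial_patterns(s: SampleSet, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial flattened scans x voxels patterns, plus per-trial labels."""
    trials = np.unique(s.trial)
    pats, labels = [], []
    for t in trials:
        rows = np.flatnonzero(s.trial == t)
        pats.append(s.x[np.ix_(rows, cols)].ravel())
        labels.append(s.y[rows[0]])
    return np.vstack(pats), np.array(labels, dtype=object)


def trial_correlation_matrix(
    actor: SampleSet,
    observer: SampleSet,
    sl: SearchlightSpec,
    center: tuple[int, int, int],
) -> TrialCorrelationMatrix:
    """Correlate every actor trial with every observer trial in one searchlight.

    Entry (i, j) is the Pearson r between actor trial i's and observer trial
    j's flattened voxels x scans patterns.  Searchlights poking out of the
    ROI keep their in-mask voxels and are flagged partial.  Zero-variance
    patterns yield r = 0 with the flag set.
    """
    if actor.voxel_index is None or observer.voxel_index is None:
        raise DesignError("sample sets need voxel_index geometry for searchlights")
    lookup = {tuple(v): i for i, v in enumerate(actor.voxel_index)}
    wanted = np.asarray(center) + sl.offsets
    cols = np.array([lookup[tuple(w)] for w in map(tuple, wanted) if tuple(w) in lookup])
    if len(cols) == 0:
        raise DesignError(f"searchlight at {center} contains no in-mask voxels")
    partial = len(cols) < sl.n_voxels

    pa, la = _trial_patterns(actor, cols)
    po, lo = _trial_patterns(observer, cols)
    pa = pa - pa.mean(axis=1, keepdims=True)
    po = po - po.mean(axis=1, keepdims=True)
    na = np.sqrt(np.sum(pa**2, axis=1))
    no = np.sqrt(np.sum(po**2, axis=1))
    flat_a = na < 1e-12
    flat_o = no < 1e-12
    na = np.where(flat_a, 1.0, na)
    no = np.where(flat_o, 1.0, no)
    c = (pa / na[:, None]) @ (po / no[:, None]).T
    zero_var = flat_a[:, None] | flat_o[None, :]
    c = np.where(zero_var, 0.0, np.clip(c, -1.0, 1.0))
    return TrialCorrelationMatrix(c, la, lo, tuple(center), partial, zero_var)


def knn_classify(
    m: TrialCorrelationMatrix,
    k_values: tuple[int, ...] = DEFAULT_K_VALUES,
) -> float:
    """Mean kNN accuracy over the k-grid, classifying observer trials.

    For each observer trial (one column of the matrix), actor trials are
    ranked by correlation; the majority class among the top k is the
    prediction, with ties broken toward the class of the single most
    correlated trial among the tied classes.  k values exceeding the trial
    count are clamped with a warning.  Rank-based, hence invariant to any
    monotone transform of the correlations.
    """
    n_actor = m.c.shape[0]
    ks = []
    for k in k_values:
        if k > n_actor:
            warnings.warn(f"k={k} clamped to {n_actor} trials", stacklevel=2)
            k = n_actor
        ks.append(k)
    order = np.argsort(-m.c, axis=0, kind="stable")  # per column, best first
    classes = np.unique(m.actor_labels)
    class_of = {c: i for i, c in enumerate(classes)}
    n_obs = m.c.shape[1]
    correct = np.zeros(len(ks))
    for j in range(n_obs):
        ranked = np.array([class_of[l] for l in m.actor_labels[order[:, j]]])
        onehot = np.zeros((n_actor, len(classes)))
        onehot[np.arange(n_actor), ranked] = 1.0
        cum = onehot.cumsum(axis=0)
        # earliest rank at which each class appears (tie-break key)
        first_rank = np.full(len(classes), n_actor)
        for pos in range(n_actor - 1, -1, -1):
            first_rank[ranked[pos]] = pos
        truth = class_of.get(m.observer_labels[j], -1)
        for ki, k in enumerate(ks):
            votes = cum[k - 1]
            tied = votes == votes.max()
            pred = np.flatnonzero(tied)[np.argmin(first_rank[tied])]
            correct[ki] += pred == truth
    return float(np.mean(100.0 * correct / n_obs))


def searchlight_accuracy_map(
    actor: SampleSet,
    observer: SampleSet,
    sl: SearchlightSpec,
    centers: np.ndarray,
    k_values: tuple[int, ...] = DEFAULT_K_VALUES,
) -> np.ndarray:
    """Mean kNN accuracy at every searchlight centre (percent)."""
    return np.array([
        knn_classify(trial_correlation_matrix(actor, observer, sl, tuple(c)), k_values)
        for c in np.asarray(centers)
    ])


@dataclass
class SearchlightContrast:
    diff: np.ndarray               # mean post - pre accuracy, percentage points
    t: np.ndarray
    p: np.ndarray
    significant: np.ndarray        # FDR-significant
    display_mask: np.ndarray       # significant AND gain > 5 points


def searchlight_accuracy_contrast(
    pre_maps: np.ndarray,
    post_maps: np.ndarray,
    n_perm: int = 1000,
    q: float = 0.05,
    seed: int = 0,
    min_gain: float = 5.0,
) -> SearchlightContrast:
    """Permutation t-test of post-vs-pre accuracy maps across pairs.

    ``pre_maps``/``post_maps`` are pairs x searchlights accuracy arrays.
    The null flips the sign of each pair's difference map (``n_perm``
    draws); per-searchlight p-values are BH-FDR corrected at ``q``.  The
    display mask additionally requires a gain above ``min_gain`` points.
    """
    pre_maps = np.atleast_2d(np.asarray(pre_maps, dtype=float))
    post_maps = np.atleast_2d(np.asarray(post_maps, dtype=float))
    if pre_maps.shape != post_maps.shape:
        raise DesignError("pre/post searchlight maps must align")
    n_pairs = pre_maps.shape[0]
    if n_pairs < 2:
        raise DesignError("need at least 2 pairs for the contrast")

    d = post_maps - pre_maps
    t_obs = _paired_t(d)

    rng = np.random.default_rng(seed)
    exceed = np.ones_like(t_obs)       # +1 smoothing: observed stat included
    for _ in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n_pairs)
        t_null = _paired_t(d * signs[:, None])
        exceed += np.abs(t_null) >= np.abs(t_obs)
    p = exceed / (n_perm + 1)
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    mean_d = d.mean(axis=0)
    return SearchlightContrast(
        diff=mean_d, t=t_obs, p=p, significant=reject,
        display_mask=reject & (mean_d > min_gain),
    )


def _paired_t(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    sd = d.std(axis=0, ddof=1)
    sd = np.where(sd < 1e-12, np.inf, sd)
    return d.mean(axis=0) / (sd / np.sqrt(n))
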