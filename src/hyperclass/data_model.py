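"""Core data structures: BOLD run matrices, trial tables, ROI masks and
the deterministic bookkeeping that turns them into classifier-ready samples.

The experimental design this package targets is a four-action motor task
(power grip, precision grip, slap, point) acquired at TR = 2 s in 5 runs of
24 trials (6 per action).  Each trial contributes the 3 scans recorded while
the action was executed or viewed, shifted by the ~6 s haemodynamic lag, so
a full session yields 5 x 24 x 3 = 360 labelled samples per subject.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The fixed action-category label set, in canonical (class-index) order.
ACTIONS: tuple[str, ...] = ("power_grip", "precision_grip", "slap", "point")

#: Canonical design constants: runs, trials per run, retained scans per trial.
CANONICAL_N_RUNS = 5
CANONICAL_TRIALS_PER_RUN = 24
CANONICAL_SCANS_PER_TRIAL = 3


class DesignError(ValueError):
    """Raised when inputs violate the experimental design contracts."""


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------

@dataclass
class VolumeSeries:
    """A masked BOLD run: a scans x voxels matrix plus grid geometry.

    Parameters
    ----------
    data:
        Real-valued matrix of shape ``(n_scans, n_voxels)``.
    tr:
        Repetition time in seconds (sampling interval of the scans).
    run_id:
        Integer identifier of the acquisition run.
    voxel_index:
        Integer array of shape ``(n_voxels, 3)`` giving the 3D grid
        coordinate of each matrix column.
    affine:
        4x4 grid-to-mm map (NIfTI convention).
    """

    data: np.ndarray
    tr: float
    run_id: int
    voxel_index: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.voxel_index = np.asarray(self.voxel_index, dtype=int)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 1:
            raise DesignError("data must be a scans x voxels matrix with >= 1 scan")
        if self.tr <= 0:
            raise DesignError(f"tr must be positive, got {self.tr}")
        if self.voxel_index.shape != (self.data.shape[1], 3):
            raise DesignError(
                f"voxel_index shape {self.voxel_index.shape} does not match "
                f"{self.data.shape[1]} data columns"
            )
        if self.affine.shape != (4, 4):
            raise DesignError("affine must be 4x4")

    @property
    def n_scans(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# Trial tables
# ---------------------------------------------------------------------------

@dataclass
class TrialTable:
    """Event table: one row per trial with run, onset scan, label, duration.

    Scan indexing is 0-based and trial windows are half-open
    ``[onset, onset + duration)``.  Labels must come from :data:`ACTIONS`.
    """

    frame: pd.DataFrame

    COLUMNS = ("run", "onset_scan", "label", "duration_scans")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.frame.columns]
        if missing:
            raise DesignError(f"trial table missing columns {missing}")
        bad = set(self.frame["label"]) - set(ACTIONS)
        if bad:
            raise DesignError(f"labels outside the 4-action set: {sorted(bad)}")
        self.frame = self.frame.reset_index(drop=True)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[int, int, str, int]]
    ) -> "TrialTable":
        return cls(pd.DataFrame(records, columns=list(cls.COLUMNS)))

    @classmethod
    def from_tsv(cls, path) -> "TrialTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def for_run(self, run_id: int) -> pd.DataFrame:
        return self.frame[self.frame["run"] == run_id]

    @property
    def n_trials(self) -> int:
        return len(self.frame)

    def class_counts(self) -> dict[str, int]:
        counts = self.frame["label"].value_counts().to_dict()
        return {a: int(counts.get(a, 0)) for a in ACTIONS}


# ---------------------------------------------------------------------------
# Samples
# ---------------------------------------------------------------------------

@dataclass
class SampleSet:
    """Labelled samples x voxels matrix — the classifier's currency.

    ``trial`` carries a globally unique (run-major) trial index so that
    trial-level operations (searchlight correlation matrices, trial-level
    shuffling) can regroup samples.  ``voxel_index`` is optional grid
    geometry carried through from the source volumes.
    """

    x: np.ndarray
    y: np.ndarray
    run: np.ndarray
    trial: np.ndarray
    voxel_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y)
        self.run = np.asarray(self.run, dtype=int)
        self.trial = np.asarray(self.trial, dtype=int)
        n = len(self.x)
        if not (len(self.y) == len(self.run) == len(self.trial) == n):
            raise DesignError("x, y, run, trial lengths disagree")
        if self.voxel_index is not None:
            self.voxel_index = np.asarray(self.voxel_index, dtype=int)
            if self.x.size and self.voxel_index.shape[0] != self.x.shape[1]:
                raise DesignError("voxel_index length must equal voxel count")

    @property
    def n_samples(self) -> int:
        return len(self.x)

    @property
    def n_voxels(self) -> int:
        return self.x.shape[1] if self.x.ndim == 2 else 0

    @property
    def runs(self) -> np.ndarray:
        return np.unique(self.run)

    def subset(self, mask: np.ndarray) -> "SampleSet":
        mask = np.asarray(mask)
        return SampleSet(
            self.x[mask], self.y[mask], self.run[mask], self.trial[mask],
            voxel_index=self.voxel_index,
        )

    def split_run(self, run_id: int) -> tuple["SampleSet", "SampleSet"]:
        """Return (training set = other runs, test set = ``run_id``)."""
        held = self.run == run_id
        return self.subset(~held), self.subset(held)

    def select_voxels(self, cols: np.ndarray) -> "SampleSet":
        vi = None if self.voxel_index is None else self.voxel_index[cols]
        return SampleSet(self.x[:, cols], self.y, self.run, self.trial, voxel_index=vi)

    def class_counts(self) -> dict[str, int]:
        vals, counts = np.unique(self.y, return_counts=True)
        out = dict(zip(vals.tolist(), counts.tolist()))
        return {a: int(out.get(a, 0)) for a in ACTIONS}


def extract_samples(
    volumes: VolumeSeries | Sequence[VolumeSeries],
    trials: TrialTable,
    lag_seconds: float = 6.0,
    scans_per_trial: int = CANONICAL_SCANS_PER_TRIAL,
) -> SampleSet:
    """Cut labelled samples out of BOLD runs at haemodynamically lagged windows.

    For each trial, the scans at ``onset + lag/tr ... onset + lag/tr +
    scans_per_trial - 1`` become samples carrying the trial's label.  Sample
    order is run-major, trial-minor (table order within run), scan-innermost.
    The lag must be an integer number of TRs; a window that extends past the
    end of its run is a hard error naming the trial.
    """
    if isinstance(volumes, VolumeSeries):
        volumes = [volumes]
    run_map = {vs.run_id: vs for vs in volumes}

    xs: list[np.ndarray] = []
    ys: list[str] = []
    runs: list[int] = []
    trial_ids: list[int] = []
    voxel_index = volumes[0].voxel_index if volumes else None

    trial_counter = 0
    for vs in volumes:
        lag_ratio = lag_seconds / vs.tr
        lag_scans = int(round(lag_ratio))
        if abs(lag_ratio - lag_scans) > 1e-9:
            raise DesignError(
                f"lag {lag_seconds}s is not an integer number of TRs (tr={vs.tr}s)"
            )
        sub = trials.for_run(vs.run_id)
        for row in sub.itertuples(index=False):
            start = int(row.onset_scan) + lag_scans
            stop = start + scans_per_trial
            if start < 0 or stop > vs.n_scans:
                raise DesignError(
                    f"trial (run={row.run}, onset_scan={row.onset_scan}, "
                    f"label={row.label}) window [{start}, {stop}) exceeds run "
                    f"length {vs.n_scans}"
                )
            xs.append(vs.data[start:stop])
            ys.extend([row.label] * scans_per_trial)
            runs.extend([vs.run_id] * scans_per_trial)
            trial_ids.extend([trial_counter] * scans_per_trial)
            trial_counter += 1

    n_vox = volumes[0].n_voxels if volumes else 0
    if not xs:
        return SampleSet(
            np.empty((0, n_vox)), np.array([], dtype=object),
            np.array([], dtype=int), np.array([], dtype=int),
            voxel_index=voxel_index,
        )
    return SampleSet(
        np.vstack(xs), np.array(ys, dtype=object), np.array(runs),
        np.array(trial_ids), voxel_index=voxel_index,
    )


# ---------------------------------------------------------------------------
# ROI masks
# ---------------------------------------------------------------------------

@dataclass
class RoiMask:
    """A possibly non-contiguous voxel set used as a single feature mask."""

    grid: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    voxel_size: float = 4.0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.grid.ndim != 3:
            raise DesignError("ROI grid must be 3D")

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())

    def voxel_coords(self) -> np.ndarray:
        """Grid coordinates of in-mask voxels in raster (C) order."""
        return np.argwhere(self.grid)

    def _check_geometry(self, other: "RoiMask") -> None:
        if self.grid.shape != other.grid.shape or not np.allclose(
            self.affine, other.affine
        ):
            raise DesignError("ROI geometry mismatch (shape or affine)")


def build_roi_from_statmap(statmap: np.ndarray, threshold: float,
                           affine: np.ndarray | None = None,
                           voxel_size: float = 4.0) -> RoiMask:
    """Threshold a statistical map at ``value > threshold`` and binarize.

    An empty result is legal (warning only): thresholded localizer maps are
    feature-selection filters, and the caller decides how to react.
    """
    statmap = np.asarray(statmap, dtype=float)
    if not np.all(np.isfinite(statmap)):
        raise DesignError("statistical map contains non-finite values")
    grid = statmap > threshold
    if not grid.any():
        warnings.warn("thresholded statistical map is empty", stacklevel=2)
    return RoiMask(grid, affine if affine is not None else np.eye(4), voxel_size)


def combine_rois(masks: Sequence[RoiMask], mode: str) -> RoiMask:
    """Voxelwise boolean algebra on masks sharing one grid geometry.

    ``union`` and ``intersection`` fold over the whole list; ``subtract``
    removes every later mask from the first (the typical use is excluding
    primary visual cortex from a distributed functional ROI).
    """
    if not masks:
        raise DesignError("no masks to combine")
    first = masks[0]
    for m in masks[1:]:
        first._check_geometry(m)
    grids = [m.grid for m in masks]
    if mode == "union":
        out = np.logical_or.reduce(grids)
    elif mode == "intersection":
        out = np.logical_and.reduce(grids)
    elif mode == "subtract":
        out = grids[0].copy()
        for g in grids[1:]:
            out &= ~g
    else:
        raise DesignError(f"unknown combine mode {mode!r}")
    return RoiMask(out, first.affine, first.voxel_size)


# ---------------------------------------------------------------------------
# Down-sampling
# ---------------------------------------------------------------------------

def downsample_volume(vs: VolumeSeries, factor: int) -> VolumeSeries:
    """Down-sample a run to a coarser grid by block averaging.

    Each output voxel is the mean of its ``factor**3`` source block; blocks
    that extend past a non-divisible grid edge average over the voxels they
    do contain (pad-and-average).  Columns absent from the (masked) series
    simply do not contribute.  The affine's spatial part is scaled by
    ``factor`` so output voxels map to the centre-of-block positions at the
    coarser resolution.
    """
    if factor < 1 or int(factor) != factor:
        raise DesignError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return VolumeSeries(vs.data.copy(), vs.tr, vs.run_id,
                            vs.voxel_index.copy(), vs.affine.copy())

    block = vs.voxel_index // factor
    # group source columns by destination block, raster order of blocks
    order = np.lexsort((block[:, 2], block[:, 1], block[:, 0]))
    sorted_blocks = block[order]
    uniq, start_idx, counts = np.unique(
        sorted_blocks, axis=0, return_index=True, return_counts=True
    )
    n_scans = vs.n_scans
    out = np.empty((n_scans, len(uniq)))
    for j, (s, c) in enumerate(zip(start_idx, counts)):
        cols = order[s: s + c]
        out[:, j] = vs.data[:, cols].mean(axis=1)
    new_affine = vs.affine.copy()
    new_affine[:3, :3] *= factor
    return VolumeSeries(out, vs.tr, vs.run_id, uniq, new_affine)
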