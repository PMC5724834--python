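"""Falsification probes: each must drive hyperclassification to chance.

If realignment merely matched noise between two brains, hyperclassification
would survive (a) destroying the temporal pairing between observer and
actor, (b) replacing the observer with spectrum-matched noise, or (c)
running in brain regions carrying no task signal.  Each probe therefore
re-runs the full realignment + decoding pipeline under one of those
manipulations and should land at the 25% four-class chance level.
"""

from __future__ import annotations

import numpy as np

from .bcca import BccaError
from .data_model import DesignError, RoiMask, SampleSet
from .pipeline import CvResult, hyperclassify_cv


def shuffle_time(
    s: SampleSet, seed: int = 0, mode: str = "permute", unit: str = "scan"
) -> SampleSet:
    """Destroy the temporal pairing of a sample set's data rows.

    The data rows are permuted (or circularly shifted, ``mode='shift'``)
    while labels, runs and trials keep their ORIGINAL temporal association,
    so the data no longer match their own annotations — exactly the
    mismatch a noise-matching realignment model would be fooled by.
    ``unit='trial'`` permutes whole trials instead of single scans.
    """
    rng = np.random.default_rng(seed)
    n = s.n_samples
    if mode == "shift":
        shift = int(rng.integers(1, n)) if n > 1 else 0
        perm = np.roll(np.arange(n), shift)
    elif mode == "permute":
        if unit == "scan":
            perm = rng.permutation(n)
        elif unit == "trial":
            trials = np.unique(s.trial)
            trial_perm = rng.permutation(len(trials))
            rows_by_trial = [np.flatnonzero(s.trial == t) for t in trials]
            perm = np.concatenate([rows_by_trial[i] for i in trial_perm])
        else:
            raise DesignError(f"unknown shuffle unit {unit!r}")
    else:
        raise DesignError(f"unknown shuffle mode {mode!r}")
    return SampleSet(s.x[perm], s.y, s.run, s.trial, voxel_index=s.voxel_index)


def surrogate_bold(s: SampleSet, seed: int = 0) -> SampleSet:
    """Phase-randomized surrogate preserving each voxel's amplitude spectrum.

    Treats each voxel's sample sequence as a time series, keeps the
    amplitude spectrum (hence mean, variance and autocorrelation
    structure) and replaces all phases by uniform draws with conjugate
    symmetry, destroying any alignment with the experimental timeline.
    """
    x = np.asarray(s.x, dtype=float)
    n = x.shape[0]
    if n < 8:
        raise DesignError("surrogate generation needs >= 8 time points")
    rng = np.random.default_rng(seed)
    spec = np.fft.rfft(x, axis=0)
    n_freq = spec.shape[0]
    phases = rng.uniform(0, 2 * np.pi, size=(n_freq, x.shape[1]))
    phases[0] = 0.0                      # keep DC (the mean) real
    if n % 2 == 0:
        phases[-1] = 0.0                 # Nyquist bin must stay real
    surrogate = np.fft.irfft(np.abs(spec) * np.exp(1j * phases), n=n, axis=0)
    return SampleSet(surrogate, s.y, s.run, s.trial, voxel_index=s.voxel_index)


def control_roi_suite(
    pairs: list[tuple[SampleSet, SampleSet]],
    control_masks: list[RoiMask],
    K: int = 20,
    prior_scale: float = 1.0,
    seed: int = 0,
    **cv_kwargs,
) -> dict[int, list[CvResult]]:
    """Hyperclassification restricted to task-unrelated control regions.

    For each control mask, the full pipeline runs per pair on the voxels
    inside the mask; accuracies should sit at chance when the region holds
    no shared task signal.  Empty masks are a hard error.
    """
    results: dict[int, list[CvResult]] = {}
    for mi, mask in enumerate(control_masks):
        if mask.n_voxels == 0:
            raise DesignError(f"control mask {mi} is empty")
        wanted = {tuple(v) for v in mask.voxel_coords()}
        per_pair = []
        for actor, observer in pairs:
            if actor.voxel_index is None:
                raise DesignError("sample sets need voxel_index to apply a mask")
            cols = np.array(
                [i for i, v in enumerate(actor.voxel_index) if tuple(v) in wanted]
            )
            if len(cols) == 0:
                raise BccaError(f"control mask {mi} shares no voxels with the data")
            per_pair.append(
                hyperclassify_cv(
                    actor.select_voxels(cols), observer.select_voxels(cols),
                    K=K, prior_scale=prior_scale, seed=seed, **cv_kwargs,
                )
            )
        results[mi] = per_pair
    return results
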