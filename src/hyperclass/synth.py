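"""Paired actor-observer BOLD simulator with known ground truth.

The generator emulates the motor-action study design: two views (an actor
performing four hand actions, an observer watching the same trials), 5 runs
of 24 trials (6 per action), 3 retained scans per trial at TR = 2 s with a
6-s haemodynamic lag.  Action-specific latent time courses (trial boxcars
convolved with a double-gamma haemodynamic kernel peaking at the lag) drive
*shared* components; each view adds its own specific components and
temporally autocorrelated AR(1) noise.

The key knob is ``misalignment``: with ``rotation`` the observer's shared
loadings are a random orthogonal mix of the actor's over the signal voxels,
so the two brains carry the same action information in spatially
incompatible voxel patterns — decodable within each subject, opaque across
subjects without functional realignment.  That is exactly the regime the
hyperclassification method exists for, and it is the package's benchmark.

Voxels sit on a compact 3D grid (4-mm spacing); the signal voxels form a
contiguous block so that cluster-level diagnostics have a planted region to
find.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.stats import gamma as gamma_dist, ortho_group

from .data_model import ACTIONS, DesignError, SampleSet, TrialTable, VolumeSeries, extract_samples

MISALIGNMENTS = ("none", "rotation", "permutation")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator configuration; defaults reproduce the canonical design."""

    n_runs: int = 5
    trials_per_run: int = 24
    scans_per_trial: int = 3
    tr_s: float = 2.0
    lag_s: float = 6.0
    n_voxels: int = 500
    n_signal_voxels: int = 160
    n_shared: int = 4
    n_actor_specific: int = 3
    n_observer_specific: int = 3
    effect_size: float = 0.1        # class-latent amplitude at HRF peak, in noise-sd units
    noise_sd: float = 1.0
    ar1_coef: float = 0.3
    misalignment: str = "rotation"
    seed: int = 0
    trial_spacing_scans: int = 10   # onset-to-onset interval within a run
    lead_in_scans: int = 4
    tail_scans: int = 8
    voxel_size_mm: float = 4.0

    @property
    def n_classes(self) -> int:
        return len(ACTIONS)

    @property
    def run_length_scans(self) -> int:
        return (
            self.lead_in_scans
            + self.trials_per_run * self.trial_spacing_scans
            + self.tail_scans
        )

    def validate(self) -> None:
        problems = []
        if self.trials_per_run % self.n_classes:
            problems.append("trials_per_run must be divisible by the class count")
        for name in ("n_runs", "trials_per_run", "scans_per_trial", "n_voxels",
                     "n_signal_voxels", "trial_spacing_scans"):
            if getattr(self, name) < 1:
                problems.append(f"{name} must be positive")
        if self.n_shared < self.n_classes:
            problems.append("n_shared must cover one latent per class")
        if self.n_signal_voxels > self.n_voxels:
            problems.append("n_signal_voxels exceeds n_voxels")
        if self.misalignment not in MISALIGNMENTS:
            problems.append(f"misalignment must be one of {MISALIGNMENTS}")
        if abs(self.lag_s / self.tr_s - round(self.lag_s / self.tr_s)) > 1e-9:
            problems.append("lag must be an integer number of TRs")
        lag = int(round(self.lag_s / self.tr_s))
        last_stop = (
            self.lead_in_scans
            + (self.trials_per_run - 1) * self.trial_spacing_scans
            + lag + self.scans_per_trial
        )
        if last_stop > self.run_length_scans:
            problems.append("lag-shifted trial windows do not fit inside the run")
        if not (0 <= self.ar1_coef < 1):
            problems.append("ar1_coef must be in [0, 1)")
        if problems:
            raise DesignError("invalid synthetic config: " + "; ".join(problems))


@dataclass
class SyntheticPair:
    """Generated actor + observer session with stored ground truth."""

    actor: list[VolumeSeries]
    observer: list[VolumeSeries]
    trials: TrialTable
    truth: dict
    config: SyntheticConfig


def hrf_kernel(tr_s: float, peak_s: float = 6.0, length_s: float = 30.0) -> np.ndarray:
    """Double-gamma haemodynamic kernel sampled at TR, unit peak.

    The positive lobe peaks at ``peak_s`` (matching the lag the sampling
    window compensates for) and a small undershoot follows at ~16 s.
    """
    t = np.arange(0, length_s + tr_s / 2, tr_s)
    peak = gamma_dist.pdf(t, peak_s + 1.0, scale=1.0)
    undershoot = gamma_dist.pdf(t, 16.0, scale=1.0)
    h = peak - undershoot / 6.0
    return h / h.max()


def _ar1(rng: np.random.Generator, shape: tuple[int, int], coef: float,
         sd: float) -> np.ndarray:
    """AR(1) series along axis 0 with marginal standard deviation ``sd``."""
    innov = rng.standard_normal(shape) * sd * np.sqrt(max(1.0 - coef**2, 1e-12))
    return lfilter([1.0], [1.0, -coef], innov, axis=0)


def _grid_coords(n_voxels: int) -> np.ndarray:
    side = int(np.ceil(n_voxels ** (1.0 / 3.0)))
    coords = np.array(
        [(x, y, z) for x in range(side) for y in range(side) for z in range(side)]
    )
    return coords[:n_voxels]


def _trial_table(cfg: SyntheticConfig, rng: np.random.Generator) -> TrialTable:
    rows = []
    for run in range(cfg.n_runs):
        labels = np.repeat(ACTIONS, cfg.trials_per_run // cfg.n_classes)
        labels = labels[rng.permutation(len(labels))]
        for t, lab in enumerate(labels):
            rows.append(
                (run, cfg.lead_in_scans + t * cfg.trial_spacing_scans,
                 str(lab), cfg.scans_per_trial)
            )
    return TrialTable.from_records(rows)


def generate_pair(cfg: SyntheticConfig) -> SyntheticPair:
    """Generate one paired actor-observer dataset (seed-deterministic)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    trials = _trial_table(cfg, rng)
    n_scans = cfg.run_length_scans
    hrf = hrf_kernel(cfg.tr_s, peak_s=cfg.lag_s)

    # --- shared latents: one HRF-convolved boxcar train per class, plus ----
    # --- optional extra smooth shared structure -----------------------------
    z_shared = np.zeros((cfg.n_runs, n_scans, cfg.n_shared))
    for run in range(cfg.n_runs):
        sub = trials.for_run(run)
        for c, action in enumerate(ACTIONS):
            box = np.zeros(n_scans)
            for row in sub.itertuples(index=False):
                if row.label == action:
                    box[row.onset_scan: row.onset_scan + row.duration_scans] = 1.0
            z_shared[run, :, c] = np.convolve(box, hrf)[:n_scans] * cfg.effect_size
    n_extra = cfg.n_shared - cfg.n_classes
    if n_extra > 0:
        for run in range(cfg.n_runs):
            z_shared[run, :, cfg.n_classes:] = _ar1(
                rng, (n_scans, n_extra), 0.9, cfg.effect_size
            )

    # --- loadings -----------------------------------------------------------
    coords = _grid_coords(cfg.n_voxels)
    signal_mask = np.zeros(cfg.n_voxels, dtype=bool)
    signal_mask[: cfg.n_signal_voxels] = True

    w_actor = np.zeros((cfg.n_voxels, cfg.n_shared))
    w_actor[signal_mask] = rng.standard_normal((cfg.n_signal_voxels, cfg.n_shared))
    w_observer = w_actor.copy()
    if cfg.misalignment == "rotation":
        r = ortho_group.rvs(cfg.n_signal_voxels, random_state=rng)
        w_observer[signal_mask] = r @ w_actor[signal_mask]
    elif cfg.misalignment == "permutation":
        perm = rng.permutation(cfg.n_signal_voxels)
        w_observer[signal_mask] = w_actor[signal_mask][perm]

    w_spec = {
        "actor": rng.standard_normal((cfg.n_voxels, cfg.n_actor_specific)),
        "observer": rng.standard_normal((cfg.n_voxels, cfg.n_observer_specific)),
    }

    # --- assemble runs ------------------------------------------------------
    affine = np.diag([cfg.voxel_size_mm] * 3 + [1.0])
    views: dict[str, list[VolumeSeries]] = {"actor": [], "observer": []}
    specs = {"actor": cfg.n_actor_specific, "observer": cfg.n_observer_specific}
    loadings = {"actor": w_actor, "observer": w_observer}
    z_spec_store: dict[str, list[np.ndarray]] = {"actor": [], "observer": []}
    for run in range(cfg.n_runs):
        for view in ("actor", "observer"):
            data = z_shared[run] @ loadings[view].T
            z_sp = _ar1(rng, (n_scans, specs[view]), 0.8, cfg.effect_size)
            z_spec_store[view].append(z_sp)
            data = data + z_sp @ w_spec[view].T
            data = data + _ar1(rng, (n_scans, cfg.n_voxels), cfg.ar1_coef,
                               cfg.noise_sd)
            views[view].append(
                VolumeSeries(data, cfg.tr_s, run, coords, affine)
            )

    truth = {
        "z_shared": z_shared,
        "z_specific": {v: np.stack(z_spec_store[v]) for v in z_spec_store},
        "W_shared": {"actor": w_actor, "observer": w_observer},
        "W_specific": w_spec,
        "signal_mask": signal_mask,
        "class_latent_index": {a: i for i, a in enumerate(ACTIONS)},
    }
    return SyntheticPair(views["actor"], views["observer"], trials, truth, cfg)


def pair_samples(pair: SyntheticPair) -> tuple[SampleSet, SampleSet]:
    """Extract the paired labelled sample sets from a generated session."""
    cfg = pair.config
    a = extract_samples(pair.actor, pair.trials, cfg.lag_s, cfg.scans_per_trial)
    o = extract_samples(pair.observer, pair.trials, cfg.lag_s, cfg.scans_per_trial)
    return a, o


def oracle_report(pair: SyntheticPair) -> dict:
    """Ground-truth summary for recovery scoring.

    Returns orthonormal bases of the true shared subspace per view, the
    signal-voxel mask, and each class's mean latent amplitude over its own
    lag-shifted sample windows.
    """
    cfg = pair.config
    truth = pair.truth
    bases = {}
    for view in ("actor", "observer"):
        q, _ = np.linalg.qr(truth["W_shared"][view])
        bases[view] = q

    lag = int(round(cfg.lag_s / cfg.tr_s))
    class_means = {}
    for action, c in truth["class_latent_index"].items():
        vals = []
        for run in range(cfg.n_runs):
            sub = pair.trials.for_run(run)
            for row in sub.itertuples(index=False):
                if row.label == action:
                    s = row.onset_scan + lag
                    vals.append(truth["z_shared"][run, s: s + cfg.scans_per_trial, c])
        class_means[action] = float(np.mean(vals))
    return {
        "shared_basis": bases,
        "signal_mask": truth["signal_mask"],
        "class_latent_means": class_means,
        "config": pair.config,
    }


def benchmark_pair(seed: int = 0, **overrides) -> SyntheticPair:
    """The default misaligned benchmark pair at a given seed."""
    return generate_pair(replace(SyntheticConfig(seed=seed), **overrides))
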