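"""Readers, writers and run configuration.

Volumes and masks travel as NIfTI-1 (optionally gzipped), event tables as
TSV, configurations and results as JSON.  Every results directory carries a
manifest with SHA-256 checksums, the seed and a config hash so a run is
verifiable and reproducible from (config, seed, inputs) alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .data_model import DesignError, RoiMask, TrialTable, VolumeSeries
from .synth import SyntheticConfig, SyntheticPair, generate_pair


# ---------------------------------------------------------------------------
# NIfTI round trips
# ---------------------------------------------------------------------------

def load_bold(
    path,
    mask: RoiMask | None = None,
    run_id: int = 0,
    tr: float | None = None,
    discard_leading: int = 0,
) -> VolumeSeries:
    """Read a 4D NIfTI run into a masked scans x voxels matrix.

    With no mask, all voxels are kept in raster order.  ``discard_leading``
    drops initial scans (dummy volumes before magnetization steady state).
    The mask's grid shape and affine must match the image.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise DesignError(f"{path} is not a 4D volume")
    if mask is not None:
        if mask.grid.shape != data.shape[:3] or not np.allclose(
            mask.affine, img.affine
        ):
            raise DesignError("mask geometry does not match the volume")
        coords = mask.voxel_coords()
    else:
        shape = data.shape[:3]
        coords = np.argwhere(np.ones(shape, dtype=bool))
    mat = data[coords[:, 0], coords[:, 1], coords[:, 2], :].T
    if discard_leading:
        mat = mat[discard_leading:]
    if tr is None:
        tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 2.0
        if tr <= 0:
            tr = 2.0
    return VolumeSeries(mat, tr, run_id, coords, img.affine)


def save_bold(vs: VolumeSeries, path) -> None:
    """Write a (masked) run back to 4D NIfTI on its bounding grid."""
    shape = tuple(vs.voxel_index.max(axis=0) + 1)
    vol = np.zeros(shape + (vs.n_scans,))
    vol[vs.voxel_index[:, 0], vs.voxel_index[:, 1], vs.voxel_index[:, 2], :] = vs.data.T
    img = nib.Nifti1Image(vol, vs.affine)
    img.header.set_zooms(tuple(np.abs(np.diag(vs.affine)[:3])) + (vs.tr,))
    nib.save(img, str(path))


def load_mask(path, voxel_size: float = 4.0) -> RoiMask:
    img = nib.load(str(path))
    return RoiMask(np.asanyarray(img.dataobj) > 0, img.affine, voxel_size)


def save_mask(mask: RoiMask, path) -> None:
    nib.save(nib.Nifti1Image(mask.grid.astype(np.uint8), mask.affine), str(path))


# ---------------------------------------------------------------------------
# Simulated-session layout
# ---------------------------------------------------------------------------

def write_pair(pair: SyntheticPair, out_dir) -> Path:
    """Write a generated pair as NIfTI + TSV in the standard subject layout.

    ``out_dir/{actor,observer}/run-<i>.nii.gz`` plus a shared
    ``events.tsv`` per subject and a ``config.json`` at the root, so
    simulated sessions flow through exactly the same readers as real data.
    """
    out = Path(out_dir)
    for view, runs in (("actor", pair.actor), ("observer", pair.observer)):
        d = out / view
        d.mkdir(parents=True, exist_ok=True)
        for vs in runs:
            save_bold(vs, d / f"run-{vs.run_id}.nii.gz")
        pair.trials.to_tsv(d / "events.tsv")
    (out / "config.json").write_text(json.dumps(asdict(pair.config), indent=2))
    return out


def read_subject(subject_dir, mask: RoiMask | None = None,
                 tr: float | None = None,
                 discard_leading: int = 0) -> tuple[list[VolumeSeries], TrialTable]:
    """Read one subject directory (run-*.nii.gz + events.tsv)."""
    d = Path(subject_dir)
    runs = []
    paths = sorted(d.glob("run-*.nii*"),
                   key=lambda p: int(p.name.split("-")[1].split(".")[0]))
    if not paths:
        raise DesignError(f"no run-*.nii[.gz] files in {d}")
    for p in paths:
        run_id = int(p.name.split("-")[1].split(".")[0])
        runs.append(load_bold(p, mask=mask, run_id=run_id, tr=tr,
                              discard_leading=discard_leading))
    return runs, TrialTable.from_tsv(d / "events.tsv")


def simulate_to_dir(cfg: SyntheticConfig, out_dir) -> Path:
    return write_pair(generate_pair(cfg), out_dir)


# ---------------------------------------------------------------------------
# Run configuration and results
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Declarative description of one analysis run."""

    actor_dir: str
    observer_dir: str | None = None
    mode: str = "hyper"
    roi_path: str | None = None
    K: int = 20
    prior_scale: float = 1.0
    seed: int = 0
    out_dir: str = "results"
    verbosity: int = 1
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        cfg = cls(**json.loads(Path(path).read_text()))
        cfg.check_paths()
        return cfg

    def check_paths(self) -> None:
        for p in (self.actor_dir, self.observer_dir, self.roi_path):
            if p is not None and not Path(p).exists():
                raise DesignError(f"configured path does not exist: {p}")

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_results(
    results: dict,
    out_dir,
    seed: int = 0,
    config: RunConfig | dict | None = None,
    maps: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
) -> dict:
    """Emit results JSON (+ optional NIfTI maps) with a checksum manifest.

    ``maps`` values are (3D array, affine) tuples.  Accuracies inside
    ``results`` should already be percentages rounded to one decimal.  On
    any failure, files written so far are removed (partial-write cleanup).
    Returns the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        rp = out / "results.json"
        rp.write_text(json.dumps({"seed": seed, **results}, indent=2, sort_keys=True))
        written.append(rp)
        for name, (vol, affine) in (maps or {}).items():
            mp = out / f"{name}.nii.gz"
            nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float32), affine), str(mp))
            written.append(mp)
        manifest = {
            "seed": seed,
            "config_hash": (
                config.content_hash() if isinstance(config, RunConfig)
                else hashlib.sha256(
                    json.dumps(config, sort_keys=True).encode()
                ).hexdigest()[:16] if config is not None else None
            ),
            "artifacts": {p.name: _sha256(p) for p in written},
        }
        mp = out / "manifest.json"
        mp.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def verify_manifest(out_dir) -> bool:
    """Re-hash every artifact listed in the manifest; True iff all match."""
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    return all(
        (out / name).exists() and _sha256(out / name) == digest
        for name, digest in manifest["artifacts"].items()
    )
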