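"""File I/O: PCD raw recordings, NIfTI maps, TIFF images, YAML configs.

PCD recordings are stored as raw little-endian float32 with a JSON sidecar
carrying the acquisition metadata (sampling rate, drive frequency, pulse
markers); MRI volumes and parametric maps as NIfTI-1 with the voxel size in
the affine; fluorescence images and masks as 16-bit TIFF.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile
import yaml

from .cavitation import DoseSeries, PCDRecording
from .mri import QuantMap

__all__ = [
    "write_pcd",
    "read_pcd",
    "write_pcd_csv",
    "write_nifti",
    "read_nifti",
    "write_quantmap",
    "write_tiff",
    "read_tiff",
    "load_yaml",
    "dump_yaml",
    "write_doses_csv",
]


def write_pcd(recording: PCDRecording, raw_path, sidecar_path=None) -> Path:
    """Write samples as raw little-endian float32 plus a JSON sidecar."""
    raw_path = Path(raw_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else raw_path.with_suffix(".json")
    np.asarray(recording.samples, dtype="<f4").tofile(raw_path)
    meta = {
        "sampling_rate": recording.sampling_rate,
        "f0": recording.f0,
        "pulse_starts": [int(s) for s in recording.pulse_starts],
        "pulse_length": recording.pulse_length,
        "dtype": "<f4",
        "n_samples": int(recording.samples.size),
    }
    sidecar_path.write_text(json.dumps(meta, indent=1, sort_keys=True))
    return raw_path


def read_pcd(raw_path, sidecar_path=None) -> PCDRecording:
    raw_path = Path(raw_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else raw_path.with_suffix(".json")
    meta = json.loads(sidecar_path.read_text())
    samples = np.fromfile(raw_path, dtype=meta.get("dtype", "<f4"))
    return PCDRecording(
        samples=samples,
        sampling_rate=meta["sampling_rate"],
        f0=meta["f0"],
        pulse_starts=np.asarray(meta["pulse_starts"], dtype=np.int64),
        pulse_length=meta["pulse_length"],
    )


def write_pcd_csv(recording: PCDRecording, path) -> Path:
    """Optional CSV export: sample_index,amplitude."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_index", "amplitude"])
        for i, v in enumerate(recording.samples):
            w.writerow([i, float(v)])
    return path


def write_nifti(volume: np.ndarray, voxel_size, path) -> Path:
    """Write a volume as NIfTI-1, RAS+ affine scaled by the voxel size (mm)."""
    path = Path(path)
    affine = np.diag([voxel_size[0], voxel_size[1], voxel_size[2], 1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), str(path))
    return path


def read_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    return np.asarray(img.get_fdata()), (float(zooms[0]), float(zooms[1]), float(zooms[2]))


def write_quantmap(qmap: QuantMap, path, flags_path=None) -> Path:
    """Write a parametric map; QC flags go to a companion NIfTI if present."""
    write_nifti(qmap.values, qmap.voxel_size, path)
    if qmap.flags is not None and flags_path is not None:
        write_nifti(qmap.flags.astype(np.float32), qmap.voxel_size, flags_path)
    return Path(path)


def write_tiff(image: np.ndarray, path, as_uint16: bool = True) -> Path:
    path = Path(path)
    arr = np.asarray(image)
    if as_uint16:
        lo, hi = float(arr.min()), float(arr.max())
        scale = 65535.0 / (hi - lo) if hi > lo else 1.0
        arr = ((arr - lo) * scale).astype(np.uint16)
    tifffile.imwrite(str(path), arr)
    return path


def read_tiff(path) -> np.ndarray:
    return tifffile.imread(str(path))


def load_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def dump_yaml(obj: dict, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(obj, sort_keys=True))
    return path


def write_doses_csv(doses: DoseSeries, path) -> Path:
    """Tidy CSV of the dose matrices: pulse,window,iud,ihd,flag."""
    path = Path(path)
    flags = (
        doses.event_flags
        if doses.event_flags is not None
        else np.zeros_like(doses.iud, dtype=bool)
    )
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["pulse", "window", "iud", "ihd", "flag"])
        for p in range(doses.n_pulses):
            for j in range(doses.n_windows):
                w.writerow(
                    [p, j, repr(float(doses.iud[p, j])), repr(float(doses.ihd[p, j])), int(flags[p, j])]
                )
    return path
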