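"""NIfTI round-tripping for dynamic images, label maps and 3-D maps."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .physics import FrameSchedule
from .synthetic import DynamicImage, LabelMap

__all__ = [
    "write_dynamic_nifti",
    "read_dynamic_nifti",
    "write_labelmap_nifti",
    "read_labelmap_nifti",
    "write_map_nifti",
    "read_map_nifti",
]


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.diag(list(voxel_size_mm) + [1.0])
    return aff


def write_dynamic_nifti(dyn: DynamicImage, path: str | Path) -> None:
    """Write the 4-D frames; schedule and flags go to a JSON sidecar."""
    path = Path(path)
    nib.save(nib.Nifti1Image(dyn.voxels.astype(np.float32), _affine(dyn.voxel_size_mm)), path)
    sidecar = {
        "frames": [list(f) for f in dyn.schedule.frames],
        "reference_time_s": dyn.schedule.reference_time_s,
        "decay_corrected": dyn.decay_corrected,
    }
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_dynamic_nifti(path: str | Path) -> DynamicImage:
    path = Path(path)
    img = nib.load(path)
    meta = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    schedule = FrameSchedule(
        frames=tuple(tuple(f) for f in meta["frames"]),
        reference_time_s=meta["reference_time_s"],
    )
    voxel_size = tuple(float(v) for v in img.header.get_zooms()[:3])
    return DynamicImage(
        np.asarray(img.dataobj, dtype=float), voxel_size, schedule,
        decay_corrected=bool(meta["decay_corrected"]),
    )


def write_labelmap_nifti(lm: LabelMap, path: str | Path) -> None:
    path = Path(path)
    nib.save(nib.Nifti1Image(lm.voxels.astype(np.int16), _affine(lm.voxel_size_mm)), path)
    sidecar = {"legend": {str(k): v for k, v in lm.legend.items()}}
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    if lm.body_mask is not None:
        body_path = path.with_suffix("").with_suffix(".body.nii.gz")
        nib.save(
            nib.Nifti1Image(lm.body_mask.astype(np.uint8), _affine(lm.voxel_size_mm)),
            body_path,
        )


def read_labelmap_nifti(path: str | Path) -> LabelMap:
    path = Path(path)
    img = nib.load(path)
    meta = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    legend = {int(k): v for k, v in meta["legend"].items()}
    voxel_size = tuple(float(v) for v in img.header.get_zooms()[:3])
    body_path = path.with_suffix("").with_suffix(".body.nii.gz")
    body = None
    if body_path.exists():
        body = np.asarray(nib.load(body_path).dataobj) > 0
    return LabelMap(
        np.asarray(img.dataobj, dtype=np.int16), legend, voxel_size, body_mask=body
    )


def write_map_nifti(arr: np.ndarray, voxel_size_mm, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(arr.astype(np.float32), _affine(voxel_size_mm)), Path(path))


def read_map_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, ...]]:
    img = nib.load(Path(path))
    return np.asarray(img.dataobj, dtype=float), tuple(
        float(v) for v in img.header.get_zooms()[:3]
    )
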