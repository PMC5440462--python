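"""NIfTI-1 and TSV I/O for the pipeline."""

from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import Volume4D

log = logging.getLogger("fncpipe")

__all__ = ["read_volume", "write_volume", "write_maps", "write_mask", "read_motion"]


def _affine(voxel_mm: float) -> np.ndarray:
    aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    return aff


def write_volume(vol: Volume4D, path) -> Path:
    """Write a 4D volume as NIfTI-1 with the TR in the header."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), _affine(vol.voxel_mm))
    img.header.set_zooms((vol.voxel_mm,) * 3 + (vol.tr_s,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    return path


def read_volume(path, tr_override: float | None = None) -> Volume4D:
    """Load a 4D NIfTI-1 volume.

    TR is taken from the header; a non-positive header TR falls back to
    ``tr_override`` (with a logged warning).  Non-finite voxels are
    rejected with their location.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float32)
    except Exception as e:
        raise ValueError(f"cannot read NIfTI file {path}: {e}") from e
    if data.ndim == 3:
        data = data[..., None]
    if data.ndim != 4:
        raise ValueError(f"{path}: expected 3D/4D image, got {data.ndim}D")
    if not np.all(np.isfinite(data)):
        bad = np.argwhere(~np.isfinite(data))[0]
        raise ValueError(f"{path}: non-finite voxel at index {tuple(bad)}")
    zooms = img.header.get_zooms()
    voxel_mm = float(zooms[0])
    tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    if tr <= 0:
        if tr_override is None or tr_override <= 0:
            raise ValueError(f"{path}: header TR is {tr} and no valid override given")
        log.warning("%s: header TR=%s, using override %.3fs", path.name, tr, tr_override)
        tr = float(tr_override)
    elif tr_override is not None and tr_override > 0 and abs(tr - tr_override) > 1e-9:
        log.warning("%s: overriding header TR %.3fs with %.3fs", path.name, tr, tr_override)
        tr = float(tr_override)
    return Volume4D(data=data, voxel_mm=voxel_mm, tr_s=tr, subject_id=path.stem.split("_")[0])


def write_maps(maps: np.ndarray, acq, path) -> Path:
    """Write component/network maps as one 4D NIfTI (one frame per map)."""
    arr = np.moveaxis(np.asarray(maps, dtype=np.float32), 0, -1)
    img = nib.Nifti1Image(arr, _affine(acq.voxel_mm))
    nib.save(img, str(path))
    return Path(path)


def write_mask(mask: np.ndarray, acq, path) -> Path:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(acq.voxel_mm))
    nib.save(img, str(path))
    return Path(path)


def read_motion(path) -> np.ndarray:
    """Read a 6-column motion TSV (3 translations mm, 3 rotations deg)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 motion columns, got {df.shape[1]}")
    return df.to_numpy(dtype=float)
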