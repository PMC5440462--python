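"""Preprocessing chain: volume discarding, motion screening, spatial
smoothing and nuisance regression.

The fixed stage order is discard -> screen -> smooth -> regress; motion
screening consumes realignment-style parameter tables (the data are
simulated in a shared grid, so realignment itself is not performed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import Volume4D

__all__ = [
    "MotionDecision",
    "discard_initial_volumes",
    "screen_motion",
    "smooth_gaussian",
    "nuisance_design",
    "regress_nuisance",
    "preprocess_subject",
]


@dataclass(frozen=True)
class MotionDecision:
    include: bool
    max_translation_mm: float
    max_rotation_deg: float
    trans_thresh_mm: float
    rot_thresh_deg: float


def discard_initial_volumes(vol: Volume4D, n_discard: int = 5) -> Volume4D:
    """Drop the first ``n_discard`` volumes (field-stabilization frames)."""
    if n_discard < 0:
        raise ValueError(f"n_discard must be >= 0, got {n_discard}")
    if n_discard >= vol.n_volumes:
        raise ValueError(
            f"cannot discard {n_discard} of {vol.n_volumes} volumes"
        )
    if n_discard == 0:
        return vol
    return vol.with_data(vol.data[..., n_discard:])


def screen_motion(
    trace: np.ndarray,
    trans_thresh_mm: float = 2.0,
    rot_thresh_deg: float = 2.0,
) -> MotionDecision:
    """Include/exclude a subject from their motion-parameter table.

    ``trace`` is (T, 6): translations in mm then rotations in degrees.
    Exclusion is strict ("exceeding"): a maximum of exactly 2.0 mm is
    retained.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 2 or trace.shape[1] != 6 or trace.shape[0] == 0:
        raise ValueError(f"motion trace must be a nonempty (T, 6) array, got {trace.shape}")
    max_t = float(np.max(np.abs(trace[:, :3])))
    max_r = float(np.max(np.abs(trace[:, 3:])))
    include = not (max_t > trans_thresh_mm or max_r > rot_thresh_deg)
    return MotionDecision(include, max_t, max_r, trans_thresh_mm, rot_thresh_deg)


def smooth_gaussian(vol: Volume4D, fwhm_mm: float = 8.0) -> Volume4D:
    """Isotropic Gaussian smoothing of each 3D frame.

    sigma = FWHM / (2 sqrt(2 ln 2)) / voxel size, in voxel units.  The
    boundary uses half-sample symmetric reflection, which conserves each
    frame's total mass exactly (no zero-padding attenuation on small
    grids).
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm_mm must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return vol
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / vol.voxel_mm
    data = ndimage.gaussian_filter(
        vol.data.astype(np.float64), sigma=(sigma, sigma, sigma, 0.0), mode="reflect"
    )
    return vol.with_data(data.astype(vol.data.dtype))


def nuisance_design(vol: Volume4D, wm_mask: np.ndarray, csf_mask: np.ndarray) -> np.ndarray:
    """(T, 4) design: WM mean, CSF mean, linear drift ramp, intercept.

    The drift column is an affine ramp over the retained (post-discard)
    time axis.
    """
    for name, m in (("wm", wm_mask), ("csf", csf_mask)):
        m = np.asarray(m, dtype=bool)
        if not m.any():
            raise ValueError(f"{name} mask is empty")
        if m.shape != vol.grid_dims:
            raise ValueError(f"{name} mask shape {m.shape} != grid {vol.grid_dims}")
    T = vol.n_volumes
    wm_series = vol.data[np.asarray(wm_mask, dtype=bool)].mean(axis=0)
    csf_series = vol.data[np.asarray(csf_mask, dtype=bool)].mean(axis=0)
    ramp = np.linspace(-1.0, 1.0, T)
    return np.column_stack([wm_series, csf_series, ramp, np.ones(T)]).astype(np.float64)


def regress_nuisance(vol: Volume4D, wm_mask: np.ndarray, csf_mask: np.ndarray) -> Volume4D:
    """OLS residuals of every voxel series against the nuisance design."""
    X = nuisance_design(vol, wm_mask, csf_mask)
    Y = vol.data.reshape(-1, vol.n_volumes).T.astype(np.float64)  # (T, V)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    data = resid.T.reshape(vol.data.shape)
    return vol.with_data(data.astype(vol.data.dtype))


def preprocess_subject(
    vol: Volume4D,
    motion: np.ndarray,
    wm_mask: np.ndarray,
    csf_mask: np.ndarray,
    *,
    n_discard: int = 5,
    trans_thresh_mm: float = 2.0,
    rot_thresh_deg: float = 2.0,
    fwhm_mm: float = 8.0,
) -> tuple[Volume4D | None, dict]:
    """Full per-subject chain; returns (volume, log) with volume None when
    the subject is excluded for motion."""
    decision = screen_motion(motion, trans_thresh_mm, rot_thresh_deg)
    log = {
        "subject_id": vol.subject_id,
        "included": decision.include,
        "max_translation_mm": decision.max_translation_mm,
        "max_rotation_deg": decision.max_rotation_deg,
        "n_discard": n_discard,
        "fwhm_mm": fwhm_mm,
    }
    if not decision.include:
        return None, log
    out = discard_initial_volumes(vol, n_discard)
    out = smooth_gaussian(out, fwhm_mm)
    out = regress_nuisance(out, wm_mask, csf_mask)
    return out, log
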