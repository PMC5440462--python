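"""Functional network connectivity: maximal lagged cross-correlation.

The connectivity between two networks is the signed Pearson correlation
of their time courses at the lag (within +/-5 s) that maximizes the
absolute correlation, Fisher z-transformed.  With TR = 2 s the +/-5 s lag
range is not a whole number of samples, so time courses are resampled to
a 1 s grid by linear interpolation by default; a TR-grid mode (lags at
multiples of TR only, no interpolation) is available for sensitivity
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Volume4D

__all__ = [
    "NetworkTimeCourse",
    "LagSpec",
    "FncEdge",
    "FncMatrix",
    "extract_timecourse",
    "max_lagged_corr",
    "fisher_z",
    "build_fnc_matrix",
]

#: |r| is clipped to 1 - Z_CLIP before atanh so z stays finite.
Z_CLIP = 1e-7


@dataclass
class NetworkTimeCourse:
    values: np.ndarray
    tr_s: float
    label: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("time course must be 1D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time course contains non-finite values")
        if self.tr_s <= 0:
            raise ValueError(f"tr_s must be positive, got {self.tr_s}")


@dataclass(frozen=True)
class LagSpec:
    """Lag grid for the maximal-lagged-correlation scan."""

    max_lag_s: float = 5.0
    step_s: float = 1.0
    interpolation: str = "linear"     # 'linear' | 'none'

    def __post_init__(self) -> None:
        if not 0 < self.step_s <= self.max_lag_s:
            raise ValueError(f"need 0 < step_s <= max_lag_s, got {self.step_s}, {self.max_lag_s}")
        if self.interpolation not in ("linear", "none"):
            raise ValueError(f"interpolation must be 'linear' or 'none', got {self.interpolation!r}")


@dataclass(frozen=True)
class FncEdge:
    label_i: str
    label_j: str
    r: float          # signed Pearson correlation at the selected lag
    lag_s: float      # signed lag in seconds (positive: j trails i)
    z: float          # Fisher z of r


@dataclass
class FncMatrix:
    subject_id: str
    labels: tuple[str, ...]
    r: np.ndarray       # (N, N), symmetric, diagonal NaN
    lag: np.ndarray     # (N, N), antisymmetric, diagonal 0
    z: np.ndarray       # (N, N), symmetric, diagonal NaN

    def to_long(self) -> pd.DataFrame:
        rows = []
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append({
                    "subject_id": self.subject_id,
                    "rsn_i": self.labels[i], "rsn_j": self.labels[j],
                    "r": self.r[i, j], "lag_s": self.lag[i, j], "z": self.z[i, j],
                })
        return pd.DataFrame(rows)


def extract_timecourse(
    vol: Volume4D,
    mask: np.ndarray,
    label: str = "",
) -> NetworkTimeCourse:
    """Unweighted mean of all in-mask voxel series, per volume."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError(f"empty mask for network {label!r}")
    if mask.shape != vol.grid_dims:
        raise ValueError(f"mask shape {mask.shape} != grid {vol.grid_dims}")
    series = vol.data[mask].mean(axis=0).astype(np.float64)
    return NetworkTimeCourse(series, tr_s=vol.tr_s, label=label, subject_id=vol.subject_id)


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """Variance-stabilizing z = atanh(r), with |r| clipped below 1."""
    arr = np.asarray(r, dtype=np.float64)
    if np.any(np.abs(arr) > 1):
        raise ValueError("|r| must be <= 1")
    z = np.arctanh(np.clip(arr, -1 + Z_CLIP, 1 - Z_CLIP))
    return float(z) if np.isscalar(r) or arr.ndim == 0 else z


def _resample(values: np.ndarray, tr_s: float, step_s: float) -> np.ndarray:
    T = len(values)
    t_old = np.arange(T) * tr_s
    t_new = np.arange(0.0, t_old[-1] + step_s / 2, step_s)
    t_new = t_new[t_new <= t_old[-1] + 1e-9]
    return np.interp(t_new, t_old, values)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return 0.0
    return float(np.clip((a @ b) / denom, -1.0, 1.0))


def max_lagged_corr(
    x: NetworkTimeCourse,
    y: NetworkTimeCourse,
    spec: LagSpec = LagSpec(),
) -> FncEdge:
    """Signed Pearson correlation at the absolute-maximal lag.

    r(l) is the correlation of x(t) with y(t + l) over the overlapping
    window, evaluated on the lag grid; the selected lag maximizes |r|
    (ties break toward smaller |l|, then toward negative l) and the
    SIGNED correlation at that lag is reported together with its Fisher
    z.  Constant series are rejected.
    """
    if len(x.values) != len(y.values):
        raise ValueError("time courses must have equal length")
    if abs(x.tr_s - y.tr_s) > 1e-12:
        raise ValueError("time courses must share TR")
    T_s = len(x.values) * x.tr_s
    if not T_s > 4 * spec.max_lag_s:
        raise ValueError(f"series too short: duration {T_s}s <= 4 x max lag {spec.max_lag_s}s")
    if x.values.std() == 0 or y.values.std() == 0:
        raise ValueError("constant time course has no defined correlation")

    if spec.interpolation == "linear" and x.tr_s > spec.step_s:
        a = _resample(x.values, x.tr_s, spec.step_s)
        b = _resample(y.values, y.tr_s, spec.step_s)
        dt = spec.step_s
    else:
        a, b = x.values.copy(), y.values.copy()
        dt = x.tr_s
    a = (a - a.mean()) / a.std()
    b = (b - b.mean()) / b.std()

    n_steps = int(np.floor(spec.max_lag_s / dt + 1e-9))
    lags = sorted(range(-n_steps, n_steps + 1), key=lambda L: (abs(L), L))
    best_r, best_lag = 0.0, 0
    first = True
    for L in lags:
        if L >= 0:
            r = _pearson(a[:len(a) - L] if L else a, b[L:])
        else:
            r = _pearson(a[-L:], b[:L])
        if first or abs(r) > abs(best_r):
            best_r, best_lag, first = r, L, False
    lag_s = best_lag * dt
    return FncEdge(
        label_i=x.label, label_j=y.label,
        r=best_r, lag_s=lag_s, z=fisher_z(best_r),
    )


def build_fnc_matrix(
    timecourses: dict[str, NetworkTimeCourse] | list[NetworkTimeCourse],
    spec: LagSpec = LagSpec(),
    subject_id: str = "",
) -> FncMatrix:
    """Evaluate all N(N-1)/2 network pairs for one subject.

    Each unordered pair is computed once; symmetry of r/z and
    antisymmetry of the lag hold by construction.
    """
    if isinstance(timecourses, dict):
        items = [(lab, tc) for lab, tc in timecourses.items()]
    else:
        items = [(tc.label, tc) for tc in timecourses]
    n = len(items)
    if n < 2:
        raise ValueError("need at least 2 networks")
    labels = tuple(lab for lab, _ in items)
    r = np.full((n, n), np.nan)
    lag = np.zeros((n, n))
    z = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                edge = max_lagged_corr(items[i][1], items[j][1], spec)
            except ValueError as e:
                raise ValueError(f"pair ({labels[i]}, {labels[j]}): {e}") from e
            r[i, j] = r[j, i] = edge.r
            z[i, j] = z[j, i] = edge.z
            lag[i, j] = edge.lag_s
            lag[j, i] = -edge.lag_s
    sid = subject_id or next((tc.subject_id for _, tc in items if tc.subject_id), "")
    return FncMatrix(subject_id=sid, labels=labels, r=r, lag=lag, z=z)
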