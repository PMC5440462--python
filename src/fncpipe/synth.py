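"""Synthetic resting-state cohort generator with known ground truth.

Builds multi-subject 4D datasets that emulate a three-group resting-state
fMRI study (healthy controls HC, myoclonic-seizure patients MS,
absence-seizure patients AS): spatially compact network maps, network time
courses with planted signed lagged correlations, white-matter/CSF nuisance
signals, linear drift, white Gaussian noise, and six-parameter motion
traces.  Every planted quantity is returned as ground truth so each
downstream stage can be validated without scanner data.

The generative model for one subject is

    y(v, t) = sum_k a_k s_k m_k(v) c_k(t)  +  n_wm/csf(v, t)
              + b (t - T/2)  +  e(v, t),    e ~ N(0, sigma^2)

with network maps ``m_k`` (unit peak), standardized time courses ``c_k``,
amplitudes ``a_k``, group amplitude scales ``s_k``, drift slope ``b`` and
corner-slab nuisance components.  Group connectivity effects act on the
Fisher-z scale of the planted correlations before time courses are drawn.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GROUP_LABELS, RSN_LABELS, AcquisitionParams, Volume4D, check_rng_seed

__all__ = [
    "NetworkSpec",
    "CouplingSpec",
    "GroupEffectSpec",
    "CohortSpec",
    "GroundTruth",
    "CohortResult",
    "make_network_maps",
    "make_timecourses",
    "assemble_subject",
    "simulate_motion",
    "simulate_cohort",
    "default_network_specs",
    "default_couplings",
    "default_group_effects",
    "default_cohort_spec",
    "default_nuisance_masks",
]

#: Map values above this fraction of the peak count as "inside" the network
#: (used for nuisance-mask disjointness and mask-based extraction checks).
SUPRA_THRESHOLD = 0.1


@dataclass(frozen=True)
class NetworkSpec:
    """Spatial layout of one planted network: a mixture of Gaussian blobs."""

    label: str
    blob_centers: tuple[tuple[int, int, int], ...]
    blob_fwhm_mm: float = 10.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError(f"amplitude must be > 0, got {self.amplitude}")
        if self.blob_fwhm_mm <= 0:
            raise ValueError(f"blob_fwhm_mm must be > 0, got {self.blob_fwhm_mm}")
        if not self.blob_centers:
            raise ValueError("at least one blob center required")
        object.__setattr__(
            self, "blob_centers", tuple(tuple(int(c) for c in ctr) for ctr in self.blob_centers)
        )


@dataclass(frozen=True)
class CouplingSpec:
    """Planted signed lagged correlation between two networks.

    ``rho`` is the population Pearson correlation between network ``i`` at
    time t and network ``j`` at time t + ``lag_s``.
    """

    pair: tuple[int, int]
    rho: float
    lag_s: float = 0.0

    def __post_init__(self) -> None:
        i, j = self.pair
        if i == j:
            raise ValueError(f"coupling pair must involve two distinct networks, got {self.pair}")
        if not abs(self.rho) < 1:
            raise ValueError(f"|rho| must be < 1, got {self.rho}")
        if abs(self.lag_s) > 5:
            raise ValueError(f"|lag_s| must be <= 5 s, got {self.lag_s}")


@dataclass(frozen=True)
class GroupEffectSpec:
    """Group-level deviations from the HC generative model.

    ``coupling_deltas`` are additive shifts applied on the Fisher-z scale
    to planted correlations (keyed by network-label pair), so planted group
    differences are commensurate with z-scale mean differences reported by
    group FNC statistics.  ``amplitude_scales`` multiply per-network BOLD
    amplitudes (keyed by label).
    """

    group: str
    coupling_deltas: dict[tuple[str, str], float] = field(default_factory=dict)
    amplitude_scales: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUP_LABELS:
            raise ValueError(f"group must be one of {GROUP_LABELS}, got {self.group!r}")


@dataclass
class GroundTruth:
    """Everything planted into a simulated cohort."""

    labels: tuple[str, ...]
    maps: np.ndarray                      # (k, X, Y, Z), unit peak
    timecourses: dict[str, np.ndarray]    # subject id -> (k, T)
    coupling_table: pd.DataFrame          # per pair: indices, labels, rho per group, lag_s
    wm_mask: np.ndarray
    csf_mask: np.ndarray
    drift_slopes: dict[str, float]
    motion: dict[str, np.ndarray]         # subject id -> (T, 6)
    amplitudes: dict[str, np.ndarray]     # subject id -> per-network effective amplitude


@dataclass
class CohortResult:
    manifest: pd.DataFrame                # subject_id, group, path, seed
    truth: GroundTruth
    volumes: dict[str, Volume4D]
    acq: AcquisitionParams


# ---------------------------------------------------------------------------
# spatial maps
# ---------------------------------------------------------------------------

def _fwhm_to_sigma_vox(fwhm_mm: float, voxel_mm: float) -> float:
    return fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_mm


def make_network_maps(
    specs: list[NetworkSpec] | tuple[NetworkSpec, ...],
    acq: AcquisitionParams,
    seed: int = 0,
) -> np.ndarray:
    """Render each network's spatial map on the acquisition grid.

    Each map is an additive mixture of isotropic Gaussian blobs,
    peak-normalized to 1.  Identical blob layouts in two specs are a
    degenerate configuration and rejected.
    """
    del seed  # layout is deterministic; kept for interface symmetry
    if len(specs) < 2 and len(specs) != 1:
        raise ValueError("at least one NetworkSpec required")
    seen: dict[tuple, str] = {}
    for s in specs:
        key = tuple(sorted(s.blob_centers))
        if key in seen:
            raise ValueError(
                f"networks {seen[key]!r} and {s.label!r} share an identical blob layout"
            )
        seen[key] = s.label
    dims = acq.grid_dims
    grids = np.meshgrid(*(np.arange(d, dtype=float) for d in dims), indexing="ij")
    maps = np.zeros((len(specs),) + dims)
    for k, s in enumerate(specs):
        sigma = _fwhm_to_sigma_vox(s.blob_fwhm_mm, acq.voxel_mm)
        for ctr in s.blob_centers:
            if not all(0 <= c < d for c, d in zip(ctr, dims)):
                raise ValueError(f"blob center {ctr} outside grid {dims} for {s.label!r}")
            d2 = sum((g - c) ** 2 for g, c in zip(grids, ctr))
            maps[k] += np.exp(-d2 / (2.0 * sigma**2))
        peak = maps[k].max()
        if peak <= 0 or not np.any(maps[k] > SUPRA_THRESHOLD * peak):
            raise ValueError(f"map for {s.label!r} is empty after thresholding")
        maps[k] /= peak
    return maps


# ---------------------------------------------------------------------------
# time courses
# ---------------------------------------------------------------------------

def _solve_shifts(couplings, n_networks: int, tr_s: float) -> np.ndarray:
    """Per-network integer sample shifts realizing every pairwise lag.

    A coupling (i, j, lag) requires shift_i - shift_j = lag / TR.  Shifts
    are propagated over the coupling graph; inconsistent lag cycles are
    rejected.
    """
    adj: dict[int, list[tuple[int, int]]] = {k: [] for k in range(n_networks)}
    for c in couplings:
        i, j = c.pair
        lag_samples = c.lag_s / tr_s
        if abs(lag_samples - round(lag_samples)) > 1e-9:
            raise ValueError(
                f"lag_s={c.lag_s} for pair {c.pair} is not a multiple of TR={tr_s}"
            )
        ls = int(round(lag_samples))
        adj[i].append((j, ls))    # shift_i - shift_j = ls
        adj[j].append((i, -ls))
    shifts = np.full(n_networks, np.iinfo(np.int64).min, dtype=np.int64)
    for start in range(n_networks):
        if shifts[start] != np.iinfo(np.int64).min:
            continue
        shifts[start] = 0
        stack = [start]
        while stack:
            u = stack.pop()
            for v, ls in adj[u]:
                want = shifts[u] - ls
                if shifts[v] == np.iinfo(np.int64).min:
                    shifts[v] = want
                    stack.append(v)
                elif shifts[v] != want:
                    raise ValueError(
                        f"inconsistent lag structure at network {v}: "
                        f"shift {shifts[v]} vs {want} samples"
                    )
    return shifts


def coupling_matrix(couplings, n_networks: int) -> np.ndarray:
    """Lag-aligned correlation matrix implied by the couplings (PSD-checked)."""
    C = np.eye(n_networks)
    seen = set()
    for c in couplings:
        i, j = c.pair
        if not (0 <= i < n_networks and 0 <= j < n_networks):
            raise ValueError(f"coupling pair {c.pair} outside 0..{n_networks - 1}")
        key = frozenset((i, j))
        if key in seen:
            raise ValueError(f"duplicate coupling for pair {c.pair}")
        seen.add(key)
        C[i, j] = C[j, i] = c.rho
    w = np.linalg.eigvalsh(C)
    if w[0] < -1e-10:
        raise ValueError(
            f"coupling structure is not positive semi-definite "
            f"(smallest eigenvalue {w[0]:.6g})"
        )
    return C


def make_timecourses(
    couplings: list[CouplingSpec] | tuple[CouplingSpec, ...],
    n_networks: int,
    acq: AcquisitionParams,
    seed: int = 0,
) -> np.ndarray:
    """Draw standardized network time courses with the planted lagged structure.

    Latent Gaussian factors with the lag-aligned correlation matrix are
    drawn on an extended time axis, each network's series is shifted by its
    solved sample offset, the wrapped margin is discarded and each row is
    re-standardized to zero mean / unit variance.  For every coupling the
    population correlation between network i at t and network j at
    t + lag_s equals rho.
    """
    if n_networks < 1:
        raise ValueError("n_networks must be >= 1")
    C = coupling_matrix(couplings, n_networks)
    shifts = _solve_shifts(couplings, n_networks, acq.tr_s)
    T = acq.n_volumes
    margin = int(np.max(np.abs(shifts))) if n_networks else 0
    rng = np.random.default_rng(check_rng_seed(seed))
    w, V = np.linalg.eigh(C)
    root = V @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ V.T
    latent = root @ rng.standard_normal((n_networks, T + 2 * margin))
    tcs = np.empty((n_networks, T))
    for k in range(n_networks):
        # x_k(t) = u_k(t + shift_k): window chosen so no wrapped samples enter
        start = margin + shifts[k]
        tcs[k] = latent[k, start:start + T]
    tcs -= tcs.mean(axis=1, keepdims=True)
    sd = tcs.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return tcs / sd


def apply_z_deltas(couplings, deltas: dict[tuple[int, int], float]) -> list[CouplingSpec]:
    """Shift planted correlations on the Fisher-z scale.

    Pairs named in ``deltas`` but absent from ``couplings`` are added with
    baseline rho = 0.
    """
    out = []
    remaining = {frozenset(p): d for p, d in deltas.items()}
    for c in couplings:
        key = frozenset(c.pair)
        if key in remaining:
            rho = float(np.tanh(np.arctanh(c.rho) + remaining.pop(key)))
            out.append(CouplingSpec(c.pair, rho, c.lag_s))
        else:
            out.append(c)
    for key, d in remaining.items():
        i, j = sorted(key)
        out.append(CouplingSpec((i, j), float(np.tanh(d)), 0.0))
    return out


# ---------------------------------------------------------------------------
# subject assembly
# ---------------------------------------------------------------------------

def default_nuisance_masks(grid_dims) -> tuple[np.ndarray, np.ndarray]:
    """Fixed corner slabs standing in for white matter and CSF.

    WM occupies the low-x/low-y corner column, CSF the high-x/high-y one;
    both span all slices and are disjoint from the default network layout.
    """
    x, y, z = grid_dims
    s = max(2, x // 8)
    wm = np.zeros(grid_dims, dtype=bool)
    csf = np.zeros(grid_dims, dtype=bool)
    wm[:s, :s, :] = True
    csf[x - s:, y - s:, :] = True
    return wm, csf


def _ar1(rng: np.random.Generator, T: int, phi: float = 0.9) -> np.ndarray:
    e = rng.standard_normal(T) * np.sqrt(1.0 - phi**2)
    out = np.empty(T)
    out[0] = rng.standard_normal()
    for t in range(1, T):
        out[t] = phi * out[t - 1] + e[t]
    out -= out.mean()
    sd = out.std()
    return out / sd if sd > 0 else out


def assemble_subject(
    maps: np.ndarray,
    timecourses: np.ndarray,
    acq: AcquisitionParams,
    *,
    amplitudes: np.ndarray | None = None,
    noise_sd: float = 1.0,
    drift_slope: float = 0.0,
    wm_mask: np.ndarray | None = None,
    csf_mask: np.ndarray | None = None,
    nuisance_leak: float = 0.15,
    seed: int = 0,
    subject_id: str = "",
) -> tuple[Volume4D, dict]:
    """Compose one subject's 4D data from the generative model.

    Returns the volume and a per-subject truth dict (nuisance series,
    drift slope, effective amplitudes).
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    maps = np.asarray(maps)
    timecourses = np.asarray(timecourses)
    k = maps.shape[0]
    if timecourses.shape[0] != k:
        raise ValueError(
            f"{k} maps but {timecourses.shape[0]} time courses"
        )
    if maps.shape[1:] != acq.grid_dims:
        raise ValueError(f"map grid {maps.shape[1:]} != acquisition grid {acq.grid_dims}")
    T = timecourses.shape[1]
    amps = np.ones(k) if amplitudes is None else np.asarray(amplitudes, dtype=float)

    rng = np.random.default_rng(check_rng_seed(seed))
    weighted = maps * amps[:, None, None, None]
    data = np.einsum("kxyz,kt->xyzt", weighted, timecourses)

    if wm_mask is not None or csf_mask is not None:
        if wm_mask is None or csf_mask is None:
            raise ValueError("provide both wm_mask and csf_mask or neither")
        for name, m in (("wm", wm_mask), ("csf", csf_mask)):
            if not m.any():
                raise ValueError(f"{name} mask is empty")
            overlap = m & np.any(maps > SUPRA_THRESHOLD, axis=0)
            if overlap.any():
                raise ValueError(
                    f"{name} mask overlaps suprathreshold network voxels "
                    f"({int(overlap.sum())} voxels)"
                )
        for m in (wm_mask, csf_mask):
            series = _ar1(rng, T)
            weight = np.where(m, 1.0, nuisance_leak)
            data += weight[..., None] * series[None, None, None, :]

    if drift_slope != 0.0:
        ramp = drift_slope * (np.arange(T) - (T - 1) / 2.0)
        data += ramp[None, None, None, :]

    if noise_sd > 0:
        data += noise_sd * rng.standard_normal(data.shape)

    vol = Volume4D(
        data=data.astype(np.float32),
        voxel_mm=acq.voxel_mm,
        tr_s=acq.tr_s,
        subject_id=subject_id,
    )
    truth = {"drift_slope": drift_slope, "amplitudes": amps.copy()}
    return vol, truth


def simulate_motion(
    n_volumes: int,
    seed: int = 0,
    *,
    step_sd: float = 0.04,
    bound: float = 1.2,
    exceed: bool = False,
) -> np.ndarray:
    """Six-parameter motion trace (3 translations mm, 3 rotations deg).

    A bounded random walk; when ``exceed`` is set, one translation spikes
    past the 2 mm screening threshold to exercise subject exclusion.
    """
    rng = np.random.default_rng(check_rng_seed(seed))
    steps = rng.standard_normal((n_volumes, 6)) * step_sd
    steps[0] = 0.0
    trace = np.clip(np.cumsum(steps, axis=0), -bound, bound)
    if exceed:
        t = int(rng.integers(n_volumes // 4, n_volumes))
        trace[t, int(rng.integers(0, 3))] = 2.6
    return trace


# ---------------------------------------------------------------------------
# cohort defaults and simulation
# ---------------------------------------------------------------------------

def default_network_specs(
    acq: AcquisitionParams, blob_fwhm_mm: float | None = None
) -> list[NetworkSpec]:
    """Twelve two-blob network layouts on a 3x3x3 interior lattice.

    Network k takes lattice points k and k+12, so each network's blobs sit
    on different slabs and neighbouring points belong to different
    networks; pairwise spatial correlations stay low by construction.
    When ``blob_fwhm_mm`` is None it defaults to 10 mm, capped so that
    suprathreshold blob extent clears the corner nuisance slabs on small
    grids.
    """
    dims = acq.grid_dims
    axes = [
        [int(np.floor(f * d + 0.5)) for f in (0.25, 0.5, 0.75)] for d in dims
    ]
    if blob_fwhm_mm is None:
        d_xy = min(dims[0], dims[1])
        slab = max(2, d_xy // 8)
        p3 = int(np.floor(0.75 * d_xy + 0.5))
        clearance_vox = np.sqrt(2.0) * max(1, d_xy - slab - p3)
        # suprathreshold radius sigma*sqrt(2 ln 10) must stay below clearance
        cap = 0.95 * clearance_vox / np.sqrt(2 * np.log(10)) * (
            2.0 * np.sqrt(2.0 * np.log(2.0))
        ) * acq.voxel_mm
        blob_fwhm_mm = float(min(10.0, cap))
    points = [(x, y, z) for z in axes[2] for y in axes[1] for x in axes[0]]
    specs = []
    for k, label in enumerate(RSN_LABELS):
        centers = (points[k], points[k + 12])
        specs.append(NetworkSpec(label=label, blob_centers=centers, blob_fwhm_mm=blob_fwhm_mm))
    return specs


def default_couplings(labels: tuple[str, ...] = RSN_LABELS) -> list[CouplingSpec]:
    """Planted coupling table for the default cohort.

    Signed correlations up to |rho| = 0.45 with lags on the TR grid,
    covering positive, negative, zero-lag and lagged pairs among the
    twelve networks; the structure mirrors the kinds of between-network
    connections group FNC studies report (e.g. a strong visual-salience
    link carrying the planted group effect).
    """
    ix = {lab: i for i, lab in enumerate(labels)}

    def c(a, b, rho, lag=0.0):
        return CouplingSpec((ix[a], ix[b]), rho, lag)

    return [
        c("AN", "RDAN", 0.35, 0.0),
        c("AN", "SRN", 0.30, 2.0),
        c("VN", "RFPN", 0.35, 0.0),
        c("VN", "LFPN", 0.30, -2.0),
        c("VN", "SN", 0.45, 0.0),
        c("LDAN", "LFPN", 0.35, 0.0),
        c("LDAN", "aDMN", 0.30, 2.0),
        c("pDMN", "aDMN", 0.40, 0.0),
        c("CBN", "SMN", 0.30, 0.0),
        c("SMN", "aDMN", -0.35, 0.0),
    ]


def default_group_effects() -> dict[str, GroupEffectSpec]:
    """Default planted group differences.

    Both patient groups lose visual-salience coupling (z-scale decreases
    of 0.31 for AS and 0.43 for MS, the magnitude range of reported FNC
    mean differences); MS additionally shows stronger sensorimotor and
    left-frontoparietal amplitude, AS weaker salience amplitude.
    """
    return {
        "HC": GroupEffectSpec("HC"),
        "MS": GroupEffectSpec(
            "MS",
            coupling_deltas={("VN", "SN"): -0.43},
            amplitude_scales={"SMN": 1.2, "LFPN": 1.15},
        ),
        "AS": GroupEffectSpec(
            "AS",
            coupling_deltas={("VN", "SN"): -0.31},
            amplitude_scales={"SN": 0.85},
        ),
    }


@dataclass
class CohortSpec:
    """Full simulation configuration for one cohort."""

    acq: AcquisitionParams = field(default_factory=AcquisitionParams)
    networks: list[NetworkSpec] = None          # default layout if None
    couplings: list[CouplingSpec] = None        # default table if None
    effects: dict[str, GroupEffectSpec] = None  # default effects if None
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"HC": 21, "MS": 20, "AS": 21}
    )
    noise_sd: float = 1.0
    drift_slope_sd: float = 0.005
    nuisance_leak: float = 0.15
    motion_exceed_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.networks is None:
            self.networks = default_network_specs(self.acq)
        if self.couplings is None:
            self.couplings = default_couplings(tuple(s.label for s in self.networks))
        if self.effects is None:
            self.effects = {g: GroupEffectSpec(g) for g in self.group_sizes}
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ValueError(f"group {g!r} needs >= 2 subjects, got {n}")
            if g not in GROUP_LABELS:
                raise ValueError(f"unknown group label {g!r}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.networks)


def default_cohort_spec(
    grid_dims=(24, 24, 18),
    n_volumes: int = 255,
    group_sizes: dict[str, int] | None = None,
    noise_sd: float = 1.0,
    effects: dict[str, GroupEffectSpec] | None = None,
    with_default_effects: bool = True,
) -> CohortSpec:
    """The study conditions: TR 2 s, 255 volumes, 3 mm grid, groups 21/20/21."""
    acq = AcquisitionParams(tr_s=2.0, n_volumes=n_volumes, grid_dims=tuple(grid_dims), voxel_mm=3.0)
    if effects is None:
        effects = default_group_effects() if with_default_effects else None
    return CohortSpec(
        acq=acq,
        group_sizes=group_sizes or {"HC": 21, "MS": 20, "AS": 21},
        noise_sd=noise_sd,
        effects=effects,
    )


def _effect_indexed(effect: GroupEffectSpec, labels: tuple[str, ...]):
    ix = {lab: i for i, lab in enumerate(labels)}
    try:
        deltas = {(ix[a], ix[b]): d for (a, b), d in effect.coupling_deltas.items()}
        scales = np.ones(len(labels))
        for lab, s in effect.amplitude_scales.items():
            scales[ix[lab]] = s
    except KeyError as e:
        raise ValueError(f"effect references unknown network label {e}") from e
    return deltas, scales


def simulate_cohort(spec: CohortSpec, seed: int = 0, out_dir=None) -> CohortResult:
    """Simulate a full three-group cohort.

    Per-subject seeds are derived deterministically from the master seed,
    so identical spec + seed reproduces the cohort bit-for-bit.  When
    ``out_dir`` is given, each subject's 4D NIfTI-1 volume, its motion
    TSV, the cohort manifest and a ground-truth archive are written there.
    """
    rng = np.random.default_rng(check_rng_seed(seed))
    labels = spec.labels
    maps = make_network_maps(spec.networks, spec.acq, seed=int(rng.integers(2**31 - 1)))
    wm, csf = default_nuisance_masks(spec.acq.grid_dims)
    base_amp = np.array([s.amplitude for s in spec.networks])

    group_couplings = {}
    rows = []
    for g in spec.group_sizes:
        deltas, scales = _effect_indexed(spec.effects.get(g, GroupEffectSpec(g)), labels)
        group_couplings[g] = (apply_z_deltas(spec.couplings, deltas), scales)
    for c in spec.couplings:
        i, j = c.pair
        row = {
            "i": i, "j": j, "label_i": labels[i], "label_j": labels[j],
            "lag_s": c.lag_s, "rho": c.rho,
        }
        for g in spec.group_sizes:
            for cg in group_couplings[g][0]:
                if frozenset(cg.pair) == frozenset(c.pair):
                    row[f"rho_{g}"] = cg.rho
        rows.append(row)
    coupling_table = pd.DataFrame(rows)

    n_total = sum(spec.group_sizes.values())
    subject_seeds = rng.integers(0, 2**31 - 1, size=n_total)
    exceed_flags = rng.random(n_total) < spec.motion_exceed_fraction

    volumes: dict[str, Volume4D] = {}
    timecourses: dict[str, np.ndarray] = {}
    motion: dict[str, np.ndarray] = {}
    drift_slopes: dict[str, float] = {}
    amplitudes: dict[str, np.ndarray] = {}
    manifest_rows = []
    idx = 0
    for g, n in spec.group_sizes.items():
        couplings_g, scales_g = group_couplings[g]
        for s in range(n):
            sid = f"{g}{s + 1:02d}"
            if sid in volumes:
                raise ValueError(f"duplicate subject id {sid!r}")
            sseed = int(subject_seeds[idx])
            srng = np.random.default_rng(sseed)
            tcs = make_timecourses(
                couplings_g, len(labels), spec.acq, seed=int(srng.integers(2**31 - 1))
            )
            drift = float(srng.normal(0.0, spec.drift_slope_sd))
            vol, _ = assemble_subject(
                maps, tcs, spec.acq,
                amplitudes=base_amp * scales_g,
                noise_sd=spec.noise_sd,
                drift_slope=drift,
                wm_mask=wm, csf_mask=csf,
                nuisance_leak=spec.nuisance_leak,
                seed=int(srng.integers(2**31 - 1)),
                subject_id=sid,
            )
            motion[sid] = simulate_motion(
                spec.acq.n_volumes,
                seed=int(srng.integers(2**31 - 1)),
                exceed=bool(exceed_flags[idx]),
            )
            volumes[sid] = vol
            timecourses[sid] = tcs
            drift_slopes[sid] = drift
            amplitudes[sid] = base_amp * scales_g
            manifest_rows.append(
                {"subject_id": sid, "group": g, "path": f"{sid}_bold.nii", "seed": sseed}
            )
            idx += 1

    manifest = pd.DataFrame(manifest_rows)
    truth = GroundTruth(
        labels=labels, maps=maps, timecourses=timecourses,
        coupling_table=coupling_table, wm_mask=wm, csf_mask=csf,
        drift_slopes=drift_slopes, motion=motion, amplitudes=amplitudes,
    )
    result = CohortResult(manifest=manifest, truth=truth, volumes=volumes, acq=spec.acq)
    if out_dir is not None:
        write_cohort(result, out_dir)
    return result


def write_cohort(result: CohortResult, out_dir) -> None:
    """Write the cohort to disk: per-subject NIfTI + motion TSV, manifest,
    and a ground-truth archive (maps as 4D NIfTI, couplings/effects as TSV/JSON)."""
    from . import io as _io
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sid, vol in result.volumes.items():
        _io.write_volume(vol, out / f"{sid}_bold.nii")
        mot = pd.DataFrame(
            result.truth.motion[sid],
            columns=["trans_x_mm", "trans_y_mm", "trans_z_mm",
                     "rot_x_deg", "rot_y_deg", "rot_z_deg"],
        )
        mot.to_csv(out / f"{sid}_motion.tsv", sep="\t", index=False)
    result.manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    gt = out / "ground_truth"
    gt.mkdir(exist_ok=True)
    _io.write_maps(result.truth.maps, result.acq, gt / "network_maps.nii")
    _io.write_mask(result.truth.wm_mask, result.acq, gt / "wm_mask.nii")
    _io.write_mask(result.truth.csf_mask, result.acq, gt / "csf_mask.nii")
    result.truth.coupling_table.to_csv(gt / "couplings.tsv", sep="\t", index=False)
    with open(gt / "labels.json", "w") as f:
        json.dump(list(result.truth.labels), f)
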