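"""Core containers shared by every pipeline stage.

The analysis operates on 4D resting-state fMRI volumes sampled every
``tr_s`` seconds on an isotropic voxel grid.  Everything downstream
(preprocessing, group ICA, FNC) consumes :class:`Volume4D`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

#: The twelve resting-state networks analysed by the pipeline: left/right
#: frontoparietal, left/right dorsal attention, anterior/posterior default
#: mode, self-referential, salience, cerebellar, sensorimotor, auditory and
#: visual networks.
RSN_LABELS: tuple[str, ...] = (
    "LFPN", "RFPN", "LDAN", "RDAN", "aDMN", "pDMN",
    "SRN", "SN", "CBN", "SMN", "AN", "VN",
)

#: Three-group design: healthy controls, myoclonic seizures, absence seizures.
GROUP_LABELS: tuple[str, ...] = ("HC", "MS", "AS")


@dataclass(frozen=True)
class AcquisitionParams:
    """EPI acquisition constants.

    Parameters
    ----------
    tr_s :
        Repetition time in seconds (one volume every ``tr_s`` s).
    n_volumes :
        Volumes acquired per run, before any are discarded.
    grid_dims :
        Spatial grid shape (X, Y, Z) in voxels.
    voxel_mm :
        Isotropic voxel edge length in millimetres.
    """

    tr_s: float = 2.0
    n_volumes: int = 255
    grid_dims: tuple[int, int, int] = (24, 24, 18)
    voxel_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise ValueError(f"tr_s must be positive, got {self.tr_s}")
        if self.n_volumes < 20:
            raise ValueError(f"n_volumes must be >= 20, got {self.n_volumes}")
        dims = tuple(int(d) for d in self.grid_dims)
        if len(dims) != 3 or any(d < 8 for d in dims):
            raise ValueError(f"grid_dims must be 3 integers >= 8, got {self.grid_dims}")
        object.__setattr__(self, "grid_dims", dims)
        if self.voxel_mm <= 0:
            raise ValueError(f"voxel_mm must be positive, got {self.voxel_mm}")

    @property
    def n_voxels(self) -> int:
        x, y, z = self.grid_dims
        return x * y * z


@dataclass
class Volume4D:
    """A subject's 4D image: ``data[x, y, z, t]`` plus grid metadata.

    ``mask`` marks in-brain voxels; a ``None`` mask means the whole grid.
    """

    data: np.ndarray
    voxel_mm: float
    tr_s: float
    mask: np.ndarray | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4D (X,Y,Z,T), got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            bad = np.argwhere(~np.isfinite(self.data))
            raise ValueError(f"non-finite voxel values, first at index {tuple(bad[0])}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:3]:
                raise ValueError(
                    f"mask shape {self.mask.shape} does not match grid {self.data.shape[:3]}"
                )

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def get_mask(self) -> np.ndarray:
        """In-brain mask, defaulting to the full grid."""
        if self.mask is None:
            return np.ones(self.grid_dims, dtype=bool)
        return self.mask

    def to_matrix(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Return the (T, V) matrix of in-mask voxel time series."""
        m = self.get_mask() if mask is None else np.asarray(mask, dtype=bool)
        return np.ascontiguousarray(self.data[m].T)

    def with_data(self, data: np.ndarray) -> "Volume4D":
        return replace(self, data=data)


def check_rng_seed(seed: int) -> int:
    seed = int(seed)
    if seed < 0:
        raise ValueError(f"seed must be non-negative, got {seed}")
    return seed
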