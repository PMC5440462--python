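"""Run configuration: one serializable object per pipeline run.

Every stochastic stage draws from an explicit seed recorded here; the
SHA-256 hash of the canonical serialized config is embedded in every
output so artifacts from different configurations are distinguishable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PrepConfig", "IcaConfig", "FncConfig", "StatsConfig", "CohortConfig", "RunConfig"]


@dataclass
class CohortConfig:
    """Synthetic-cohort block (ignored when reading an external manifest)."""

    simulate: bool = True
    grid_dims: tuple[int, int, int] = (24, 24, 18)
    n_volumes: int = 255
    voxel_mm: float = 3.0
    tr_s: float = 2.0
    group_sizes: dict = field(default_factory=lambda: {"HC": 21, "MS": 20, "AS": 21})
    noise_sd: float = 1.0
    with_default_effects: bool = True
    motion_exceed_fraction: float = 0.0


@dataclass
class PrepConfig:
    n_discard: int = 5
    trans_thresh_mm: float = 2.0
    rot_thresh_deg: float = 2.0
    fwhm_mm: float = 8.0


@dataclass
class IcaConfig:
    k: int | str = 12              # component count, or 'mdl'
    max_iter: int = 512
    tol: float = 1e-6
    learning_rate: float | None = None


@dataclass
class FncConfig:
    max_lag_s: float = 5.0
    step_s: float = 1.0
    interpolation: str = "linear"
    timecourse_source: str = "mask"    # 'mask' | 'dualreg'


@dataclass
class StatsConfig:
    mask_alpha: float = 0.05
    mask_correction: str = "fwe"
    anova_alpha: float = 0.05
    within_alpha: float = 0.05
    match_threshold: float = 0.2


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "fncpipe_out"
    input_manifest: str | None = None   # external cohort; None => simulate
    cohort: CohortConfig = field(default_factory=CohortConfig)
    prep: PrepConfig = field(default_factory=PrepConfig)
    ica: IcaConfig = field(default_factory=IcaConfig)
    fnc: FncConfig = field(default_factory=FncConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"]["grid_dims"] = list(self.cohort.grid_dims)
        return d

    def config_hash(self) -> str:
        """Hash of the analysis configuration (the output location is
        excluded, so reruns into different directories share a hash)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        kwargs = {}
        for name, sub in (
            ("cohort", CohortConfig), ("prep", PrepConfig), ("ica", IcaConfig),
            ("fnc", FncConfig), ("stats", StatsConfig),
        ):
            if name in d:
                block = dict(d.pop(name))
                if name == "cohort" and "grid_dims" in block:
                    block["grid_dims"] = tuple(block["grid_dims"])
                kwargs[name] = sub(**block)
        kwargs.update(d)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
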