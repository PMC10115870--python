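"""Run configuration: YAML loading, validation, and provenance dumps."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import yaml

from . import __version__
from .errors import ConfigError

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved settings for one pipeline run (defaults per arm)."""

    pipeline: str = "focal"  # focal | dysconnect | evaluate | simulate
    seed: int = 0

    # grid (used when no volume defines one; origin defaults to loci bbox)
    voxel_size_mm: float = 1.5
    grid_margin_mm: float = 15.0

    # kernels & masking
    focal_fwhm_mm: float = 10.0
    dysconnectome_fwhm_mm: float = 6.0
    kernel_mass_fraction: float = 0.9
    focal_mask_threshold: float = 1e-5
    predictive_mask_threshold: float = 1e-4

    # inference
    alpha: float = 0.05
    n_perm: int = 2000
    uncorrected_p: float = 0.001

    # dysconnectome
    clamp_low_q: float = 0.001
    clamp_high_q: float = 0.999
    seed_cutoff_mm: float = 5.0
    seed_self_value: str = "max_edge"  # or "zero"
    clamp_before_smoothing: bool = True
    connectome_voxel_size_mm: float = 2.0

    # predictive
    n_boot: int = 100
    test_frac: float = 0.2
    eval_n_perm: int = 500
    roi_q_threshold: float = 0.05

    extra: dict = field(default_factory=dict)  # pipeline-specific sub-config

    @classmethod
    def field_names(cls) -> set[str]:
        return {f.name for f in dataclasses.fields(cls)}

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = cls.field_names()
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(unknown)}")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        return cls.from_dict(raw)

    def override(self, **kwargs) -> "RunConfig":
        """CLI-flag overrides (None values ignored); precedence CLI > file."""
        updates = {k: v for k, v in kwargs.items() if v is not None}
        unknown = sorted(set(updates) - self.field_names())
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(unknown)}")
        for k, v in updates.items():
            log.info("config override: %s = %r", k, v)
        return dataclasses.replace(self, **updates)

    def dump(self, path) -> None:
        """Write the resolved configuration next to the run outputs."""
        payload = {"dysmap_version": __version__, **dataclasses.asdict(self)}
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)
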