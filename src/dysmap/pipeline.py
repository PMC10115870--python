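"""End-to-end analysis runs shared by the focal and dysconnectome arms."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError
from .focal import DensityStack, build_density_mask, build_density_stack
from .glm import (
    DesignMatrix,
    GlmFit,
    NonSphericity,
    ThresholdResult,
    build_design,
    estimate_nonsphericity,
    fit_glm,
    fwe_threshold_maxT,
    t_contrast,
)
from .records import StimulationRecord, coords_array
from .volumes import Volume, VolumeGrid, build_gaussian_kernel, make_grid

log = logging.getLogger(__name__)


@dataclass
class ArmResult:
    """Everything one behaviour's analysis produced."""

    design: DesignMatrix
    ns: NonSphericity
    fit: GlmFit | None
    mask: Volume
    t_map: Volume
    threshold: ThresholdResult


def grid_from_records(
    records: list[StimulationRecord],
    voxel_size_mm: float = 1.5,
    margin_mm: float = 15.0,
) -> VolumeGrid:
    """Axis-aligned grid covering the loci bounding box plus a margin."""
    xyz = coords_array(records)
    lo = xyz.min(axis=0) - margin_mm
    hi = xyz.max(axis=0) + margin_mm
    shape = np.maximum(np.ceil((hi - lo) / voxel_size_mm).astype(int) + 1, 3)
    return make_grid(tuple(shape), voxel_size_mm, origin_mm=tuple(lo))


def run_glm_arm(
    Y_full: np.ndarray,
    records: list[StimulationRecord],
    behaviour: str,
    mask: Volume,
    alpha: float = 0.05,
    n_perm: int = 2000,
    seed: int | None = 0,
) -> ArmResult:
    """Design -> non-sphericity -> whitened fit -> maxT FWE threshold.

    ``Y_full`` is rows x voxels over the whole grid (C order); only in-mask
    voxels enter the model.
    """
    mask_flat = mask.values.ravel() > 0
    if not mask_flat.any():
        raise InvalidArgumentError("analysis mask is empty")
    Y = np.asarray(Y_full, dtype=float)[:, mask_flat].T  # voxels x rows
    design = build_design(records, behaviour)
    ns = estimate_nonsphericity(Y, design)
    fit = fit_glm(Y, design, ns)
    t = t_contrast(fit, design.behaviour_contrast())
    t_full = np.zeros(mask.grid.shape)
    t_full.ravel()[mask_flat] = t
    t_map = Volume(mask.grid, t_full)
    threshold = fwe_threshold_maxT(
        Y, design, ns, mask, alpha=alpha, n_perm=n_perm, seed=seed, t_map=t_map
    )
    return ArmResult(
        design=design, ns=ns, fit=fit, mask=mask, t_map=t_map, threshold=threshold
    )


def run_focal_pipeline(
    records: list[StimulationRecord],
    behaviour: str,
    grid: VolumeGrid | None = None,
    fwhm_mm: float = 10.0,
    mass_fraction: float = 0.9,
    mask_threshold: float = 1e-5,
    extra_mask: Volume | None = None,
    alpha: float = 0.05,
    n_perm: int = 2000,
    seed: int | None = 0,
    stack: DensityStack | None = None,
) -> tuple[ArmResult, DensityStack]:
    """The focal arm: densities -> mask -> repeated-measures GLM -> FWE maps.

    A precomputed ``stack`` (for the same records and settings) skips the
    density construction, which bootstrap loops exploit.
    """
    if stack is None:
        if grid is None:
            grid = grid_from_records(records)
        kernel = build_gaussian_kernel(fwhm_mm, grid.voxel_size_mm, mass_fraction)
        stack = build_density_stack(records, grid, kernel)
    mask = build_density_mask(stack, mask_threshold, extra_mask)
    Y_full = stack.data_matrix()
    arm = run_glm_arm(
        Y_full, records, behaviour, mask, alpha=alpha, n_perm=n_perm, seed=seed
    )
    return arm, stack
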