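"""Point-to-density transformation and analysis masking (the focal arm).

Each stimulation locus becomes an image that is zero everywhere except a
truncated Gaussian centred on the locus's nearest voxel. The analysis mask
keeps voxels whose mean density across all stimulation images exceeds a
threshold, excluding poorly sampled territory.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError, OutOfBoundsError
from .records import StimulationRecord
from .volumes import GaussianKernel, Volume, VolumeGrid

log = logging.getLogger(__name__)


@dataclass
class DensityStack:
    """One density volume per stimulation record, on a shared grid."""

    grid: VolumeGrid
    volumes: list[Volume]
    records: list[StimulationRecord]

    def __post_init__(self):
        if len(self.volumes) != len(self.records):
            raise InvalidArgumentError("volumes and records must be aligned")

    def __len__(self) -> int:
        return len(self.records)

    def data_matrix(self) -> np.ndarray:
        """(n_records, n_voxels) flattened view of the stack."""
        return np.stack([v.values.ravel() for v in self.volumes])

    def mean_density(self) -> Volume:
        mean = np.stack([v.values for v in self.volumes]).mean(axis=0)
        return Volume(self.grid, mean)


def make_density_volume(
    record: StimulationRecord, grid: VolumeGrid, kernel: GaussianKernel
) -> Volume:
    """Truncated Gaussian stencil centred at the record's nearest voxel.

    The point is snapped to the nearest voxel centre before convolution;
    the stencil is clipped at the grid boundary.
    """
    centre = grid.voxel(record.world_mm)
    if not grid.contains(centre):
        raise OutOfBoundsError(
            f"stimulation for subject {record.subject_id} at {record.world_mm} "
            f"maps to voxel {tuple(centre)} outside grid {grid.shape}"
        )
    values = np.zeros(grid.shape)
    half = kernel.half_width
    lo = [max(0, centre[a] - half[a]) for a in range(3)]
    hi = [min(grid.shape[a], centre[a] + half[a] + 1) for a in range(3)]
    klo = [lo[a] - (centre[a] - half[a]) for a in range(3)]
    khi = [klo[a] + (hi[a] - lo[a]) for a in range(3)]
    values[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = kernel.weights[
        klo[0] : khi[0], klo[1] : khi[1], klo[2] : khi[2]
    ]
    return Volume(grid, values)


def build_density_stack(
    records: list[StimulationRecord], grid: VolumeGrid, kernel: GaussianKernel
) -> DensityStack:
    volumes = [make_density_volume(r, grid, kernel) for r in records]
    return DensityStack(grid=grid, volumes=volumes, records=list(records))


def build_density_mask(
    stack: DensityStack,
    density_threshold: float = 1e-5,
    extra_mask: Volume | None = None,
) -> Volume:
    """Binary mask: mean stimulation density above threshold.

    Intersected with ``extra_mask`` (e.g. an anatomical mask supplied as an
    input volume) when given.
    """
    if len(stack) == 0:
        raise InvalidArgumentError("cannot build a mask from an empty stack")
    if density_threshold < 0:
        raise InvalidArgumentError("density_threshold must be >= 0")
    mean = stack.mean_density().values
    mask = (mean > density_threshold).astype(float)
    if extra_mask is not None:
        if extra_mask.grid != stack.grid:
            raise InvalidArgumentError("extra_mask grid differs from stack grid")
        mask *= (extra_mask.values > 0).astype(float)
    if mask.sum() == 0:
        log.warning(
            "density mask is empty at threshold %g (max mean density %g)",
            density_threshold,
            mean.max(),
        )
    return Volume(stack.grid, mask)


def behaviour_counts(
    records: list[StimulationRecord],
) -> dict[str, tuple[int, int]]:
    """Per-behaviour (count, percent-of-total) with half-up integer rounding."""
    if not records:
        raise InvalidArgumentError("no records")
    behaviours = sorted({b for r in records for b in r.behaviours})
    total = len(records)
    out = {}
    for b in behaviours:
        count = sum(r.behaviours.get(b, 0) for r in records)
        out[b] = (count, percent_of(count, total))
    return out


def percent_of(count: int, total: int) -> int:
    """Percentage rounded half-up to the nearest integer, as in cohort tables."""
    if total <= 0:
        raise InvalidArgumentError("total must be positive")
    return int(math.floor(100.0 * count / total + 0.5))
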