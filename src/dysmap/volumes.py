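"""Voxel grids, volumes, Gaussian kernels, smoothing and IO.

Shared plumbing for both analysis arms. World coordinates are millimetres
(MNI convention); voxel indices are 0-based. A world point is assigned to its
nearest voxel centre, ties broken toward the lower index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import FormatError, InvalidArgumentError, ParseError
from .records import StimulationRecord

log = logging.getLogger(__name__)

#: FWHM of a Gaussian equals this constant times sigma.
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

COORD_COLUMNS = ("x_mm", "y_mm", "z_mm")


@dataclass(frozen=True)
class VolumeGrid:
    """A 3D sampling lattice with a voxel-index -> world-mm affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray  # 4x4, world = affine @ (i, j, k, 1)

    def __post_init__(self):
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise InvalidArgumentError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise InvalidArgumentError("affine must be invertible")
        object.__setattr__(self, "affine", affine)
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        if any(s < 1 for s in self.shape):
            raise InvalidArgumentError("shape entries must be >= 1")

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Per-axis voxel edge lengths in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def world(self, ijk) -> np.ndarray:
        """Map voxel indices (…, 3) to world coordinates in mm."""
        ijk = np.asarray(ijk, dtype=float)
        single = ijk.ndim == 1
        ijk = np.atleast_2d(ijk)
        xyz = ijk @ self.affine[:3, :3].T + self.affine[:3, 3]
        return xyz[0] if single else xyz

    def voxel(self, xyz) -> np.ndarray:
        """Nearest voxel index for world coordinates; ties toward lower index."""
        xyz = np.asarray(xyz, dtype=float)
        single = xyz.ndim == 1
        xyz = np.atleast_2d(xyz)
        inv = np.linalg.inv(self.affine)
        cont = xyz @ inv[:3, :3].T + inv[:3, 3]
        # ceil(x - 0.5) rounds halves down, implementing the lower-index tie rule
        idx = np.ceil(cont - 0.5).astype(int)
        return idx[0] if single else idx

    def contains(self, ijk) -> np.ndarray | bool:
        ijk = np.asarray(ijk, dtype=int)
        single = ijk.ndim == 1
        ijk = np.atleast_2d(ijk)
        ok = np.all((ijk >= 0) & (ijk < np.asarray(self.shape)), axis=1)
        return bool(ok[0]) if single else ok

    def __eq__(self, other):
        return (
            isinstance(other, VolumeGrid)
            and self.shape == other.shape
            and np.allclose(self.affine, other.affine)
        )

    def __hash__(self):
        return hash((self.shape, self.affine.tobytes()))


def make_grid(shape, voxel_size_mm, origin_mm=(0.0, 0.0, 0.0)) -> VolumeGrid:
    """Axis-aligned grid whose voxel (0, 0, 0) centre sits at ``origin_mm``."""
    voxel_size_mm = np.asarray(voxel_size_mm, dtype=float)
    if voxel_size_mm.size == 1:
        voxel_size_mm = np.repeat(voxel_size_mm, 3)
    if np.any(voxel_size_mm <= 0):
        raise InvalidArgumentError("voxel sizes must be positive")
    affine = np.eye(4)
    affine[:3, :3] = np.diag(voxel_size_mm)
    affine[:3, 3] = np.asarray(origin_mm, dtype=float)
    return VolumeGrid(shape=tuple(shape), affine=affine)


@dataclass
class Volume:
    """A scalar field sampled on a :class:`VolumeGrid`."""

    grid: VolumeGrid
    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.shape != self.grid.shape:
            raise InvalidArgumentError(
                f"values shape {values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise InvalidArgumentError("volume values must be finite")
        self.values = values

    def copy(self) -> "Volume":
        return Volume(self.grid, self.values.copy())

    def sample_at(self, xyz) -> np.ndarray:
        """Value at the nearest voxel of each world coordinate (0 outside)."""
        idx = np.atleast_2d(self.grid.voxel(xyz))
        inside = self.grid.contains(idx)
        out = np.zeros(len(idx))
        if np.any(inside):
            ii = idx[inside]
            out[inside] = self.values[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out if np.asarray(xyz).ndim > 1 else float(out[0])


def zeros_like(grid: VolumeGrid) -> Volume:
    return Volume(grid, np.zeros(grid.shape))


@dataclass(frozen=True)
class GaussianKernel:
    """A radially truncated Gaussian stencil on a cubic voxel lattice.

    ``weights`` are *unnormalised* (peak value 1) so that a density image
    built from an impulse keeps the FWHM interpretation of its values;
    :meth:`unit_sum_weights` provides the normalised variant for smoothing.
    """

    fwhm_mm: float
    sigma_mm: float
    truncation_radius_mm: float
    voxel_size_mm: tuple[float, float, float]
    weights: np.ndarray

    def unit_sum_weights(self) -> np.ndarray:
        return self.weights / self.weights.sum()

    @property
    def half_width(self) -> tuple[int, int, int]:
        return tuple((s - 1) // 2 for s in self.weights.shape)


def truncation_radius(sigma_mm: float, mass_fraction: float) -> float:
    """Radius enclosing ``mass_fraction`` of a 3D isotropic Gaussian.

    The radial distance of a 3D Gaussian follows a chi distribution with
    3 degrees of freedom, so the radius is its quantile scaled by sigma.
    """
    return float(stats.chi(3).ppf(mass_fraction) * sigma_mm)


def build_gaussian_kernel(
    fwhm_mm: float, voxel_size_mm, mass_fraction: float = 0.9
) -> GaussianKernel:
    """Construct a truncated Gaussian stencil.

    The stencil is odd-sided and spans the truncation radius on each axis;
    weights beyond the radius are exactly zero.
    """
    if fwhm_mm <= 0:
        raise InvalidArgumentError("fwhm_mm must be positive")
    if not 0.0 < mass_fraction < 1.0:
        raise InvalidArgumentError("mass_fraction must lie in (0, 1)")
    voxel_size_mm = np.asarray(voxel_size_mm, dtype=float)
    if voxel_size_mm.size == 1:
        voxel_size_mm = np.repeat(voxel_size_mm, 3)
    if np.any(voxel_size_mm <= 0):
        raise InvalidArgumentError("voxel sizes must be positive")

    sigma = fwhm_mm / FWHM_PER_SIGMA
    radius = truncation_radius(sigma, mass_fraction)
    half = np.ceil(radius / voxel_size_mm).astype(int)
    axes = [np.arange(-h, h + 1) * v for h, v in zip(half, voxel_size_mm)]
    dx, dy, dz = np.meshgrid(*axes, indexing="ij")
    r2 = dx**2 + dy**2 + dz**2
    weights = np.exp(-r2 / (2.0 * sigma**2))
    weights[r2 > radius**2] = 0.0
    return GaussianKernel(
        fwhm_mm=float(fwhm_mm),
        sigma_mm=float(sigma),
        truncation_radius_mm=radius,
        voxel_size_mm=tuple(voxel_size_mm),
        weights=weights,
    )


def smooth_volume(
    vol: Volume,
    fwhm_mm: float,
    mass_fraction: float = 0.9,
    renormalise: bool = False,
) -> Volume:
    """Convolve with a unit-sum truncated Gaussian.

    Boundaries are zero-padded, so values near the edge lose mass unless
    ``renormalise`` divides by the local kernel coverage.
    """
    kernel = build_gaussian_kernel(fwhm_mm, vol.grid.voxel_size_mm, mass_fraction)
    w = kernel.unit_sum_weights()
    out = ndimage.convolve(vol.values, w, mode="constant", cval=0.0)
    if renormalise:
        coverage = ndimage.convolve(
            np.ones_like(vol.values), w, mode="constant", cval=0.0
        )
        out = out / coverage
    return Volume(vol.grid, out)


# ---------------------------------------------------------------------------
# NIfTI IO


def write_volume(vol: Volume, path) -> None:
    img = nib.Nifti1Image(vol.values.astype(np.float64), vol.grid.affine)
    nib.save(img, str(path))


def read_volume(path) -> Volume:
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=float)
        affine = np.asarray(img.affine, dtype=float)
    except Exception as exc:  # nibabel raises a zoo of types for bad files
        raise FormatError(f"cannot read NIfTI volume {path}: {exc}") from exc
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got shape {data.shape}")
    grid = VolumeGrid(shape=data.shape, affine=affine)
    return Volume(grid, data)


# ---------------------------------------------------------------------------
# Stimulation tables


def read_stimulation_table(path, behaviours: list[str] | None = None) -> list[StimulationRecord]:
    """Read a delimited stimulation table into records.

    The file must carry a header with ``subject_id``, ``x_mm``, ``y_mm``,
    ``z_mm`` plus one binary column per behaviour. When ``behaviours`` is
    None, every non-coordinate column is treated as a behaviour flag.
    """
    sep = "," if str(path).lower().endswith(".csv") else "\t"
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except Exception as exc:
        raise ParseError(f"cannot read stimulation table {path}: {exc}") from exc

    required = ("subject_id",) + COORD_COLUMNS
    for col in required:
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    if behaviours is None:
        behaviours = [c for c in df.columns if c not in required]
    else:
        for b in behaviours:
            if b not in df.columns:
                raise ParseError(f"{path}: missing behaviour column {b!r}")

    out: list[StimulationRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rowd = dict(zip(df.columns, row))
        coords = []
        for col in COORD_COLUMNS:
            try:
                coords.append(float(rowd[col]))
            except (TypeError, ValueError):
                raise ParseError(
                    f"non-numeric coordinate {col}={rowd[col]!r}", row=i
                ) from None
        if not np.all(np.isfinite(coords)):
            raise ParseError(f"non-finite coordinate {coords}", row=i)
        flags = {}
        for b in behaviours:
            raw = rowd[b]
            try:
                val = float(raw)
            except (TypeError, ValueError):
                raise ParseError(f"behaviour {b}={raw!r} is not numeric", row=i) from None
            if val not in (0.0, 1.0):
                raise ParseError(f"behaviour {b}={raw!r} outside {{0,1}}", row=i)
            flags[b] = int(val)
        out.append(
            StimulationRecord(
                subject_id=str(rowd["subject_id"]),
                world_mm=tuple(coords),
                behaviours=flags,
            )
        )
    log.info("read %d stimulation records from %s", len(out), path)
    return out


def write_stimulation_table(records: list[StimulationRecord], path) -> None:
    """Write records as a TSV with the canonical column layout."""
    behaviours = sorted({b for r in records for b in r.behaviours})
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "x_mm": r.world_mm[0],
            "y_mm": r.world_mm[1],
            "z_mm": r.world_mm[2],
        }
        row.update({b: r.behaviours.get(b, 0) for b in behaviours})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
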