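"""Synthetic cohorts, ground-truth effect maps, parcellations and connectomes.

Outcomes are drawn from a logistic model with per-subject random intercepts —
deliberately *not* the linear model the analysis fits — so the pipeline is
exercised under realistic model mismatch. Connectomes combine distance-decay
weights with designated long-range bundles between region pairs, giving a
ground truth for remote-hub recovery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .connectome import ConnectomeGraph
from .errors import ConfigError, InvalidArgumentError
from .predictive import Parcellation
from .records import StimulationRecord, subject_blocks
from .volumes import Volume, VolumeGrid, make_grid

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TruthRegion:
    """Spherical ground-truth effect region for one behaviour."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    behaviour: str
    effect_logodds: float

    def contains(self, xyz: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(np.atleast_2d(xyz) - np.asarray(self.center_mm), axis=1)
        return d <= self.radius_mm


@dataclass(frozen=True)
class Bundle:
    """Long-range connection boost between two spherical node groups."""

    center_a_mm: tuple[float, float, float]
    center_b_mm: tuple[float, float, float]
    radius_mm: float
    weight: float


@dataclass
class ConnectomeSpec:
    n_nodes: int = 600
    decay_mm: float = 12.0
    bundles: list[Bundle] = field(default_factory=list)
    shell_fraction: float = 1.0  # fraction of the grid radius forming the shell


@dataclass
class SyntheticConfig:
    n_subjects: int = 20
    loci_range: tuple[int, int] = (8, 16)
    grid: VolumeGrid = field(default_factory=lambda: make_grid((40, 48, 40), 3.0))
    sampling_mode: str = "uniform"  # grid_electrodes | depth_trajectories | uniform
    behaviours: tuple[str, ...] = ("positive_motor",)
    truth_regions: list[TruthRegion] = field(default_factory=list)
    baseline_logodds: float = -1.0
    subject_sd: float = 0.5
    connectome: ConnectomeSpec | None = None
    seed: int = 0
    #: optional (lo_mm, hi_mm) box confining loci to a sub-volume (e.g. a
    #: sampled strip), mirroring clinically constrained electrode coverage
    sampling_box: tuple[tuple[float, float, float], tuple[float, float, float]] | None = None

    def __post_init__(self):
        if self.sampling_mode not in (
            "grid_electrodes", "depth_trajectories", "uniform"
        ):
            raise ConfigError(f"unknown sampling_mode {self.sampling_mode!r}")
        for tr in self.truth_regions:
            if tr.radius_mm <= 0:
                raise ConfigError("truth region radius must be positive")
            if tr.behaviour not in self.behaviours:
                raise ConfigError(
                    f"truth region behaviour {tr.behaviour!r} not in behaviours"
                )
            idx = self.grid.voxel(tr.center_mm)
            if not self.grid.contains(idx):
                raise ConfigError(
                    f"truth region centre {tr.center_mm} lies outside the grid"
                )


@dataclass
class SyntheticTruth:
    truth_volumes: dict[str, Volume]
    subject_intercepts: dict[tuple[str, str], float]  # (subject, behaviour)
    probabilities: np.ndarray  # n_records x n_behaviours
    behaviours: tuple[str, ...]


def _grid_bounds(grid: VolumeGrid) -> tuple[np.ndarray, np.ndarray]:
    lo = grid.world((0, 0, 0))
    hi = grid.world(tuple(s - 1 for s in grid.shape))
    return np.minimum(lo, hi), np.maximum(lo, hi)


def _sample_loci(
    cfg: SyntheticConfig, rng: np.random.Generator, n_loci: int
) -> np.ndarray:
    lo, hi = _grid_bounds(cfg.grid)
    if cfg.sampling_box is not None:
        lo = np.maximum(lo, np.asarray(cfg.sampling_box[0], dtype=float))
        hi = np.minimum(hi, np.asarray(cfg.sampling_box[1], dtype=float))
    span = hi - lo
    if cfg.sampling_mode == "uniform":
        return lo + rng.uniform(0, 1, size=(n_loci, 3)) * span
    if cfg.sampling_mode == "grid_electrodes":
        # planar k x k lattice patch with ~10 mm pitch, random in-plane axes
        k = max(2, int(np.ceil(np.sqrt(n_loci))))
        pitch = 10.0
        axes = rng.permutation(3)
        u, v, w = axes
        centre = lo + rng.uniform(0.3, 0.7, size=3) * span
        pts = []
        for i in range(k):
            for j in range(k):
                if len(pts) >= n_loci:
                    break
                p = centre.copy()
                p[u] += (i - (k - 1) / 2) * pitch
                p[v] += (j - (k - 1) / 2) * pitch
                pts.append(p)
        pts = np.asarray(pts)
    else:  # depth_trajectories: collinear points along a random line
        entry = lo + rng.uniform(0.2, 0.8, size=3) * span
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        step = 5.0
        pts = entry + np.outer(np.arange(n_loci) * step, direction)
    return np.clip(pts, lo, hi)


def generate_cohort(
    cfg: SyntheticConfig,
) -> tuple[list[StimulationRecord], SyntheticTruth]:
    """Draw a cohort of clustered, within-subject-correlated stimulations.

    Outcome probability per behaviour: logistic(baseline + subject intercept
    + sum of effect log-odds of truth regions containing the locus).
    Deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    lo_n, hi_n = cfg.loci_range
    if not 1 <= lo_n <= hi_n:
        raise ConfigError("loci_range must satisfy 1 <= lo <= hi")

    intercepts = {
        (f"sub{s:03d}", b): float(rng.normal(0.0, cfg.subject_sd))
        for s in range(cfg.n_subjects)
        for b in cfg.behaviours
    }
    records: list[StimulationRecord] = []
    probs: list[list[float]] = []
    for s in range(cfg.n_subjects):
        subject = f"sub{s:03d}"
        n_loci = int(rng.integers(lo_n, hi_n + 1))
        pts = _sample_loci(cfg, rng, n_loci)
        for p in pts:
            flags = {}
            row_p = []
            for b in cfg.behaviours:
                eta = cfg.baseline_logodds + intercepts[(subject, b)]
                for tr in cfg.truth_regions:
                    if tr.behaviour == b and tr.contains(p)[0]:
                        eta += tr.effect_logodds
                prob = 1.0 / (1.0 + np.exp(-eta))
                flags[b] = int(rng.uniform() < prob)
                row_p.append(prob)
            records.append(
                StimulationRecord(
                    subject_id=subject, world_mm=tuple(float(x) for x in p),
                    behaviours=flags,
                )
            )
            probs.append(row_p)

    truth_volumes = {}
    ii, jj, kk = np.meshgrid(
        *[np.arange(s) for s in cfg.grid.shape], indexing="ij"
    )
    voxel_world = cfg.grid.world(
        np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    )
    for b in cfg.behaviours:
        truth = np.zeros(cfg.grid.n_voxels)
        for tr in cfg.truth_regions:
            if tr.behaviour == b:
                truth = np.maximum(truth, tr.contains(voxel_world).astype(float))
        truth_volumes[b] = Volume(cfg.grid, truth.reshape(cfg.grid.shape))

    truth = SyntheticTruth(
        truth_volumes=truth_volumes,
        subject_intercepts=intercepts,
        probabilities=np.asarray(probs),
        behaviours=cfg.behaviours,
    )
    log.info(
        "generated %d records across %d subjects (seed %d)",
        len(records), cfg.n_subjects, cfg.seed,
    )
    return records, truth


def generate_connectome(cfg: SyntheticConfig) -> ConnectomeGraph:
    """Distance-decay connectome on a grey-matter shell, plus bundles.

    weight(i, j) = exp(-d_ij / decay) with additive bundle boosts between
    node groups inside the bundle end spheres.
    """
    spec = cfg.connectome
    if spec is None:
        raise ConfigError("config has no connectome spec")
    if spec.n_nodes < 2:
        raise InvalidArgumentError("n_nodes must be >= 2")
    rng = np.random.default_rng(cfg.seed + 1)
    grid = cfg.grid
    shape = np.asarray(grid.shape)
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    idx = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    # ellipsoidal grey-matter shell in voxel space
    centre = (shape - 1) / 2.0
    r = np.linalg.norm((idx - centre) / (shape / 2.0), axis=1)
    shell = (r <= 0.95) & (r >= 0.95 * (1.0 - spec.shell_fraction))
    candidates = np.flatnonzero(shell)
    if len(candidates) < spec.n_nodes:
        raise ConfigError(
            f"shell holds {len(candidates)} voxels < n_nodes {spec.n_nodes}"
        )
    chosen = np.sort(rng.choice(candidates, size=spec.n_nodes, replace=False))
    coords = grid.world(idx[chosen])

    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    weights = np.exp(-d / spec.decay_mm)
    np.fill_diagonal(weights, 0.0)
    for bundle in spec.bundles:
        in_a = np.linalg.norm(coords - bundle.center_a_mm, axis=1) <= bundle.radius_mm
        in_b = np.linalg.norm(coords - bundle.center_b_mm, axis=1) <= bundle.radius_mm
        if (in_a & in_b).any():
            log.warning("bundle end regions overlap; proceeding")
        weights[np.ix_(in_a, in_b)] += bundle.weight
        weights[np.ix_(in_b, in_a)] += bundle.weight
    weights[weights < 1e-8] = 0.0
    return ConnectomeGraph(
        node_coords_mm=coords, grid=grid, weights=sparse.csr_matrix(weights)
    )


def make_null_cohort(
    records: list[StimulationRecord], seed: int | None = 0
) -> list[StimulationRecord]:
    """Permute behaviour maps across each subject's records.

    Destroys any location-behaviour association while preserving per-subject
    outcome counts and within-record flag co-occurrence.
    """
    if not records:
        raise InvalidArgumentError("no records")
    rng = np.random.default_rng(seed)
    out = list(records)
    for idx in subject_blocks(records).values():
        perm = rng.permutation(idx)
        for dst, src in zip(idx, perm):
            out[dst] = StimulationRecord(
                subject_id=records[dst].subject_id,
                world_mm=records[dst].world_mm,
                behaviours=dict(records[src].behaviours),
            )
    return out


def make_parcellation(grid: VolumeGrid, block_voxels: tuple[int, int, int]) -> Parcellation:
    """Regular cuboid parcels tiling the grid (labels start at 1)."""
    if any(b < 1 for b in block_voxels):
        raise InvalidArgumentError("block_voxels entries must be >= 1")
    shape = grid.shape
    labels = np.zeros(shape)
    n_blocks = [int(np.ceil(shape[a] / block_voxels[a])) for a in range(3)]
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    bi = ii // block_voxels[0]
    bj = jj // block_voxels[1]
    bk = kk // block_voxels[2]
    labels = 1 + bi * n_blocks[1] * n_blocks[2] + bj * n_blocks[2] + bk
    return Parcellation(label_volume=Volume(grid, labels.astype(float)))
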