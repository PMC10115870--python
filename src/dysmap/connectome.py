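"""Seed-to-all-grey-matter projection of stimulations through a connectome.

The connectome is an undirected weighted graph over grey-matter voxel nodes.
Each stimulation is mapped to its nearest node and its adjacency row is
rendered as an image volume (direct edge weights only — no path composition),
clamped at extreme intensity quantiles, smoothed, and analysed with the same
repeated-measures GLM as the focal arm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread
from scipy.spatial import cKDTree

from .errors import FormatError, InvalidArgumentError, UnmappableSeedError
from .focal import DensityStack
from .pipeline import ArmResult, run_glm_arm
from .records import StimulationRecord
from .volumes import Volume, VolumeGrid, smooth_volume

log = logging.getLogger(__name__)


def complete_graph_edges(n_nodes: int) -> int:
    """Unique undirected edge capacity of a complete graph: n(n-1)/2."""
    if n_nodes < 0:
        raise InvalidArgumentError("n_nodes must be non-negative")
    return n_nodes * (n_nodes - 1) // 2


@dataclass
class ConnectomeGraph:
    """Grey-matter voxel nodes with symmetric non-negative edge weights."""

    node_coords_mm: np.ndarray  # n x 3 world coordinates
    grid: VolumeGrid
    weights: sparse.csr_matrix  # n x n, symmetric, diagonal ignored

    def __post_init__(self):
        self.node_coords_mm = np.asarray(self.node_coords_mm, dtype=float)
        n = self.node_coords_mm.shape[0]
        if self.weights.shape != (n, n):
            raise InvalidArgumentError(
                f"weight matrix {self.weights.shape} does not match {n} nodes"
            )
        if self.weights.nnz and self.weights.data.min() < 0:
            raise InvalidArgumentError("edge weights must be non-negative")
        voxels = self.grid.voxel(self.node_coords_mm)
        if not np.all(self.grid.contains(voxels)):
            raise InvalidArgumentError("some nodes map outside the grid")
        if len({tuple(v) for v in voxels}) != n:
            raise InvalidArgumentError("nodes must map to unique voxels")
        self._node_voxels = voxels
        self._tree = cKDTree(self.node_coords_mm)

    @property
    def n_nodes(self) -> int:
        return self.node_coords_mm.shape[0]

    @property
    def node_voxels(self) -> np.ndarray:
        return self._node_voxels

    def edge_capacity(self) -> int:
        return complete_graph_edges(self.n_nodes)

    def scaled(self, factor: float) -> "ConnectomeGraph":
        return ConnectomeGraph(self.node_coords_mm, self.grid, self.weights * factor)


def read_connectome(matrix_path, coords_path, grid: VolumeGrid) -> ConnectomeGraph:
    """Load a Matrix Market weight matrix plus a node coordinate table.

    Asymmetric inputs are symmetrised by averaging (A + A')/2 with the
    maximum asymmetry logged.
    """
    try:
        A = sparse.csr_matrix(mmread(str(matrix_path)))
    except Exception as exc:
        raise FormatError(f"cannot read Matrix Market file {matrix_path}: {exc}") from exc
    coords = pd.read_csv(coords_path, sep="\t")
    for col in ("node_id", "x_mm", "y_mm", "z_mm"):
        if col not in coords.columns:
            raise FormatError(f"{coords_path}: missing column {col!r}")
    coords = coords.sort_values("node_id")
    n = len(coords)
    if A.shape != (n, n):
        raise FormatError(
            f"node count mismatch: matrix is {A.shape}, coordinate table has {n} rows"
        )
    if A.nnz and A.data.min() < 0:
        raise FormatError("connectome contains negative weights")
    asym = abs(A - A.T)
    max_asym = asym.max() if asym.nnz else 0.0
    if max_asym > 1e-9:
        log.warning("asymmetric connectome (max |A - A'| = %g); averaging", max_asym)
    A = (A + A.T) * 0.5
    return ConnectomeGraph(
        node_coords_mm=coords[["x_mm", "y_mm", "z_mm"]].to_numpy(float),
        grid=grid,
        weights=sparse.csr_matrix(A),
    )


def write_connectome(graph: ConnectomeGraph, matrix_path, coords_path) -> None:
    from scipy.io import mmwrite

    mmwrite(str(matrix_path), sparse.coo_matrix(graph.weights))
    pd.DataFrame(
        {
            "node_id": np.arange(graph.n_nodes),
            "x_mm": graph.node_coords_mm[:, 0],
            "y_mm": graph.node_coords_mm[:, 1],
            "z_mm": graph.node_coords_mm[:, 2],
        }
    ).to_csv(coords_path, sep="\t", index=False)


def nearest_node(
    graph: ConnectomeGraph, world_mm, cutoff_mm: float = 5.0
) -> tuple[int, float]:
    """Closest node to a world point; ties go to the lower node id."""
    world_mm = np.asarray(world_mm, dtype=float)
    dists, idx = graph._tree.query(world_mm, k=2)
    dists, idx = np.atleast_1d(dists), np.atleast_1d(idx)
    node, dist = int(idx[0]), float(dists[0])
    if len(idx) > 1 and abs(dists[1] - dists[0]) < 1e-9:
        node = int(min(idx[0], idx[1]))
    if dist > cutoff_mm:
        raise UnmappableSeedError(
            f"nearest node to {tuple(world_mm)} is {dist:.2f} mm away "
            f"(cutoff {cutoff_mm} mm)"
        )
    return node, dist


def project_stimulation(
    graph: ConnectomeGraph,
    record: StimulationRecord,
    cutoff_mm: float = 5.0,
    seed_value: str = "max_edge",
) -> Volume:
    """Render the seed's adjacency row on the connectome grid.

    Direct edge weights only. The seed's own voxel takes the maximum of its
    edge weights by default (``seed_value='max_edge'``) or zero
    (``seed_value='zero'``).
    """
    seed, _ = nearest_node(graph, record.world_mm, cutoff_mm)
    row = np.asarray(graph.weights.getrow(seed).todense()).ravel()
    row[seed] = row.max() if seed_value == "max_edge" else 0.0
    if row.max() == 0.0:
        log.info("seed node %d has no edges; all-zero projection", seed)
    values = np.zeros(graph.grid.shape)
    vox = graph.node_voxels
    values[vox[:, 0], vox[:, 1], vox[:, 2]] = row
    return Volume(graph.grid, values)


def clamp_intensities(vol: Volume, low_q: float = 0.001, high_q: float = 0.999) -> Volume:
    """Clamp values outside the [low_q, high_q] quantiles of nonzero intensities."""
    if not 0.0 <= low_q < high_q <= 1.0:
        raise InvalidArgumentError("need 0 <= low_q < high_q <= 1")
    nonzero = vol.values[vol.values != 0]
    if nonzero.size == 0:
        return vol.copy()
    # order-statistic quantiles (no interpolation) make clamping idempotent
    lo = np.quantile(nonzero, low_q, method="higher")
    hi = np.quantile(nonzero, high_q, method="lower")
    out = vol.values.copy()
    active = vol.values != 0
    out[active] = np.clip(out[active], lo, hi)
    return Volume(vol.grid, out)


def build_dysconnectome_stack(
    graph: ConnectomeGraph,
    records: list[StimulationRecord],
    fwhm_mm: float = 6.0,
    low_q: float = 0.001,
    high_q: float = 0.999,
    cutoff_mm: float = 5.0,
    seed_value: str = "max_edge",
    clamp_before_smoothing: bool = True,
) -> DensityStack:
    """Project -> clamp -> smooth each stimulation into a connectivity volume."""
    volumes = []
    for record in records:
        vol = project_stimulation(graph, record, cutoff_mm, seed_value)
        if clamp_before_smoothing:
            vol = clamp_intensities(vol, low_q, high_q)
            vol = smooth_volume(vol, fwhm_mm)
        else:
            vol = smooth_volume(vol, fwhm_mm)
            vol = clamp_intensities(vol, low_q, high_q)
        volumes.append(vol)
    return DensityStack(grid=graph.grid, volumes=volumes, records=list(records))


def run_dysconnectome_pipeline(
    graph: ConnectomeGraph,
    records: list[StimulationRecord],
    behaviour: str,
    fwhm_mm: float = 6.0,
    mask_threshold: float = 0.0,
    low_q: float = 0.001,
    high_q: float = 0.999,
    cutoff_mm: float = 5.0,
    seed_value: str = "max_edge",
    alpha: float = 0.05,
    n_perm: int = 2000,
    seed: int | None = 0,
    stack: DensityStack | None = None,
) -> tuple[ArmResult, DensityStack]:
    """Full connective arm with the same statistical design as the focal arm."""
    from .focal import build_density_mask

    if stack is None:
        stack = build_dysconnectome_stack(
            graph, records, fwhm_mm, low_q, high_q, cutoff_mm, seed_value
        )
    mask = build_density_mask(stack, mask_threshold)
    if mask.values.sum() == 0:
        # degenerate graph (e.g. no edges anywhere): empty maps, not an error
        log.warning("dysconnectome mask is empty; returning empty maps")
        from .glm import ThresholdResult, build_design, estimate_nonsphericity
        import pandas as pd

        design = build_design(records, behaviour)
        ns = estimate_nonsphericity(stack.data_matrix().T, design)
        zero = Volume(graph.grid, np.zeros(graph.grid.shape))
        threshold = ThresholdResult(
            critical_t=float("inf"),
            alpha=alpha,
            method="degenerate",
            sig_map=zero.copy(),
            clusters=pd.DataFrame(
                columns=["cluster_id", "extent_voxels", "peak_t",
                         "peak_x_mm", "peak_y_mm", "peak_z_mm"]
            ),
        )
        arm = ArmResult(
            design=design, ns=ns, fit=None, mask=mask,
            t_map=zero, threshold=threshold,
        )
        return arm, stack
    arm = run_glm_arm(
        stack.data_matrix(), records, behaviour, mask,
        alpha=alpha, n_perm=n_perm, seed=seed,
    )
    return arm, stack
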