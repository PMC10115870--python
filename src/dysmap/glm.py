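"""Voxel-wise repeated-measures GLM with whitening and permutation FWE control.

One model per behaviour: the design holds one indicator column per subject
plus the binary behaviour regressor, the dependent variable is the per-voxel
image intensity (density or connectivity). Within-subject error correlation
is modelled as a single pooled compound-symmetry coefficient and removed by
prewhitening, which leaves the residual degrees of freedom unchanged.
Family-wise error over voxels is controlled by a maxT permutation scheme
with subjects as exchangeability blocks.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import DegenerateDesignError, InvalidArgumentError
from .records import StimulationRecord, behaviour_vector, subject_blocks
from .volumes import Volume, VolumeGrid

log = logging.getLogger(__name__)

_ZERO_VAR_TOL = 1e-12


@dataclass
class DesignMatrix:
    """Rows = stimulations; columns = subject indicators then the behaviour."""

    X: np.ndarray
    subject_blocks: dict[str, np.ndarray]
    behaviour_col: int
    behaviour: str
    rank: int = field(init=False)
    df: int = field(init=False)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        n = self.X.shape[0]
        self.rank = int(np.linalg.matrix_rank(self.X))
        self.df = n - self.rank
        if self.df <= 0:
            raise DegenerateDesignError(
                f"residual df = {n} - {self.rank} <= 0; model not estimable"
            )

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_cols(self) -> int:
        return self.X.shape[1]

    def behaviour_contrast(self) -> np.ndarray:
        c = np.zeros(self.n_cols)
        c[self.behaviour_col] = 1.0
        return c


def build_design(records: list[StimulationRecord], behaviour: str) -> DesignMatrix:
    """Subject-indicator columns (sorted subject order) plus the behaviour column."""
    blocks = subject_blocks(records)
    if len(blocks) < 2:
        raise DegenerateDesignError("need at least 2 subjects")
    g = behaviour_vector(records, behaviour)
    if g.min() == g.max():
        raise DegenerateDesignError(
            f"behaviour {behaviour!r} is constant ({g[0]:g}) across all records"
        )
    n = len(records)
    X = np.zeros((n, len(blocks) + 1))
    for j, subj in enumerate(blocks):
        X[blocks[subj], j] = 1.0
    X[:, -1] = g
    design = DesignMatrix(
        X=X, subject_blocks=blocks, behaviour_col=len(blocks), behaviour=behaviour
    )
    log.info(
        "design: %d rows, %d subjects, rank %d, residual df %d",
        n, len(blocks), design.rank, design.df,
    )
    return design


@dataclass
class NonSphericity:
    """Pooled compound-symmetry error model and its whitening transform."""

    rho: float
    blocks: dict[str, np.ndarray]
    n_rows: int

    def covariance(self) -> np.ndarray:
        """Implied error correlation matrix V (unit diagonal)."""
        V = np.eye(self.n_rows)
        for idx in self.blocks.values():
            for a in idx:
                for b in idx:
                    if a != b:
                        V[a, b] = self.rho
        return V

    def whitener(self) -> np.ndarray:
        """W = V^{-1/2}, block-closed-form: W V W^T = I.

        A compound-symmetry block (1-rho) I + rho J has eigenvalue
        1 + (m-1) rho on the constant direction and 1 - rho elsewhere, so
        its inverse square root is beta I + ((alpha - beta)/m) J.
        """
        W = np.eye(self.n_rows)
        for idx in self.blocks.values():
            m = len(idx)
            if m < 2 or self.rho == 0.0:
                continue
            alpha = 1.0 / math.sqrt(1.0 + (m - 1) * self.rho)
            beta = 1.0 / math.sqrt(1.0 - self.rho)
            block = beta * np.eye(m) + ((alpha - beta) / m) * np.ones((m, m))
            W[np.ix_(idx, idx)] = block
        return W


def estimate_nonsphericity(
    Y: np.ndarray, design: DesignMatrix, mask_idx: np.ndarray | None = None
) -> NonSphericity:
    """Pool a single within-subject correlation across voxels.

    Residuals are taken against the *reduced* design (intercept plus the
    behaviour regressor, without subject indicators): subject indicators
    absorb block means exactly and would make the block correlation
    unidentifiable (centred compound-symmetry residuals always correlate at
    -1/(m-1) regardless of the true coefficient).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))  # voxels x rows
    if mask_idx is not None:
        Y = Y[mask_idx]
    n = design.n_rows
    if Y.shape[1] != n:
        raise InvalidArgumentError("Y row count must match the design")
    blocks = design.subject_blocks
    sizes = [len(v) for v in blocks.values()]
    m_max = max(sizes)
    if m_max < 2:
        log.info("all subject blocks are singletons; rho set to 0")
        return NonSphericity(rho=0.0, blocks=blocks, n_rows=n)

    X0 = np.column_stack([np.ones(n), design.X[:, design.behaviour_col]])
    P = X0 @ np.linalg.pinv(X0)
    R = Y - Y @ P.T  # residuals, per voxel

    num = 0.0
    n_pairs = 0
    den = 0.0
    n_obs = 0
    for idx in blocks.values():
        Rb = R[:, idx]
        m = len(idx)
        s = Rb.sum(axis=1)
        sq = (Rb**2).sum(axis=1)
        den += sq.sum()
        n_obs += Y.shape[0] * m
        if m >= 2:
            num += ((s**2 - sq) / 2.0).sum()
            n_pairs += Y.shape[0] * (m * (m - 1) // 2)
    if den <= 0 or n_pairs == 0:
        rho = 0.0
    else:
        rho = (num / n_pairs) / (den / n_obs)
    lo = -1.0 / (m_max - 1) + 1e-3
    hi = 1.0 - 1e-3
    rho = float(np.clip(rho, lo, hi))
    log.info("pooled within-subject rho = %.4f (clipped to [%.4f, %.4f])", rho, lo, hi)
    return NonSphericity(rho=rho, blocks=blocks, n_rows=n)


@dataclass
class GlmFit:
    """Per-voxel whitened least-squares fit."""

    beta: np.ndarray       # voxels x p
    sigma2: np.ndarray     # voxels
    df: int
    Xw: np.ndarray         # whitened design, n x p
    XtX_pinv: np.ndarray   # (Xw' Xw)^+, p x p
    rank: int
    n_zero_variance: int = 0


def fit_glm(Y: np.ndarray, design: DesignMatrix, ns: NonSphericity) -> GlmFit:
    """Whitened (GLS) fit at every voxel.

    ``Y`` is voxels x rows. beta = (WX)^+ (WY); sigma2 = RSS / df with
    df = rows - rank(X), unchanged by whitening.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[1] != design.n_rows:
        raise InvalidArgumentError("Y row count must match the design")
    W = ns.whitener()
    Xw = W @ design.X
    Yw = Y @ W.T
    pinv = np.linalg.pinv(Xw)
    beta = Yw @ pinv.T  # voxels x p
    resid = Yw - beta @ Xw.T
    rss = (resid**2).sum(axis=1)
    sigma2 = rss / design.df
    n_zero = int((sigma2 <= _ZERO_VAR_TOL).sum())
    if n_zero:
        log.info("%d voxel(s) with zero residual variance", n_zero)
    return GlmFit(
        beta=beta,
        sigma2=sigma2,
        df=design.df,
        Xw=Xw,
        XtX_pinv=np.linalg.pinv(Xw.T @ Xw),
        rank=design.rank,
        n_zero_variance=n_zero,
    )


def t_contrast(fit: GlmFit, contrast) -> np.ndarray:
    """One-tailed t statistic of a contrast at every voxel."""
    c = np.asarray(contrast, dtype=float)
    if c.shape != (fit.Xw.shape[1],):
        raise InvalidArgumentError("contrast length must equal design columns")
    if np.allclose(c, 0):
        raise InvalidArgumentError("contrast of all zeros")
    # estimability: c must lie in the row space of the whitened design
    proj = np.linalg.pinv(fit.Xw) @ fit.Xw @ c
    if not np.allclose(proj, c, atol=1e-8 * max(1.0, np.abs(c).max())):
        raise InvalidArgumentError("contrast is not estimable under this design")
    var_c = float(c @ fit.XtX_pinv @ c)
    num = fit.beta @ c
    t = np.zeros_like(num)
    ok = fit.sigma2 > _ZERO_VAR_TOL
    t[ok] = num[ok] / np.sqrt(fit.sigma2[ok] * var_c)
    return t


def critical_t_uncorrected(p: float, df: float) -> float:
    """Upper-tail Student-t quantile for a one-tailed test."""
    if not 0.0 < p < 1.0:
        raise InvalidArgumentError("p must lie in (0, 1)")
    if df <= 0:
        raise InvalidArgumentError("df must be positive")
    return float(stats.t.isf(p, df))


@dataclass
class ThresholdResult:
    critical_t: float
    alpha: float
    method: str
    sig_map: Volume
    clusters: pd.DataFrame
    max_t_distribution: np.ndarray | None = None


def _count_within_block_labelings(g: np.ndarray, blocks: dict[str, np.ndarray]) -> int:
    total = 1
    for idx in blocks.values():
        k = int(g[idx].sum())
        total *= math.comb(len(idx), k)
        if total > 10**9:
            return total
    return total


def _enumerate_labelings(g: np.ndarray, blocks: dict[str, np.ndarray]):
    """Yield every distinct within-block arrangement of the binary labels."""
    block_opts = []
    block_idx = []
    for idx in blocks.values():
        k = int(g[idx].sum())
        block_opts.append(list(itertools.combinations(range(len(idx)), k)))
        block_idx.append(idx)
    for combo in itertools.product(*block_opts):
        gp = np.zeros_like(g)
        for ones, idx in zip(combo, block_idx):
            for o in ones:
                gp[idx[o]] = 1.0
        yield gp


class _FastBehaviourT:
    """Closed-form behaviour-column t via residualisation against the rest.

    Only the behaviour column changes under permutation, so nuisance columns
    are projected out of the whitened data once; each permutation then costs
    one matrix-vector product per voxel (Frisch-Waugh-Lovell).
    """

    def __init__(self, Y: np.ndarray, design: DesignMatrix, ns: NonSphericity):
        self.design = design
        self.W = ns.whitener()
        Xw = self.W @ design.X
        nuisance = np.delete(Xw, design.behaviour_col, axis=1)
        Q, R = np.linalg.qr(nuisance)
        # drop numerically null directions of the nuisance space
        self.Q = Q[:, np.abs(np.diag(R)) > 1e-10]
        Yw = np.atleast_2d(Y) @ self.W.T
        self.Yr = Yw - (Yw @ self.Q) @ self.Q.T
        self.yss = (self.Yr**2).sum(axis=1)
        self.df = design.df

    def t_for_labels(self, g: np.ndarray) -> np.ndarray:
        gw = self.W @ g
        gr = gw - self.Q @ (self.Q.T @ gw)
        ss_g = float(gr @ gr)
        if ss_g <= _ZERO_VAR_TOL:
            return np.zeros(self.Yr.shape[0])
        num = self.Yr @ gr
        rss = np.maximum(self.yss - num**2 / ss_g, 0.0)
        sigma2 = rss / self.df
        t = np.zeros_like(num)
        ok = sigma2 > _ZERO_VAR_TOL
        t[ok] = (num[ok] / ss_g) / np.sqrt(sigma2[ok] / ss_g)
        return t


def fwe_threshold_maxT(
    Y: np.ndarray,
    design: DesignMatrix,
    ns: NonSphericity,
    mask: Volume,
    alpha: float = 0.05,
    n_perm: int = 2000,
    seed: int | None = 0,
    t_map: Volume | None = None,
) -> ThresholdResult:
    """Peak-voxel FWE threshold by within-subject label permutation.

    ``Y`` must be voxels x rows restricted to in-mask voxels (same order as
    ``mask`` nonzeros in C order). The observed statistic is included in the
    maxT distribution; the critical value is its (1 - alpha) empirical
    quantile with a conservative ceiling-index tie rule.
    """
    if not 0.0 < alpha <= 1.0:
        raise InvalidArgumentError("alpha must lie in (0, 1]")
    if n_perm < 1:
        raise InvalidArgumentError("n_perm must be >= 1")
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    g = design.X[:, design.behaviour_col].copy()
    engine = _FastBehaviourT(Y, design, ns)
    t_obs = engine.t_for_labels(g)

    n_distinct = _count_within_block_labelings(g, design.subject_blocks)
    max_ts = [float(t_obs.max())]
    if n_distinct < 1.0 / alpha:
        warnings.warn(
            f"only {n_distinct} distinct within-subject labelings "
            f"(< 1/alpha = {1.0 / alpha:.0f}); falling back to exact enumeration",
            stacklevel=2,
        )
        max_ts = []
        for gp in _enumerate_labelings(g, design.subject_blocks):
            max_ts.append(float(engine.t_for_labels(gp).max()))
        method = "perm_maxT_exact"
    elif n_distinct <= n_perm:
        max_ts = []
        for gp in _enumerate_labelings(g, design.subject_blocks):
            max_ts.append(float(engine.t_for_labels(gp).max()))
        method = "perm_maxT_exact"
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            gp = g.copy()
            for idx in design.subject_blocks.values():
                gp[idx] = gp[rng.permutation(idx)] if len(idx) > 1 else gp[idx]
            max_ts.append(float(engine.t_for_labels(gp).max()))
        method = "perm_maxT"

    max_ts = np.sort(np.asarray(max_ts))
    B = len(max_ts)
    k = math.ceil((1.0 - alpha) * B)
    critical_t = float(max_ts[max(k - 1, 0)])

    sig = np.zeros(mask.grid.shape)
    mask_flat = mask.values.ravel() > 0
    sig_flat = np.zeros(mask_flat.sum())
    sig_flat[t_obs >= critical_t] = 1.0
    sig.ravel()[mask_flat] = sig_flat
    sig_map = Volume(mask.grid, sig)

    if t_map is None:
        t_full = np.zeros(mask.grid.shape)
        t_full.ravel()[mask_flat] = t_obs
        t_map = Volume(mask.grid, t_full)
    clusters = extract_clusters(sig_map, t_map)
    return ThresholdResult(
        critical_t=critical_t,
        alpha=alpha,
        method=method,
        sig_map=sig_map,
        clusters=clusters,
        max_t_distribution=max_ts,
    )


def extract_clusters(sig_map: Volume, t_map: Volume) -> pd.DataFrame:
    """26-connected supra-threshold components, sorted by peak t descending."""
    structure = np.ones((3, 3, 3), dtype=int)
    labels, n = ndimage.label(sig_map.values > 0, structure=structure)
    rows = []
    grid = sig_map.grid
    for lab in range(1, n + 1):
        idx = np.argwhere(labels == lab)
        ts = t_map.values[idx[:, 0], idx[:, 1], idx[:, 2]]
        peak = idx[int(np.argmax(ts))]
        world = grid.world(peak)
        rows.append(
            {
                "extent_voxels": len(idx),
                "peak_t": float(ts.max()),
                "peak_x_mm": float(world[0]),
                "peak_y_mm": float(world[1]),
                "peak_z_mm": float(world[2]),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["extent_voxels", "peak_t", "peak_x_mm", "peak_y_mm", "peak_z_mm"],
    )
    df = df.sort_values("peak_t", ascending=False).reset_index(drop=True)
    df.insert(0, "cluster_id", np.arange(1, len(df) + 1))
    return df
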