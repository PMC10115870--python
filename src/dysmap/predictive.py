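"""SPM-map vs ROI-map predictive benchmarking with bootstrapped metrics.

Both arms are fitted on a mapping split and judged on held-out loci: a test
locus counts as predicted-positive when it falls inside the arm's significant
region. ROC curves use unthresholded weights (the voxel t value for the map
arm, the enclosing region's odds ratio for the ROI arm) and are vertically
averaged on a fixed FPR grid.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidArgumentError, OutOfBoundsError
from .focal import DensityStack
from .pipeline import run_focal_pipeline
from .records import StimulationRecord, behaviour_vector
from .volumes import Volume, VolumeGrid

log = logging.getLogger(__name__)

FPR_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class Parcellation:
    """Integer label volume; 0 is background."""

    label_volume: Volume
    region_ids: frozenset[int] = field(init=False)

    def __post_init__(self):
        labels = np.unique(self.label_volume.values)
        if not np.allclose(labels, np.round(labels)):
            raise InvalidArgumentError("parcellation labels must be integers")
        if labels.min() < 0:
            raise InvalidArgumentError("parcellation labels must be >= 0")
        self.region_ids = frozenset(int(v) for v in labels if v != 0)


def assign_roi(parcellation: Parcellation, record: StimulationRecord) -> int:
    """Label of the voxel enclosing the locus (nearest-voxel rule); 0 = background."""
    grid = parcellation.label_volume.grid
    idx = grid.voxel(record.world_mm)
    if not grid.contains(idx):
        raise OutOfBoundsError(
            f"locus {record.world_mm} falls outside the parcellation grid"
        )
    return int(round(parcellation.label_volume.values[idx[0], idx[1], idx[2]]))


def fisher_exact(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    Returns (odds_ratio, p_value). The odds ratio is the sample ad/bc with a
    Haldane +0.5 correction applied to every cell iff any cell is zero.
    """
    cells = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in cells):
        raise InvalidArgumentError("cells must be non-negative integers")
    a, b, c, d = (int(x) for x in cells)
    if a + b + c + d == 0:
        log.info("all-zero contingency table; OR = 1, p = 1")
        return 1.0, 1.0
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q values, clipped to 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise InvalidArgumentError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class RoiStats:
    """Per-region association statistics on a training split."""

    table: pd.DataFrame  # region, a, b, c, d, odds_ratio, p_value, q_value, significant

    def weight_of(self, region: int) -> float:
        """Odds ratio of a region; 0 for background or untested regions."""
        if region == 0:
            return 0.0
        row = self.table[self.table["region"] == region]
        return float(row["odds_ratio"].iloc[0]) if len(row) else 0.0

    def is_significant(self, region: int) -> bool:
        if region == 0:
            return False
        row = self.table[self.table["region"] == region]
        return bool(row["significant"].iloc[0]) if len(row) else False


def build_roi_map(
    records: list[StimulationRecord],
    parcellation: Parcellation,
    behaviour: str,
    q_threshold: float = 0.05,
) -> RoiStats:
    """Fisher's exact test per region with BH-FDR across regions.

    Contingency per region: a = in-region behaviour+, b = in-region
    behaviour-, c/d the out-of-region complements over training loci.
    Regions without any training locus are excluded. Significance requires
    q < ``q_threshold`` and odds ratio > 1.
    """
    if not records:
        raise InvalidArgumentError("no training records")
    region_of = np.array([assign_roi(parcellation, r) for r in records])
    y = behaviour_vector(records, behaviour).astype(int)
    n_background = int((region_of == 0).sum())
    if n_background:
        log.info("%d training loci in background (excluded from tables)", n_background)
    rows = []
    for region in sorted(parcellation.region_ids):
        inside = region_of == region
        if not inside.any():
            continue
        a = int((inside & (y == 1)).sum())
        b = int((inside & (y == 0)).sum())
        c = int((~inside & (y == 1)).sum())
        d = int((~inside & (y == 0)).sum())
        odds, p = fisher_exact(a, b, c, d)
        rows.append(
            {"region": region, "a": a, "b": b, "c": c, "d": d,
             "odds_ratio": odds, "p_value": p}
        )
    table = pd.DataFrame(
        rows, columns=["region", "a", "b", "c", "d", "odds_ratio", "p_value"]
    )
    if len(table):
        table["q_value"] = bh_fdr(table["p_value"].to_numpy())
        table["significant"] = (table["q_value"] < q_threshold) & (
            table["odds_ratio"] > 1.0
        )
    else:
        table["q_value"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
    return RoiStats(table=table)


def build_spm_map(
    records: list[StimulationRecord],
    behaviour: str,
    grid: VolumeGrid,
    stack: DensityStack | None = None,
    fwhm_mm: float = 10.0,
    mask_threshold: float = 1e-4,
    alpha: float = 0.05,
    n_perm: int = 500,
    seed: int | None = 0,
) -> tuple[Volume, Volume]:
    """Focal pipeline on a training split -> (t map, binary FWE map)."""
    y = behaviour_vector(records, behaviour)
    if y.sum() < 2 or (1 - y).sum() < 2:
        warnings.warn(
            f"behaviour {behaviour!r} has < 2 loci in one class on this split; "
            "returning an empty map",
            stacklevel=2,
        )
        zero = Volume(grid, np.zeros(grid.shape))
        return zero, zero.copy()
    arm, _ = run_focal_pipeline(
        records,
        behaviour,
        grid=grid,
        fwhm_mm=fwhm_mm,
        mask_threshold=mask_threshold,
        alpha=alpha,
        n_perm=n_perm,
        seed=seed,
        stack=stack,
    )
    return arm.t_map, arm.threshold.sig_map


def roc_auc(weights, labels) -> tuple[np.ndarray, float]:
    """ROC by threshold sweep over unique weights (ties grouped).

    Returns ((k, 2) array of (fpr, tpr) points, trapezoidal AUC). The AUC
    equals the Mann-Whitney statistic U / (n1 * n0) with 0.5 tie credit.
    """
    w = np.asarray(weights, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise InvalidArgumentError("both classes must be present")
    order = np.argsort(-w, kind="stable")
    w_sorted, y_sorted = w[order], y[order]
    tps = np.cumsum(y_sorted == 1)
    fps = np.cumsum(y_sorted == 0)
    # keep the last index of each tied group of weights
    distinct = np.r_[np.diff(w_sorted) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / n1]
    fpr = np.r_[0.0, fps[distinct] / n0]
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


def confusion_metrics(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    total = tp + fp + fn + tn
    pos, neg = tp + fn, fp + tn
    tpr = tp / pos if pos else 0.0
    tnr = tn / neg if neg else 0.0
    return {
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "accuracy": (tp + tn) / total if total else 0.0,
        "balanced_accuracy": 0.5 * (tpr + tnr),
        "precision": tp / (tp + fp) if (tp + fp) else 0.0,
        "recall_tpr": tpr,
        "fpr": fp / neg if neg else 0.0,
    }


def stratified_split(
    y: np.ndarray, test_frac: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of a label-stratified train/test split."""
    test = []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n_test = max(1, int(round(test_frac * len(idx)))) if len(idx) else 0
        test.extend(idx[:n_test])
    test = np.sort(np.asarray(test, dtype=int))
    train = np.setdiff1d(np.arange(len(y)), test)
    return train, test


def _interp_roc(points: np.ndarray) -> np.ndarray:
    """Vertical interpolation of a ROC polyline onto the common FPR grid."""
    fpr, tpr = points[:, 0], points[:, 1]
    return np.interp(FPR_GRID, fpr, tpr)


@dataclass
class ArmEval:
    metrics: list[dict[str, float]] = field(default_factory=list)
    roc_curves: list[np.ndarray] = field(default_factory=list)
    aucs: list[float] = field(default_factory=list)

    def summary(self) -> dict:
        keys = ["accuracy", "balanced_accuracy", "precision", "recall_tpr", "fpr"]
        out = {
            k: float(np.mean([m[k] for m in self.metrics])) if self.metrics else None
            for k in keys
        }
        if self.roc_curves:
            curves = np.stack(self.roc_curves)
            out["roc_fpr_grid"] = FPR_GRID.tolist()
            out["roc_tpr_mean"] = curves.mean(axis=0).tolist()
            out["roc_tpr_sd"] = curves.std(axis=0).tolist()
            out["auc_mean"] = float(np.mean(self.aucs))
            out["auc_sd"] = float(np.std(self.aucs))
        return out


@dataclass
class EvalReport:
    behaviour: str
    n_boot: int
    test_frac: float
    spm: ArmEval
    roi: ArmEval
    n_roc_skipped: int = 0

    def to_dict(self) -> dict:
        return {
            "behaviour": self.behaviour,
            "n_boot": self.n_boot,
            "test_frac": self.test_frac,
            "n_roc_skipped": self.n_roc_skipped,
            "spm": {"summary": self.spm.summary(), "per_bootstrap": self.spm.metrics,
                    "aucs": self.spm.aucs},
            "roi": {"summary": self.roi.summary(), "per_bootstrap": self.roi.metrics,
                    "aucs": self.roi.aucs},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for arm in ("spm", "roi"):
            s = getattr(self, arm).summary()
            rows.append(
                {"arm": arm, **{k: s.get(k) for k in
                 ("accuracy", "balanced_accuracy", "precision",
                  "recall_tpr", "fpr", "auc_mean", "auc_sd")}}
            )
        return pd.DataFrame(rows)


def bootstrap_evaluate(
    records: list[StimulationRecord],
    parcellation: Parcellation,
    behaviour: str,
    grid: VolumeGrid,
    n_boot: int = 100,
    test_frac: float = 0.2,
    seed: int | None = 0,
    stack: DensityStack | None = None,
    fwhm_mm: float = 10.0,
    mask_threshold: float = 1e-4,
    alpha: float = 0.05,
    n_perm: int = 500,
    q_threshold: float = 0.05,
) -> EvalReport:
    """Bootstrap both arms over stratified mapping/testing splits.

    A precomputed density ``stack`` for all records is subset per split,
    avoiding repeated convolution.
    """
    if n_boot < 1:
        raise InvalidArgumentError("n_boot must be >= 1")
    if not 0.0 < test_frac < 1.0:
        raise InvalidArgumentError("test_frac must lie in (0, 1)")
    y_all = behaviour_vector(records, behaviour).astype(int)
    if y_all.sum() == 0 or (1 - y_all).sum() == 0:
        raise InvalidArgumentError(f"behaviour {behaviour!r} is single-class")
    rng = np.random.default_rng(seed)
    if stack is None:
        from .volumes import build_gaussian_kernel
        from .focal import build_density_stack

        kernel = build_gaussian_kernel(fwhm_mm, grid.voxel_size_mm)
        stack = build_density_stack(records, grid, kernel)

    spm_eval, roi_eval = ArmEval(), ArmEval()
    n_skipped = 0
    for b in range(n_boot):
        train, test = stratified_split(y_all, test_frac, rng)
        train_records = [records[i] for i in train]
        test_records = [records[i] for i in test]
        y_test = y_all[test]
        sub_stack = DensityStack(
            grid=stack.grid,
            volumes=[stack.volumes[i] for i in train],
            records=train_records,
        )
        t_map, sig_map = build_spm_map(
            train_records, behaviour, grid, stack=sub_stack,
            fwhm_mm=fwhm_mm, mask_threshold=mask_threshold,
            alpha=alpha, n_perm=n_perm, seed=int(rng.integers(2**31)),
        )
        roi_stats = build_roi_map(train_records, parcellation, behaviour, q_threshold)

        spm_w = np.array([t_map.sample_at(r.world_mm) for r in test_records])
        spm_pred = np.array(
            [sig_map.sample_at(r.world_mm) > 0 for r in test_records], dtype=int
        )
        regions = [assign_roi(parcellation, r) for r in test_records]
        roi_w = np.array([roi_stats.weight_of(g) for g in regions])
        roi_pred = np.array(
            [roi_stats.is_significant(g) for g in regions], dtype=int
        )

        for pred, weights, ev in (
            (spm_pred, spm_w, spm_eval),
            (roi_pred, roi_w, roi_eval),
        ):
            tp = int(((pred == 1) & (y_test == 1)).sum())
            fp = int(((pred == 1) & (y_test == 0)).sum())
            fn = int(((pred == 0) & (y_test == 1)).sum())
            tn = int(((pred == 0) & (y_test == 0)).sum())
            ev.metrics.append(confusion_metrics(tp, fp, fn, tn))
            if y_test.min() == y_test.max():
                continue
            points, auc = roc_auc(weights, y_test)
            ev.roc_curves.append(_interp_roc(points))
            ev.aucs.append(auc)
        if y_test.min() == y_test.max():
            n_skipped += 1
    if n_skipped:
        log.info("%d bootstrap replicate(s) lacked both classes; ROC skipped", n_skipped)
    return EvalReport(
        behaviour=behaviour,
        n_boot=n_boot,
        test_frac=test_frac,
        spm=spm_eval,
        roi=roi_eval,
        n_roc_skipped=n_skipped,
    )


def plot_roc(report: EvalReport, path) -> None:
    """Averaged ROC (+- 1 SD band) per arm; requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for arm, colour in (("spm", "tab:red"), ("roi", "tab:blue")):
        s = getattr(report, arm).summary()
        if "roc_tpr_mean" not in s:
            continue
        mean = np.asarray(s["roc_tpr_mean"])
        sd = np.asarray(s["roc_tpr_sd"])
        ax.plot(FPR_GRID, mean, color=colour,
                label=f"{arm.upper()} (AUC {s['auc_mean']:.2f})")
        ax.fill_between(FPR_GRID, mean - sd, mean + sd, color=colour, alpha=0.2)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title(report.behaviour)
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
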