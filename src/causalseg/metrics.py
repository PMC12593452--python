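"""Evaluation machinery: overlap, boundary and volume metrics, probability
calibration, uncertainty-error correlation, perturbation robustness and
causal-graph recovery scoring.

Region conventions follow the standard nested tumor reading: ET is the
enhancing-tumor class, TC = NCR ∪ ET, WT = NCR ∪ ED ∪ ET. HD95 is the
maximum of the two directed 95th-percentile surface distances in mm (the
common BraTS convention); boundary F1 matches surface voxels within a
2-voxel tolerance. Empty-region conventions: both masks empty → Dice 1 and
HD95 0; exactly one empty → Dice 0 and HD95 equal to the grid's diagonal
extent in mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats

from .io_prep import ED, ET, NCR, SegmentationMask

__all__ = ["RegionReport", "CalibrationReport", "REGIONS",
           "dice_coefficient", "hd95", "boundary_f1", "volume_error_pct",
           "overlap_metrics", "calibration", "uncertainty_error_correlation",
           "robustness_suite", "graph_recovery"]

#: Region name -> set of class labels.
REGIONS: dict[str, tuple[int, ...]] = {
    "ET": (ET,),
    "TC": (NCR, ET),
    "WT": (NCR, ED, ET),
}

BF1_TOLERANCE_VOX = 2.0


@dataclass
class RegionReport:
    """Per-region overlap/boundary/volume metrics."""

    regions: dict  # name -> {dice, hd95_mm, boundary_f1, volume_error_pct}

    def mean(self, key: str) -> float:
        return float(np.mean([r[key] for r in self.regions.values()]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.regions).T


@dataclass
class CalibrationReport:
    ece_pct: float
    mce_pct: float
    brier: float
    nll: float
    n_bins: int


# ---------------------------------------------------------------------------
# Overlap / boundary metrics
# ---------------------------------------------------------------------------

def dice_coefficient(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice = 2|P∩G| / (|P| + |G|); both-empty convention 1.0."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    denom = int(pred.sum()) + int(truth.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((pred & truth).sum()) / denom


def _surface(mask: np.ndarray) -> np.ndarray:
    """Boundary voxels: mask minus its erosion (array border counts)."""
    if not mask.any():
        return mask
    return mask & ~ndi.binary_erosion(mask)


def _diagonal_mm(shape, spacing) -> float:
    return float(np.linalg.norm(np.asarray(shape) * np.asarray(spacing)))


def hd95(pred: np.ndarray, truth: np.ndarray,
         spacing=(1.0, 1.0, 1.0)) -> float:
    """Max of the two directed 95th-percentile surface distances (mm)."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if spacing is None:
        raise ValueError("voxel spacing is required for mm distances")
    if not pred.any() and not truth.any():
        return 0.0
    if not pred.any() or not truth.any():
        return _diagonal_mm(pred.shape, spacing)
    sp = _surface(pred)
    st = _surface(truth)
    dt_t = ndi.distance_transform_edt(~st, sampling=spacing)
    dt_p = ndi.distance_transform_edt(~sp, sampling=spacing)
    d_pt = np.percentile(dt_t[sp], 95)
    d_tp = np.percentile(dt_p[st], 95)
    return float(max(d_pt, d_tp))


def boundary_f1(pred: np.ndarray, truth: np.ndarray,
                tolerance_vox: float = BF1_TOLERANCE_VOX) -> float:
    """F1 of boundary voxels matched within a voxel tolerance."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if not pred.any() and not truth.any():
        return 1.0
    if not pred.any() or not truth.any():
        return 0.0
    sp = _surface(pred)
    st = _surface(truth)
    dt_t = ndi.distance_transform_edt(~st)
    dt_p = ndi.distance_transform_edt(~sp)
    precision = float((dt_t[sp] <= tolerance_vox).mean())
    recall = float((dt_p[st] <= tolerance_vox).mean())
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def volume_error_pct(pred: np.ndarray, truth: np.ndarray) -> float:
    """100·|V_P − V_G| / V_G (0 when both empty)."""
    vp = int(np.asarray(pred, dtype=bool).sum())
    vg = int(np.asarray(truth, dtype=bool).sum())
    if vg == 0:
        return 0.0 if vp == 0 else float("inf")
    return 100.0 * abs(vp - vg) / vg


def _region_mask(labels: np.ndarray, classes) -> np.ndarray:
    return np.isin(labels, classes)


def overlap_metrics(pred_mask, true_mask,
                    spacing=(1.0, 1.0, 1.0)) -> RegionReport:
    """Dice / HD95 / boundary-F1 / volume error for ET, TC and WT."""
    pred = pred_mask.labels if isinstance(pred_mask, SegmentationMask) \
        else np.asarray(pred_mask)
    true = true_mask.labels if isinstance(true_mask, SegmentationMask) \
        else np.asarray(true_mask)
    if pred.shape != true.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {true.shape}")
    regions = {}
    for name, classes in REGIONS.items():
        p = _region_mask(pred, classes)
        g = _region_mask(true, classes)
        regions[name] = {
            "dice": dice_coefficient(p, g),
            "hd95_mm": hd95(p, g, spacing),
            "boundary_f1": boundary_f1(p, g),
            "volume_error_pct": volume_error_pct(p, g),
        }
    return RegionReport(regions=regions)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def calibration(probs: np.ndarray, true_labels: np.ndarray,
                n_bins: int = 15,
                mask: np.ndarray | None = None) -> CalibrationReport:
    """ECE/MCE over equal-width confidence bins (as %), Brier and NLL.

    ``probs`` is (C, ...) or (N, C, ...); confidence is the max class
    probability per voxel and accuracy the argmax correctness. Computed
    over ``mask`` voxels when given (e.g. the brain mask).
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(true_labels)
    if probs.ndim == labels.ndim:       # (C, ...) single case
        probs = probs[None]
        labels = labels[None]
        if mask is not None:
            mask = mask[None]
    c_axis = 1
    n_classes = probs.shape[c_axis]
    conf = probs.max(axis=c_axis)
    pred = probs.argmax(axis=c_axis)
    correct = pred == labels
    if mask is not None:
        sel = np.asarray(mask, dtype=bool)
        conf, correct = conf[sel], correct[sel]
        p_sel = np.moveaxis(probs, c_axis, -1)[sel]
        lab_sel = labels[sel]
    else:
        conf, correct = conf.ravel(), correct.ravel()
        p_sel = np.moveaxis(probs, c_axis, -1).reshape(-1, n_classes)
        lab_sel = labels.ravel()

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(conf, edges[1:-1]), 0, n_bins - 1)
    n = conf.size
    ece = 0.0
    mce = 0.0
    for b in range(n_bins):
        sel_b = idx == b
        nb = int(sel_b.sum())
        if nb == 0:
            continue
        gap = abs(correct[sel_b].mean() - conf[sel_b].mean())
        ece += nb / n * gap
        mce = max(mce, gap)
    onehot = np.eye(n_classes)[lab_sel]
    brier = float(((p_sel - onehot) ** 2).sum(axis=1).mean())
    nll = float(-np.log(np.clip(p_sel[np.arange(n), lab_sel],
                                1e-12, None)).mean())
    return CalibrationReport(ece_pct=100.0 * ece, mce_pct=100.0 * mce,
                             brier=brier, nll=nll, n_bins=n_bins)


def uncertainty_error_correlation(case_probs: list, case_labels: list,
                                  ) -> dict:
    """Rank correlation between predictive entropy and segmentation error.

    Case level: Spearman rho between per-case mean entropy and per-case
    error rate (requires ≥ 2 cases). Voxel level: Spearman rho between
    pooled voxel entropies and misclassification indicators. Degenerate
    (constant) inputs are reported as rho 0 with a flag.
    """
    if len(case_probs) != len(case_labels):
        raise ValueError("probs/labels case counts differ")
    if len(case_probs) < 2:
        raise ValueError("case-level correlation requires at least 2 cases")
    mean_ent, err_rate = [], []
    all_ent, all_err = [], []
    for probs, labels in zip(case_probs, case_labels):
        probs = np.asarray(probs, dtype=np.float64)
        labels = np.asarray(labels)
        p = np.clip(probs, 1e-12, 1.0)
        ent = -(p * np.log(p)).sum(axis=0)
        err = probs.argmax(axis=0) != labels
        mean_ent.append(float(ent.mean()))
        err_rate.append(float(err.mean()))
        all_ent.append(ent.ravel())
        all_err.append(err.ravel())

    def _spearman(a, b):
        a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            return 0.0, True
        rho = stats.spearmanr(a, b).statistic
        return (0.0, True) if not np.isfinite(rho) else (float(rho), False)

    rho_case, deg_case = _spearman(mean_ent, err_rate)
    rho_vox, deg_vox = _spearman(np.concatenate(all_ent),
                                 np.concatenate(all_err))
    return {"rho_case": rho_case, "rho_voxel": rho_vox,
            "degenerate_case": deg_case, "degenerate_voxel": deg_vox}


# ---------------------------------------------------------------------------
# Robustness harness
# ---------------------------------------------------------------------------

def default_perturbation_grid() -> list[tuple[str, object]]:
    """The stress grid: each single-modality ablation plus Rician noise at
    SNR 15 and 10, ±15% intensity bias and 1.5-voxel motion blur."""
    from .io_prep import MODALITIES
    grid: list[tuple[str, object]] = [("baseline", None)]
    grid += [("ablate_modality", m) for m in MODALITIES]
    grid += [("rician_snr", 15.0), ("rician_snr", 10.0),
             ("intensity_bias", 0.15), ("motion_blur", 1.5)]
    return grid


def robustness_suite(model, cases, grid=None, seed: int = 0,
                     patch_size: int | None = None) -> pd.DataFrame:
    """Evaluate region Dice under each perturbation of the grid.

    ``cases`` are raw (unnormalised) PhantomCase-like objects; each row
    reports mean per-region Dice over the cohort plus the delta against
    the baseline row.
    """
    from .io_prep import preprocess
    from .phantom import perturb

    grid = grid if grid is not None else default_perturbation_grid()
    rng = np.random.default_rng(seed)
    rows = []
    for kind, level in grid:
        dices = {name: [] for name in REGIONS}
        pseed = int(rng.integers(2 ** 31 - 1))
        for ci, case in enumerate(cases):
            vol = case.volume
            if kind != "baseline":
                vol = perturb(vol, kind, level, seed=pseed + ci)
            shape = ((patch_size,) * 3 if patch_size
                     else vol.grid_shape)
            # epsilon guard: an ablated channel is constant zero
            vol_p, mask_p = preprocess(vol, case.mask, target_shape=shape,
                                       variance_epsilon=1.0)
            pred = model.predict(vol_p.data[None]).argmax(axis=1)[0]
            for name, classes in REGIONS.items():
                dices[name].append(dice_coefficient(
                    _region_mask(pred, classes),
                    _region_mask(mask_p.labels, classes)))
        row = {"perturbation": kind,
               "level": level if level is not None else ""}
        for name in REGIONS:
            row[f"dice_{name.lower()}"] = float(np.mean(dices[name]))
        row["dice_mean"] = float(np.mean(
            [row[f"dice_{n.lower()}"] for n in REGIONS]))
        rows.append(row)
    frame = pd.DataFrame(rows)
    base = frame.loc[frame["perturbation"] == "baseline", "dice_mean"]
    if len(base):
        frame["delta_vs_baseline"] = frame["dice_mean"] - float(base.iloc[0])
    return frame


# ---------------------------------------------------------------------------
# Graph recovery
# ---------------------------------------------------------------------------

def graph_recovery(edge_scores, truth_adjacency) -> tuple[float, float]:
    """AUROC (tie-averaged ranks) and precision-at-k of edge scores against
    the phantom's ground-truth adjacency; k = number of true edges.

    ``edge_scores`` is either an array shaped like the adjacency or a
    mapping from (modality, class) to score in the adjacency's order.
    """
    truth = np.asarray(truth_adjacency).ravel().astype(int)
    if truth.min() < 0 or truth.max() > 1:
        raise ValueError("truth adjacency must be binary")
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("degenerate truth adjacency (all 0 or all 1)")
    if isinstance(edge_scores, dict):
        from .io_prep import MODALITIES
        from .phantom import TUMOR_CLASSES
        scores = np.asarray([[edge_scores[(m, c)] for c in TUMOR_CLASSES]
                             for m in MODALITIES]).ravel()
    else:
        scores = np.asarray(edge_scores, dtype=float).ravel()
    if scores.shape != truth.shape:
        raise ValueError("scores and truth adjacency differ in size")
    ranks = stats.rankdata(scores)            # ties averaged
    auroc = (ranks[truth == 1].sum() - n_pos * (n_pos + 1) / 2) \
        / (n_pos * n_neg)
    top_k = np.argsort(-scores, kind="stable")[:n_pos]
    precision = float(truth[top_k].mean())
    return float(auroc), precision
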