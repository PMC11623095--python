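"""Segmentation evaluation: dice similarity coefficient (DSC, %) and
Hausdorff distance (HD) between label masks.

DSC is the overlap ``2|A∩B| / (|A| + |B|)`` per class, reported in percent
and averaged over foreground classes.  HD is the maximum boundary-to-
boundary distance between the two regions (lower is better); HD95 is its
95th-percentile variant, less sensitive to single outlier pixels.
Distances are Euclidean in pixel units unless a (row, col) spacing in mm is
given.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

__all__ = ["dsc_metric", "hd_metric", "boundary_points", "evaluate_case", "write_report"]


def _check_shapes(pred, gt):
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    return pred, gt


def dsc_metric(pred, gt, K: int) -> dict:
    """Per-class and mean-foreground DSC in percent.

    A class empty in both masks scores 100; empty in exactly one scores 0.
    The mean is over foreground classes (labels 1..K-1), matching how
    multi-organ benchmarks report accuracy.
    """
    pred, gt = _check_shapes(pred, gt)
    per_class = {}
    for k in range(K):
        a = pred == k
        b = gt == k
        na, nb = int(a.sum()), int(b.sum())
        if na == 0 and nb == 0:
            per_class[k] = 100.0
        elif na == 0 or nb == 0:
            per_class[k] = 0.0
        else:
            per_class[k] = 200.0 * float(np.logical_and(a, b).sum()) / (na + nb)
    fg = [per_class[k] for k in range(1, K)]
    return {
        "per_class": per_class,
        "mean_foreground": float(np.mean(fg)) if fg else float("nan"),
    }


def boundary_points(mask: np.ndarray) -> np.ndarray:
    """Coordinates (row, col) of boundary pixels: mask pixels with at least
    one 4-neighbour outside the mask (image border counts as outside)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.empty((0, 2), dtype=int)
    interior = ndimage.binary_erosion(mask, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool
    ), border_value=0)
    return np.argwhere(mask & ~interior)


def hd_metric(pred, gt, spacing=(1.0, 1.0), percentile: float | None = None) -> float:
    """(Symmetric) Hausdorff distance between two binary masks.

    ``percentile=95`` gives HD95.  If either mask is empty the distance is
    undefined; NaN is returned with a warning so callers can exclude the
    case from means.
    """
    pred, gt = _check_shapes(pred, gt)
    pa = boundary_points(pred).astype(float) * np.asarray(spacing, dtype=float)
    pb = boundary_points(gt).astype(float) * np.asarray(spacing, dtype=float)
    if len(pa) == 0 or len(pb) == 0:
        warnings.warn(
            "Hausdorff distance undefined for an empty mask; returning NaN",
            stacklevel=2,
        )
        return float("nan")
    d = cdist(pa, pb)
    fwd = d.min(axis=1)  # pred boundary -> nearest gt boundary
    bwd = d.min(axis=0)
    if percentile is None:
        return float(max(fwd.max(), bwd.max()))
    return float(max(np.percentile(fwd, percentile), np.percentile(bwd, percentile)))


def evaluate_case(pred, gt, K: int, spacing=(1.0, 1.0)) -> dict:
    """DSC (%) and HD / HD95 per foreground class plus foreground means.

    Classes with an empty boundary on either side contribute NaN to HD and
    are excluded from the HD means.
    """
    pred, gt = _check_shapes(pred, gt)
    dsc = dsc_metric(pred, gt, K)
    hd, hd95 = {}, {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in range(1, K):
            hd[k] = hd_metric(pred == k, gt == k, spacing)
            hd95[k] = hd_metric(pred == k, gt == k, spacing, percentile=95.0)
    hds = [v for v in hd.values() if np.isfinite(v)]
    hd95s = [v for v in hd95.values() if np.isfinite(v)]
    return {
        "dsc_per_class": dsc["per_class"],
        "dsc_mean_foreground": dsc["mean_foreground"],
        "hd_per_class": hd,
        "hd_mean_foreground": float(np.mean(hds)) if hds else float("nan"),
        "hd95_per_class": hd95,
        "hd95_mean_foreground": float(np.mean(hd95s)) if hd95s else float("nan"),
    }


def write_report(path, case_results: dict[str, dict], K: int) -> None:
    """Write per-case and mean rows (DSC %, HD, HD95) to a CSV report."""
    path = Path(path)
    fields = ["case"]
    for k in range(1, K):
        fields += [f"dsc_{k}", f"hd_{k}", f"hd95_{k}"]
    fields += ["dsc_mean", "hd_mean", "hd95_mean"]
    rows = []
    for case, r in case_results.items():
        row = {"case": case}
        for k in range(1, K):
            row[f"dsc_{k}"] = f"{r['dsc_per_class'][k]:.4f}"
            row[f"hd_{k}"] = f"{r['hd_per_class'][k]:.4f}"
            row[f"hd95_{k}"] = f"{r['hd95_per_class'][k]:.4f}"
        row["dsc_mean"] = f"{r['dsc_mean_foreground']:.4f}"
        row["hd_mean"] = f"{r['hd_mean_foreground']:.4f}"
        row["hd95_mean"] = f"{r['hd95_mean_foreground']:.4f}"
        rows.append(row)
    mean_row = {"case": "mean"}
    for key in fields[1:]:
        vals = [float(r[key]) for r in rows]
        vals = [v for v in vals if np.isfinite(v)]
        mean_row[key] = f"{np.mean(vals):.4f}" if vals else "nan"
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        writer.writerows(rows)
        writer.writerow(mean_row)
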