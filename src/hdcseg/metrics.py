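"""Segmentation evaluation: Dice overlap and (95th-percentile) Hausdorff distance.

Dice = 2·TP / (FN + FP + 2·TP) measures volume overlap. The Hausdorff
distance is computed between mask boundaries (a voxel is boundary if any
of its 6 face-neighbours — or the outside of the array — lies outside the
mask), with Euclidean distances in voxel units or, when a spacing is
given, in millimetres. ``percentile=100`` gives the classical symmetric
Hausdorff distance max{sup-inf, sup-inf}; the default 95 takes the 95th
percentile of the pooled directed boundary distances, the robust variant
standard in BraTS reporting.

Empty-mask policy (not defined by the metric): Dice of two empty masks is
1 and of one empty mask is 0; HD of two empty masks is 0 (flagged), and of
one empty mask the worst-case volume diagonal (flagged).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import LabelVolume, labels_to_regions

__all__ = ["ConfusionCounts", "dice", "dice_from_counts", "boundary_voxels",
           "hd95", "EvalReport", "evaluate_cases", "REGIONS"]

REGIONS = ("et", "wt", "tc")

_STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int


def dice_from_counts(counts: ConfusionCounts) -> float:
    """Eq-style Dice 2TP/(FN+FP+2TP); two empty masks give 1 by convention."""
    den = counts.fn + counts.fp + 2 * counts.tp
    if den == 0:
        return 1.0
    return 2.0 * counts.tp / den


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    return dice_from_counts(ConfusionCounts(tp, fp, fn))


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Voxels of ``mask`` with at least one 6-neighbour outside the mask."""
    mask = np.asarray(mask, dtype=bool)
    interior = ndimage.binary_erosion(mask, structure=_STRUCT6, border_value=0)
    return mask & ~interior


def _diagonal(shape, spacing) -> float:
    ext = [s * sp for s, sp in zip(shape, spacing)]
    return float(np.sqrt(np.sum(np.square(ext))))


def hd95(pred: np.ndarray, truth: np.ndarray, percentile: float = 95,
         spacing: tuple[float, float, float] | None = None
         ) -> tuple[float, str]:
    """Robust Hausdorff distance between mask boundaries.

    Returns ``(value, flag)`` where flag is "" normally, "empty" when one
    mask is empty (policy value: volume diagonal) and "both_empty" when
    both are (value 0).
    """
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    spacing = (1.0, 1.0, 1.0) if spacing is None else tuple(spacing)
    if not pred.any() and not truth.any():
        return 0.0, "both_empty"
    if not pred.any() or not truth.any():
        return _diagonal(pred.shape, spacing), "empty"
    bp = boundary_voxels(pred)
    bt = boundary_voxels(truth)
    # distance-to-nearest-boundary fields give the directed inf terms
    dt_to_t = ndimage.distance_transform_edt(~bt, sampling=spacing)
    dt_to_p = ndimage.distance_transform_edt(~bp, sampling=spacing)
    d_pt = dt_to_t[bp]   # inf over ∂T, for each p in ∂P
    d_tp = dt_to_p[bt]
    pooled = np.concatenate([d_pt, d_tp])
    if percentile >= 100:
        return float(pooled.max()), ""
    return float(np.percentile(pooled, percentile)), ""


@dataclass
class EvalReport:
    """Per-case, per-region Dice/HD95 table plus an aggregate mean row."""

    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @property
    def means(self) -> pd.Series:
        return self.table.iloc[-1]


def evaluate_cases(preds, truths, case_ids=None, percentile: float = 95,
                   spacing=None) -> EvalReport:
    """Region-wise evaluation of predicted vs reference label volumes.

    ``preds``/``truths`` are sequences of label arrays or LabelVolumes with
    values in {0, 1, 2, 4}; regions are derived with
    :func:`hdcseg.io.labels_to_regions`. The returned table has one row
    per case and a final "mean" row (HD means ignore flagged entries).
    """
    if len(preds) != len(truths):
        raise ValueError("preds and truths differ in length")
    if case_ids is None:
        case_ids = [f"case_{i:03d}" for i in range(len(preds))]
    rows = []
    for cid, p, t in zip(case_ids, preds, truths):
        p = p.labels if isinstance(p, LabelVolume) else np.asarray(p)
        t = t.labels if isinstance(t, LabelVolume) else np.asarray(t)
        pr = labels_to_regions(p)
        tr = labels_to_regions(t)
        row = {"case_id": cid}
        for region in REGIONS:
            pm, tm = getattr(pr, region), getattr(tr, region)
            row[f"dice_{region}"] = dice(pm, tm)
            hd, flag = hd95(pm, tm, percentile=percentile, spacing=spacing)
            row[f"hd95_{region}"] = hd
            row[f"hd95_{region}_flag"] = flag
        rows.append(row)
    df = pd.DataFrame(rows)
    mean_row = {"case_id": "mean"}
    for region in REGIONS:
        mean_row[f"dice_{region}"] = df[f"dice_{region}"].mean()
        ok = df[f"hd95_{region}_flag"] == ""
        mean_row[f"hd95_{region}"] = df.loc[ok, f"hd95_{region}"].mean() if ok.any() else np.nan
        mean_row[f"hd95_{region}_flag"] = ""
    df = pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
    return EvalReport(df)
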