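"""Segmentation metrics and feature-space analyses.

* DSC  = 2|P ∩ G| / (|P| + |G|) per zone (both-empty convention: 1).
* mIoU = mean over foreground classes of |P ∩ G| / |P ∪ G|.
* MSD  = 0.5 [d(S_P, S_G) + d(S_G, S_P)] with d the mean over one surface
  of the Euclidean nearest-neighbour distance to the other; surfaces are
  face-connected boundary voxels; distances are in physical units via the
  voxel spacing (default: voxel units).  If either surface is empty the
  value is NaN (the "failed to segment" flag).
* Retention after task k = mean task-1 test DSC under the task-k weights
  divided by the same mean under the task-1 weights (1 at k = 1 by
  construction).
* Silhouette s(i) = (b(i) - a(i)) / max{a(i), b(i)} with a(i) the mean
  intra-cluster and b(i) the nearest-other-cluster mean distance;
  singleton clusters score 0; the reported score is the sample mean.

Feature embeddings for the silhouette analysis are the model's fused
feature maps averaged over each zone's pixels — one vector per
(slice, zone), labelled TZ or PZ.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "dsc", "miou", "msd", "worst_case", "MetricRecord", "evaluate_cases",
    "aggregate_records", "retention_curve", "silhouette",
    "extract_embeddings",
]


def _binarize(arr: np.ndarray, zone: int) -> np.ndarray:
    return np.asarray(arr) == zone


def dsc(pred: np.ndarray, truth: np.ndarray, zone: int) -> float:
    """Dice similarity coefficient of one zone."""
    p, g = _binarize(pred, zone), _binarize(truth, zone)
    denom = int(p.sum()) + int(g.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & g).sum()) / denom


def miou(pred: np.ndarray, truth: np.ndarray,
         zones: tuple[int, ...] = (1, 2)) -> float:
    """Mean intersection-over-union across foreground classes."""
    vals = []
    for z in zones:
        p, g = _binarize(pred, z), _binarize(truth, z)
        union = int((p | g).sum())
        vals.append(1.0 if union == 0 else int((p & g).sum()) / union)
    return float(np.mean(vals))


def _surface(mask: np.ndarray) -> np.ndarray:
    """Boundary voxels: zone voxels with at least one face-neighbour
    outside the zone (6-connectivity in 3-D, 4 in 2-D)."""
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    eroded = ndimage.binary_erosion(mask, structure=structure,
                                    border_value=0)
    return np.argwhere(mask & ~eroded)


def msd(pred: np.ndarray, truth: np.ndarray, zone: int,
        spacing=None) -> float:
    """Symmetric mean surface distance of one zone; NaN when either
    surface is empty."""
    p, g = _binarize(pred, zone), _binarize(truth, zone)
    sp, sg = _surface(p), _surface(g)
    if len(sp) == 0 or len(sg) == 0:
        return float("nan")
    if spacing is not None:
        scale = np.asarray(spacing, dtype=float)
        sp = sp * scale
        sg = sg * scale
    d_pg = cKDTree(sg).query(sp)[0].mean()
    d_gp = cKDTree(sp).query(sg)[0].mean()
    return float(0.5 * (d_pg + d_gp))


def worst_case(values) -> float:
    values = [v for v in values if not np.isnan(v)]
    if not values:
        raise ValueError("worst_case of an empty record set")
    return float(min(values))


@dataclasses.dataclass
class MetricRecord:
    case_id: int
    zone: int
    dsc: float
    msd: float
    iou: float


def evaluate_cases(preds, truths, spacing=None,
                   zones: tuple[int, ...] = (1, 2)) -> list[MetricRecord]:
    """Per-case, per-zone metrics over paired (pred, truth) label arrays."""
    records = []
    for cid, (p, t) in enumerate(zip(preds, truths)):
        for z in zones:
            pb, tb = _binarize(p, z), _binarize(t, z)
            union = int((pb | tb).sum())
            iou = 1.0 if union == 0 else int((pb & tb).sum()) / union
            records.append(MetricRecord(case_id=cid, zone=z,
                                        dsc=dsc(p, t, z),
                                        msd=msd(p, t, z, spacing),
                                        iou=iou))
    return records


def aggregate_records(records: list[MetricRecord]) -> pd.DataFrame:
    """Table-style aggregate: per zone, mean +/- SD DSC and MSD, worst-case
    DSC, mean IoU."""
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    rows = []
    for zone, grp in df.groupby("zone"):
        rows.append({
            "zone": {1: "TZ", 2: "PZ"}.get(zone, zone),
            "dsc_mean": grp.dsc.mean(), "dsc_sd": grp.dsc.std(ddof=1),
            "dsc_worst": grp.dsc.min(),
            "msd_mean": grp.msd.mean(), "msd_sd": grp.msd.std(ddof=1),
            "iou_mean": grp.iou.mean(), "n_cases": len(grp),
        })
    return pd.DataFrame(rows)


def retention_curve(eval_fn, checkpoints: list,
                    task1_test) -> list[float]:
    """Retention after task k = eval_fn(checkpoint_k, task1_test) /
    eval_fn(checkpoint_1, task1_test); eval_fn returns a mean test DSC."""
    if not checkpoints:
        raise ValueError("need at least the task-1 checkpoint")
    base = eval_fn(checkpoints[0], task1_test)
    if base <= 0:
        raise ValueError("task-1 baseline performance is zero")
    return [eval_fn(ck, task1_test) / base for ck in checkpoints]


# -- silhouette ------------------------------------------------------------

def silhouette(embeddings: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette score with Euclidean distances, computed directly
    from its definition; singleton clusters contribute 0."""
    X = np.asarray(embeddings, dtype=float)
    y = np.asarray(labels)
    n = len(X)
    if n != len(y):
        raise ValueError("embeddings and labels length mismatch")
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("silhouette needs at least two clusters")
    scores = np.zeros(n)
    for i in range(n):
        same = (y == y[i])
        n_same = same.sum()
        if n_same == 1:
            scores[i] = 0.0
            continue
        a = d[i, same].sum() / (n_same - 1)       # exclude self
        b = min(d[i, y == c].mean() for c in classes if c != y[i])
        m = max(a, b)
        scores[i] = 0.0 if m == 0 else (b - a) / m
    return float(scores.mean())


def extract_embeddings(model, pairs) -> tuple[np.ndarray, np.ndarray]:
    """Per (slice, zone) fused-feature mean vectors with TZ/PZ labels;
    slices missing a zone emit no vector for it."""
    vecs, labs = [], []
    for p in pairs:
        feats = model.fused_features(p.image[None])[0]   # (C, H, W)
        for zone in (1, 2):
            mask = p.mask == zone
            if not mask.any():
                continue
            vecs.append(feats[:, mask].mean(axis=1))
            labs.append(zone)
    return np.asarray(vecs), np.asarray(labs)
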