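"""From block scores to detected cells and TPR/PPV/FNR/FDR.

The trained network scores every block position of a field of view,
producing a probability image on the block-center grid.  A probability
cutoff and a minimum region size — calibrated jointly on training FOVs by
maximizing mean pixel-wise Dice overlap with the ground-truth masks — turn
scores into a predicted mask.  Detection is counted per cell: connected
components of the ground truth (8-connectivity) that share at least one
pixel with any predicted component are true positives; predicted components
touching no ground-truth cell are false positives.  True negatives are
undefined in this workflow (there is no exhaustive labeling of
non-microglia structures), so only TPR, PPV, FNR and FDR are reported.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import skimage.measure

from .ann_core import NetworkSpec, predict
from .labelprep import (block_centers, drop_small_objects,
                        extract_dbm_vectors, extract_fbm_blocks)
from .tcspc_io import DecayCube, FitParamMaps, RunConfig

__all__ = [
    "ProbabilityImage",
    "DetectionThresholds",
    "DetectionResult",
    "predict_image",
    "block_grid_view",
    "cell_labels_view",
    "calibrate_thresholds",
    "binarize_and_clean",
    "match_detections",
    "compute_metrics",
    "dice",
]

DEFAULT_CUTOFFS = tuple(np.round(np.arange(0.05, 0.951, 0.05), 2))
DEFAULT_MIN_SIZES = (5, 10, 25, 50, 100)


@dataclasses.dataclass
class ProbabilityImage:
    """Block-grid microglia scores mapped back to image coordinates."""

    values: np.ndarray        # (nby, nbx), NaN where the block was invalid
    valid: np.ndarray
    block_size: int
    block_stride: int
    image_shape: tuple[int, int]

    def __post_init__(self):
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def center_offset(self) -> int:
        return self.block_size // 2


@dataclasses.dataclass
class DetectionThresholds:
    cutoff: float
    min_region_px: int

    def __post_init__(self):
        if not (0 < self.cutoff < 1):
            raise ValueError("cutoff must lie in (0, 1)")
        if self.min_region_px < 1:
            raise ValueError("min_region_px must be >= 1")


@dataclasses.dataclass
class DetectionResult:
    """Per-FOV detection counts and the derived rates.

    ``tpr``/``ppv``/``fnr``/``fdr`` are per-FOV arrays (NaN where a
    denominator is zero); pooled_* aggregates the counts over FOVs first.
    """

    tp: np.ndarray
    fn: np.ndarray
    fp: np.ndarray
    tpr: np.ndarray
    ppv: np.ndarray
    fnr: np.ndarray
    fdr: np.ndarray
    pooled_tpr: float
    pooled_ppv: float
    pooled_fnr: float
    pooled_fdr: float

    @property
    def n_fovs(self) -> int:
        return len(self.tp)

    def summary(self) -> dict[str, tuple[float, float]]:
        """Across-FOV mean ± sd of each rate (NaN-aware)."""
        out = {}
        for name in ("tpr", "ppv", "fnr", "fdr"):
            vals = getattr(self, name)
            out[name] = (float(np.nanmean(vals)), float(np.nanstd(vals)))
        return out


def predict_image(net: NetworkSpec, data: FitParamMaps | DecayCube,
                  config: RunConfig, include_chi2: bool = True) -> ProbabilityImage:
    """Score every block of a FOV with the same feature pipeline as training.

    FBM networks (7 inputs) require fitted parameter maps; DBM networks
    (n_bins inputs) require a decay cube.  Blocks dropped by the feature
    filters are NaN in the output.
    """
    if net.norm_stats is None:
        raise ValueError("network carries no normalization statistics; "
                         "train or load a model first")
    dummy_mask = np.zeros(data.shape, dtype=bool)
    if isinstance(data, FitParamMaps):
        table = extract_fbm_blocks(data, dummy_mask, config, include_chi2=include_chi2)
    elif isinstance(data, DecayCube):
        table = extract_dbm_vectors(data, dummy_mask, config)
    else:
        raise TypeError(f"cannot score a {type(data).__name__}")
    if table.n_features != net.n_inputs:
        raise ValueError(
            f"model expects {net.n_inputs} inputs but the {type(data).__name__} "
            f"pipeline produced {table.n_features}; model/input kind mismatch")
    rows, cols = block_centers(data.shape, config)
    nby, nbx = len(rows), len(cols)
    values = np.full((nby, nbx), np.nan)
    if len(table):
        scores = predict(net, table.features)
        iy = (table.y - config.block_size // 2) // config.block_stride
        ix = (table.x - config.block_size // 2) // config.block_stride
        values[iy, ix] = scores
    return ProbabilityImage(values=values, valid=np.isfinite(values),
                            block_size=config.block_size,
                            block_stride=config.block_stride,
                            image_shape=data.shape)


def block_grid_view(mask: np.ndarray, config: RunConfig) -> np.ndarray:
    """Sample a full-resolution mask at the block-center grid.

    This is the ground truth against which block-grid predictions are
    calibrated and matched: pixel (i, j) of the view is the mask value at
    the center of block (i, j), exactly the labeling rule used for
    training instances.
    """
    mask = np.asarray(mask)
    rows, cols = block_centers(mask.shape, config)
    return mask[np.ix_(rows, cols)]


def binarize_and_clean(prob_image: ProbabilityImage | np.ndarray,
                       thresholds: DetectionThresholds) -> np.ndarray:
    """Threshold at the cutoff, then drop small 8-connected components."""
    values = prob_image.values if isinstance(prob_image, ProbabilityImage) else prob_image
    with np.errstate(invalid="ignore"):
        mask = np.asarray(values) >= thresholds.cutoff  # NaN compares False
    return drop_small_objects(mask, thresholds.min_region_px)


def dice(pred: np.ndarray, gt: np.ndarray) -> float:
    """Pixel-wise Dice overlap; 1.0 when both masks are empty."""
    pred = np.asarray(pred, dtype=bool)
    gt = np.asarray(gt, dtype=bool)
    total = pred.sum() + gt.sum()
    if total == 0:
        return 1.0
    return 2.0 * np.logical_and(pred, gt).sum() / total


def _iou(pred, gt):
    union = np.logical_or(pred, gt).sum()
    if union == 0:
        return 1.0
    return np.logical_and(pred, gt).sum() / union


def calibrate_thresholds(prob_images: list[ProbabilityImage | np.ndarray],
                         gt_masks: list[np.ndarray],
                         cutoffs=DEFAULT_CUTOFFS,
                         min_sizes=DEFAULT_MIN_SIZES,
                         overlap: str = "dice") -> DetectionThresholds:
    """Grid-search (cutoff, min region size) maximizing mean mask overlap.

    Overlap is pixel-wise Dice by default (``overlap="iou"`` optional),
    averaged over the training FOVs.  Ties break toward the higher cutoff,
    then the larger minimum size.  Ground-truth masks must be on the same
    grid as the probability images.
    """
    if len(prob_images) != len(gt_masks) or not prob_images:
        raise ValueError("need equally many probability images and masks")
    gt_masks = [np.asarray(m, dtype=bool) for m in gt_masks]
    if not any(m.any() for m in gt_masks):
        raise ValueError("all ground-truth masks are empty; cannot calibrate")
    score_fn = {"dice": dice, "iou": _iou}[overlap]
    best = (-1.0, None)
    for cutoff in cutoffs:
        for min_size in min_sizes:
            thr = DetectionThresholds(cutoff=float(cutoff), min_region_px=int(min_size))
            score = float(np.mean([
                score_fn(binarize_and_clean(p, thr), g)
                for p, g in zip(prob_images, gt_masks)
            ]))
            if score >= best[0]:  # >= keeps the later (higher) grid point on ties
                best = (score, thr)
    if best[0] <= 0.0:
        raise ValueError("no threshold achieves positive overlap; "
                         "probability images look empty")
    return best[1]


def cell_labels_view(mask: np.ndarray, config: RunConfig) -> np.ndarray:
    """Full-resolution cell labels sampled at the block-center grid.

    Labeling before sampling keeps each cell one entity even when the grid
    crop cuts through a thin process; pass the result to
    ``match_detections`` so fragments of one cell are never double-counted.
    """
    labels = skimage.measure.label(np.asarray(mask, dtype=bool), connectivity=2)
    return block_grid_view(labels, config)


def match_detections(pred_mask: np.ndarray, gt_mask: np.ndarray) -> tuple[int, int, int]:
    """Component-level matching: (TP, FN, FP).

    A ground-truth cell counts as detected (TP) when any predicted component
    shares at least one pixel with it — cell body or processes.  A predicted
    component that touches no ground-truth cell is one false positive; one
    touching several cells detects them all and contributes no FP.
    ``TP + FN`` equals the number of ground-truth cells.

    ``gt_mask`` may be boolean (cells are its 8-connected components) or an
    integer label image whose positive values identify cells (see
    ``cell_labels_view``).
    """
    pred_mask = np.asarray(pred_mask, dtype=bool)
    gt = np.asarray(gt_mask)
    if pred_mask.shape != gt.shape:
        raise ValueError(f"mask shapes disagree: {pred_mask.shape} vs {gt.shape}")
    if gt.dtype == bool:
        gt_lab = skimage.measure.label(gt, connectivity=2)
    else:
        gt_lab = gt.astype(np.int64)
    n_gt = len(np.unique(gt_lab[gt_lab > 0]))
    pr_lab, n_pr = skimage.measure.label(pred_mask, connectivity=2, return_num=True)
    overlap = pred_mask & (gt_lab > 0)
    hit_gt = np.unique(gt_lab[overlap])
    hit_pr = np.unique(pr_lab[overlap])
    tp = int((hit_gt > 0).sum())
    fn = n_gt - tp
    fp = n_pr - int((hit_pr > 0).sum())
    return tp, fn, fp


def _rate(num, den):
    return num / den if den > 0 else math.nan


def compute_metrics(counts) -> DetectionResult:
    """TPR/PPV/FNR/FDR per FOV and pooled over FOVs.

    ``counts`` is a sequence of (TP, FN, FP) triples, one per FOV.  Rates
    with a zero denominator are NaN.  The identities ``TPR + FNR = 1`` and
    ``PPV + FDR = 1`` hold exactly wherever defined.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[1] != 3 or np.any(arr < 0):
        raise ValueError("counts must be non-negative (TP, FN, FP) triples")
    tp, fn, fp = arr[:, 0], arr[:, 1], arr[:, 2]
    with np.errstate(invalid="ignore", divide="ignore"):
        tpr = np.where(tp + fn > 0, tp / (tp + fn), np.nan)
        ppv = np.where(tp + fp > 0, tp / (tp + fp), np.nan)
    return DetectionResult(
        tp=tp.astype(int), fn=fn.astype(int), fp=fp.astype(int),
        tpr=tpr, ppv=ppv, fnr=1.0 - tpr, fdr=1.0 - ppv,
        pooled_tpr=_rate(tp.sum(), tp.sum() + fn.sum()),
        pooled_ppv=_rate(tp.sum(), tp.sum() + fp.sum()),
        pooled_fnr=1.0 - _rate(tp.sum(), tp.sum() + fn.sum()),
        pooled_fdr=1.0 - _rate(tp.sum(), tp.sum() + fp.sum()),
    )
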