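"""Masks, labeled training instances, and dataset splitting.

Ground-truth masks come from a label-channel intensity image (GFP in
culture, antibody staining in tissue): threshold (Otsu by default), then
drop objects below a minimum pixel count.

Training instances are built from overlapping spatial blocks (8x8 by
default, stride 1).  The fitting-based method (FBM) averages each of the
seven fitted lifetime parameters over a block's valid pixels; the
decay-based method (DBM) sums the raw photon histograms over the block and
normalizes the result to unit area, so classification sees decay *shape*
rather than brightness.  A block's label is the mask value at its center
pixel.  Tables are split 70/15/15 into train/validation/test, stratified by
label, and z-scored with statistics that travel with the trained model.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib

import numpy as np
import pandas as pd
import skimage.filters
import skimage.measure

from .tcspc_io import DecayCube, FitParamMaps, PARAM_NAMES, RunConfig

__all__ = [
    "drop_small_objects",
    "NormStats",
    "FeatureTable",
    "SplitAssignment",
    "build_mask",
    "block_grid_shape",
    "block_centers",
    "extract_fbm_blocks",
    "extract_dbm_vectors",
    "split_dataset",
    "normalize_features",
]

logger = logging.getLogger(__name__)

TRAIN, VAL, TEST = 0, 1, 2


@dataclasses.dataclass
class NormStats:
    """Per-feature z-score statistics, persisted with the model."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.mean.shape != self.sd.shape or self.mean.ndim != 1:
            raise ValueError("mean and sd must be 1-D arrays of equal length")

    def apply(self, features: np.ndarray) -> np.ndarray:
        return (features - self.mean) / self.sd

    def invert(self, features: np.ndarray) -> np.ndarray:
        return features * self.sd + self.mean

    def to_json(self) -> dict:
        return {"mean": self.mean.tolist(), "sd": self.sd.tolist()}

    @classmethod
    def from_json(cls, obj: dict) -> "NormStats":
        return cls(mean=np.array(obj["mean"]), sd=np.array(obj["sd"]))


@dataclasses.dataclass
class FeatureTable:
    """Labeled block instances from one or more fields of view."""

    fov: np.ndarray        # per-row FOV identifier
    x: np.ndarray          # block-center column (image coordinates)
    y: np.ndarray          # block-center row
    features: np.ndarray   # (n, d)
    labels: np.ndarray     # (n,) in {0, 1}
    feature_names: tuple[str, ...]
    stats: NormStats | None = None

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        n = self.features.shape[0]
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D (rows x dims)")
        if len(self.feature_names) != self.features.shape[1]:
            raise ValueError("feature_names length must match feature dimension")
        for name in ("fov", "x", "y", "labels"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name!r} length mismatch")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")
        if np.isnan(self.features).any():
            raise ValueError("feature rows must not contain NaN")

    def __len__(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @staticmethod
    def concat(tables: list["FeatureTable"]) -> "FeatureTable":
        if not tables:
            raise ValueError("nothing to concatenate")
        names = tables[0].feature_names
        if any(t.feature_names != names for t in tables):
            raise ValueError("tables disagree on feature names")
        return FeatureTable(
            fov=np.concatenate([np.asarray(t.fov) for t in tables]),
            x=np.concatenate([t.x for t in tables]),
            y=np.concatenate([t.y for t in tables]),
            features=np.vstack([t.features for t in tables]),
            labels=np.concatenate([t.labels for t in tables]),
            feature_names=names,
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"fov": self.fov, "x": self.x, "y": self.y})
        for j, name in enumerate(self.feature_names):
            frame[name] = self.features[:, j]
        frame["label"] = self.labels
        return frame

    def to_csv(self, path) -> None:
        """Write the table as CSV plus a JSON sidecar with names and stats."""
        path = pathlib.Path(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = {
            "feature_names": list(self.feature_names),
            "stats": self.stats.to_json() if self.stats is not None else None,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def read_csv(cls, path) -> "FeatureTable":
        path = pathlib.Path(path)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        frame = pd.read_csv(path)
        names = tuple(sidecar["feature_names"])
        stats = NormStats.from_json(sidecar["stats"]) if sidecar["stats"] else None
        return cls(
            fov=frame["fov"].to_numpy(), x=frame["x"].to_numpy(), y=frame["y"].to_numpy(),
            features=frame[list(names)].to_numpy(dtype=float),
            labels=frame["label"].to_numpy(), feature_names=names, stats=stats,
        )


@dataclasses.dataclass
class SplitAssignment:
    """Row-wise train/validation/test codes (0/1/2), stratified by label."""

    codes: np.ndarray
    seed: int

    def mask(self, partition: int) -> np.ndarray:
        return self.codes == partition


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------


def drop_small_objects(mask: np.ndarray, min_object_px: int) -> np.ndarray:
    """Remove 8-connected components with fewer than ``min_object_px`` pixels."""
    mask = np.asarray(mask, dtype=bool)
    if min_object_px <= 1 or not mask.any():
        return mask
    labels, n = skimage.measure.label(mask, connectivity=2, return_num=True)
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_object_px
    keep[0] = False
    return keep[labels]


def build_mask(intensity: np.ndarray, threshold: float | str = "otsu",
               min_object_px: int = 1) -> np.ndarray:
    """Threshold a label-channel image and drop small objects.

    ``threshold`` is either an explicit intensity value or ``"otsu"``.
    Objects (8-connectivity) smaller than ``min_object_px`` are removed.
    """
    intensity = np.asarray(intensity, dtype=float)
    if np.any(intensity < 0):
        raise ValueError("intensity must be non-negative")
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold method {threshold!r}")
        if np.ptp(intensity) == 0:
            raise ValueError(
                "constant image: automatic thresholding is undefined; "
                "pass an explicit threshold value"
            )
        thr = skimage.filters.threshold_otsu(intensity)
    else:
        thr = float(threshold)
    mask = intensity >= thr
    return drop_small_objects(mask, min_object_px)


# ---------------------------------------------------------------------------
# block extraction
# ---------------------------------------------------------------------------


def block_grid_shape(image_shape: tuple[int, int], config: RunConfig) -> tuple[int, int]:
    """Number of block positions (rows, cols) for an image under *config*."""
    h, w = image_shape
    b, s = config.block_size, config.block_stride
    if b > min(h, w):
        raise ValueError(f"block_size {b} exceeds image side {min(h, w)}")
    return ((h - b) // s + 1, (w - b) // s + 1)


def block_centers(image_shape: tuple[int, int], config: RunConfig) -> tuple[np.ndarray, np.ndarray]:
    """Image-space (rows, cols) of block centers: top-left + block_size // 2."""
    nby, nbx = block_grid_shape(image_shape, config)
    c = config.block_size // 2
    rows = np.arange(nby) * config.block_stride + c
    cols = np.arange(nbx) * config.block_stride + c
    return rows, cols


def _window_sums(arr: np.ndarray, b: int, s: int) -> np.ndarray:
    """Sliding b x b window sums at stride s via a summed-area table."""
    ii = np.zeros((arr.shape[0] + 1, arr.shape[1] + 1) + arr.shape[2:], dtype=float)
    ii[1:, 1:] = np.cumsum(np.cumsum(arr, axis=0), axis=1)
    nby = (arr.shape[0] - b) // s + 1
    nbx = (arr.shape[1] - b) // s + 1
    y0 = np.arange(nby) * s
    x0 = np.arange(nbx) * s
    return (ii[np.ix_(y0 + b, x0 + b)] - ii[np.ix_(y0, x0 + b)]
            - ii[np.ix_(y0 + b, x0)] + ii[np.ix_(y0, x0)])


def _block_table(fov_id, feats: np.ndarray, keep: np.ndarray, mask: np.ndarray,
                 names: tuple[str, ...], config: RunConfig) -> "FeatureTable":
    rows, cols = block_centers(mask.shape, config)
    yy, xx = np.meshgrid(rows, cols, indexing="ij")
    labels = np.asarray(mask, dtype=bool)[yy, xx]
    keep = keep & np.isfinite(feats).all(axis=2)
    sel = keep.ravel()
    n = int(sel.sum())
    return FeatureTable(
        fov=np.full(n, fov_id, dtype=object),
        y=yy.ravel()[sel], x=xx.ravel()[sel],
        features=feats.reshape(-1, feats.shape[2])[sel],
        labels=labels.ravel()[sel].astype(np.int8),
        feature_names=names,
    )


def extract_fbm_blocks(maps: FitParamMaps, mask: np.ndarray, config: RunConfig,
                       fov_id="fov0", include_chi2: bool = True) -> FeatureTable:
    """Block-mean lifetime-parameter features with mask-center labels.

    Features are the per-parameter means over each block's *valid* pixels;
    blocks with fewer than 50% valid pixels are dropped.  ``include_chi2``
    keeps the goodness-of-fit map as a seventh feature (ablation flag).
    """
    mask = np.asarray(mask, dtype=bool)
    if maps.shape != mask.shape:
        raise ValueError(f"maps {maps.shape} and mask {mask.shape} disagree")
    b, s = config.block_size, config.block_stride
    block_grid_shape(mask.shape, config)  # validates block size
    names = tuple(n for n in PARAM_NAMES if include_chi2 or n != "chi2")
    valid = maps.valid.astype(float)
    n_valid = _window_sums(valid, b, s)
    keep = n_valid >= 0.5 * b * b
    feats = np.empty(n_valid.shape + (len(names),))
    with np.errstate(invalid="ignore", divide="ignore"):
        for j, name in enumerate(names):
            grid = np.nan_to_num(getattr(maps, name), nan=0.0) * valid
            feats[:, :, j] = _window_sums(grid, b, s) / np.maximum(n_valid, 1e-12)
    feats[~keep] = 0.0  # rows are dropped; keep the array NaN-free
    return _block_table(fov_id, feats, keep, mask, names, config)


def extract_dbm_vectors(cube: DecayCube, mask: np.ndarray, config: RunConfig,
                        fov_id="fov0") -> FeatureTable:
    """Block-summed decay histograms, normalized to unit area.

    Zero-photon blocks are dropped.  Normalization removes the photon
    budget so the classifier sees only decay shape.
    """
    mask = np.asarray(mask, dtype=bool)
    if cube.shape != mask.shape:
        raise ValueError(f"cube {cube.shape} and mask {mask.shape} disagree")
    b, s = config.block_size, config.block_stride
    block_grid_shape(mask.shape, config)
    sums = _window_sums(cube.counts.astype(float), b, s)  # (nby, nbx, T)
    totals = sums.sum(axis=2)
    keep = totals > 0
    feats = sums / np.maximum(totals, 1e-300)[..., None]
    feats[~keep] = 0.0
    names = tuple(f"bin{i:03d}" for i in range(cube.n_bins))
    return _block_table(fov_id, feats, keep, mask, names, config)


# ---------------------------------------------------------------------------
# splitting and normalization
# ---------------------------------------------------------------------------


def split_dataset(table: FeatureTable, fractions=(0.70, 0.15, 0.15),
                  seed: int = 0) -> SplitAssignment:
    """Random train/validation/test assignment, stratified by label."""
    fractions = tuple(float(f) for f in fractions)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1; got {sum(fractions)}")
    rng = np.random.default_rng(seed)
    codes = np.empty(len(table), dtype=np.int8)
    for cls in np.unique(table.labels):
        idx = np.nonzero(table.labels == cls)[0]
        if idx.size < 3:
            raise ValueError(
                f"class {cls} has {idx.size} rows, fewer than the 3 partitions")
        perm = rng.permutation(idx)
        c1 = int(round(fractions[0] * idx.size))
        c2 = int(round((fractions[0] + fractions[1]) * idx.size))
        codes[perm[:c1]] = TRAIN
        codes[perm[c1:c2]] = VAL
        codes[perm[c2:]] = TEST
    return SplitAssignment(codes=codes, seed=seed)


def normalize_features(table: FeatureTable,
                       stats: NormStats | None = None) -> tuple[FeatureTable, NormStats]:
    """z-score features; compute stats from the table or apply given ones.

    Train-time: call without ``stats``.  Test-time: pass the training stats
    so held-out rows are scaled identically.  Zero-variance features are
    centered only (sd treated as 1) with a logged warning.
    """
    if len(table) == 0:
        raise ValueError("cannot normalize an empty table")
    if stats is None:
        mean = table.features.mean(axis=0)
        sd = table.features.std(axis=0)
        flat = sd == 0
        if flat.any():
            logger.warning("zero-variance features centered only: %s",
                           [table.feature_names[j] for j in np.nonzero(flat)[0]])
            sd = np.where(flat, 1.0, sd)
        stats = NormStats(mean=mean, sd=sd)
    normalized = dataclasses.replace(
        table, features=stats.apply(table.features), stats=stats)
    return normalized, stats
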