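"""Readers and writers for every on-disk TCSPC/FLIM artifact.

The package's native container for time-resolved data is a small HDF5
dialect: a single dataset ``counts`` with axis order (y, x, t) and the
attributes ``bin_width_ns`` and ``shift_bins``.  Decay cubes may also be
stored as multi-page grayscale TIFF stacks whose pages are the time bins.
Fitted lifetime-parameter maps travel as plain-text matrices (one ``.asc``
file per parameter, mirroring the export convention of commercial TCSPC
fitting software), intensity images and masks as single-page TIFFs.

Conventions used throughout the package
---------------------------------------
* axis order ``(y, x, t)``, pixel coordinates 0-based, row-major;
* 256 time bins by default, bin width 12.5 ns / 256 ~ 48.8 ps (the
  repetition period of an 80 MHz Ti:Sapphire laser) unless metadata says
  otherwise;
* ASC matrices are single-space separated, C-locale decimals, with
  unfitted pixels spelled ``NaN``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import pathlib
from typing import Mapping

import h5py
import numpy as np
import tifffile

__all__ = [
    "DEFAULT_N_BINS",
    "DEFAULT_BIN_WIDTH_NS",
    "PARAM_NAMES",
    "FormatError",
    "DecayCube",
    "IRFVector",
    "RunConfig",
    "FitParamMaps",
    "read_decay_cube",
    "write_decay_cube",
    "read_param_maps",
    "write_param_maps",
    "read_intensity_image",
    "read_mask",
    "write_image",
    "write_mask",
    "read_irf",
    "write_irf",
    "read_config",
    "write_config",
    "config_hash",
]

DEFAULT_N_BINS = 256
#: 80 MHz repetition period divided into 256 TCSPC bins.
DEFAULT_BIN_WIDTH_NS = 12.5 / 256

#: Canonical order of the seven fitted-parameter maps.
PARAM_NAMES = ("t1", "t2", "tm", "a1", "a2", "a1pct", "chi2")


class FormatError(ValueError):
    """An on-disk artifact violates the documented format contract."""


def _as_path(path) -> pathlib.Path:
    return pathlib.Path(path)


@dataclasses.dataclass
class DecayCube:
    """A field of view of per-pixel TCSPC photon-arrival histograms.

    Parameters
    ----------
    counts
        Array of shape ``(height, width, n_bins)``.  Non-negative.  Integer
        for raw photon counts; real-valued cubes arise from simulation steps
        such as sub-bin decay shifting.
    bin_width
        Time per bin in nanoseconds.
    pixel_size
        Optional lateral pixel size in micrometers (metadata only).
    shift_bins
        Per-acquisition decay shift in bins.  For synthetic cubes this is
        ground-truth metadata; the fitting code never reads it.
    """

    counts: np.ndarray
    bin_width: float = DEFAULT_BIN_WIDTH_NS
    pixel_size: float | None = None
    shift_bins: float = 0.0

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise FormatError(
                f"decay cube must be 3-D (y, x, t); got rank {self.counts.ndim}"
            )
        if self.counts.shape[2] < 4:
            raise FormatError(f"need at least 4 time bins; got {self.counts.shape[2]}")
        if np.any(self.counts < 0):
            raise FormatError("decay cube contains negative counts")
        if not self.bin_width > 0:
            raise FormatError(f"bin_width must be positive; got {self.bin_width}")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial shape (height, width)."""
        return self.counts.shape[:2]

    @property
    def time_axis(self) -> np.ndarray:
        """Bin-center times in nanoseconds."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_width

    @property
    def total_counts(self) -> np.ndarray:
        """Per-pixel photon totals (sum over the time axis)."""
        return self.counts.sum(axis=2)


@dataclasses.dataclass
class IRFVector:
    """Instrument response function sampled on the same time bins as the data."""

    values: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise FormatError("IRF must be a 1-D vector")
        if np.any(self.values < 0):
            raise FormatError("IRF values must be non-negative")
        total = self.values.sum()
        if not total > 0:
            raise FormatError("IRF must have positive total")
        if self.normalized and not math.isclose(total, 1.0, abs_tol=1e-9):
            raise FormatError(f"IRF flagged normalized but sums to {total!r}")

    @property
    def n_bins(self) -> int:
        return self.values.size

    @property
    def mode(self) -> int:
        """Index of the peak bin."""
        return int(np.argmax(self.values))

    def normalize(self) -> "IRFVector":
        return IRFVector(self.values / self.values.sum(), normalized=True)


@dataclasses.dataclass
class RunConfig:
    """Knobs shared across the fitting / feature / training pipeline."""

    photon_threshold: int = 100
    bin_radius: int = 1
    block_size: int = 8
    block_stride: int = 1
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    n_hidden: int = 10
    rng_seed: int = 0

    def __post_init__(self):
        if self.photon_threshold < 0:
            raise ValueError("photon_threshold must be >= 0")
        if self.bin_radius < 0:
            raise ValueError("bin_radius must be >= 0")
        if self.block_size < 1 or self.block_stride < 1:
            raise ValueError("block_size and block_stride must be positive")
        fr = self.split_fractions
        if len(fr) != 3 or any(not (0 < f < 1) for f in fr):
            raise ValueError("split fractions must be three values in (0, 1)")
        if not math.isclose(sum(fr), 1.0, abs_tol=1e-9):
            raise ValueError(f"split fractions must sum to 1; got {sum(fr)!r}")
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be positive")


@dataclasses.dataclass
class FitParamMaps:
    """The seven per-pixel fitted-parameter images plus a validity mask.

    Pixels that failed the photon threshold (or were never fit) are NaN in
    every grid and False in ``valid``.
    """

    t1: np.ndarray
    t2: np.ndarray
    tm: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    a1pct: np.ndarray
    chi2: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self):
        grids = [np.asarray(getattr(self, n), dtype=float) for n in PARAM_NAMES]
        shape = grids[0].shape
        if any(g.shape != shape for g in grids):
            raise FormatError("parameter maps must all share dimensions")
        for name, g in zip(PARAM_NAMES, grids):
            setattr(self, name, g)
        if self.valid is None:
            finite = np.ones(shape, dtype=bool)
            for g in grids:
                finite &= np.isfinite(g)
            self.valid = finite
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != shape:
                raise FormatError("validity mask shape does not match maps")
        # Invalid pixels are NaN everywhere, by contract.
        for name in PARAM_NAMES:
            g = getattr(self, name)
            g[~self.valid] = np.nan

    @property
    def shape(self) -> tuple[int, int]:
        return self.t1.shape

    def as_dict(self) -> dict[str, np.ndarray]:
        return {n: getattr(self, n) for n in PARAM_NAMES}

    @classmethod
    def from_dict(cls, maps: Mapping[str, np.ndarray], valid=None) -> "FitParamMaps":
        missing = [n for n in PARAM_NAMES if n not in maps]
        if missing:
            raise FormatError(f"missing parameter maps: {missing}")
        return cls(**{n: np.array(maps[n], dtype=float) for n in PARAM_NAMES}, valid=valid)


def write_config(config: RunConfig, path) -> None:
    """Persist a run configuration as JSON."""
    obj = dataclasses.asdict(config)
    obj["split_fractions"] = list(config.split_fractions)
    _as_path(path).write_text(json.dumps(obj, indent=1))


def read_config(path) -> RunConfig:
    path = _as_path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    obj = json.loads(path.read_text())
    obj["split_fractions"] = tuple(obj["split_fractions"])
    return RunConfig(**obj)


def config_hash(config: RunConfig) -> str:
    """Short stable digest of a run configuration, for report provenance."""
    obj = dataclasses.asdict(config)
    obj["split_fractions"] = list(config.split_fractions)
    payload = json.dumps(obj, sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


# ---------------------------------------------------------------------------
# decay cubes
# ---------------------------------------------------------------------------

_TIFF_SUFFIXES = {".tif", ".tiff"}


def read_decay_cube(path) -> DecayCube:
    """Read a decay cube from the HDF5 dialect or a multi-page TIFF stack.

    HDF5 files must contain a 3-D dataset ``counts`` in (y, x, t) order;
    TIFF pages are interpreted as time bins.  Missing metadata attributes
    fall back to the package defaults (12.5/256 ns bins, zero shift).
    """
    path = _as_path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    if path.suffix.lower() in _TIFF_SUFFIXES:
        stack = tifffile.imread(path)
        if stack.ndim == 2:  # single page: one time bin is not a decay
            raise FormatError(
                f"{path}: expected a multi-page time stack, got a single 2-D page"
            )
        if stack.ndim != 3:
            raise FormatError(f"{path}: expected pages of 2-D images, got rank {stack.ndim}")
        counts = np.moveaxis(stack, 0, 2)  # (t, y, x) -> (y, x, t)
        return DecayCube(counts=counts)
    with h5py.File(path, "r") as fh:
        if "counts" not in fh:
            raise FormatError(f"{path}: missing dataset 'counts'")
        ds = fh["counts"]
        if ds.ndim != 3:
            raise FormatError(
                f"{path}: dataset 'counts' must be 3-D (y, x, t); got rank {ds.ndim}"
            )
        counts = ds[()]
        attrs = dict(ds.attrs)
        bin_width = float(attrs.get("bin_width_ns", DEFAULT_BIN_WIDTH_NS))
        shift = float(attrs.get("shift_bins", 0.0))
        pixel = attrs.get("pixel_size_um")
        pixel = float(pixel) if pixel is not None else None
    return DecayCube(counts=counts, bin_width=bin_width, pixel_size=pixel, shift_bins=shift)


def write_decay_cube(cube: DecayCube, path) -> None:
    """Write a cube to HDF5 (default) or a multi-page TIFF (by suffix)."""
    path = _as_path(path)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        tifffile.imwrite(path, np.moveaxis(cube.counts, 2, 0))
        return
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("counts", data=cube.counts)
        ds.attrs["bin_width_ns"] = cube.bin_width
        ds.attrs["shift_bins"] = cube.shift_bins
        if cube.pixel_size is not None:
            ds.attrs["pixel_size_um"] = cube.pixel_size


# ---------------------------------------------------------------------------
# IRF vectors
# ---------------------------------------------------------------------------


def read_irf(path) -> IRFVector:
    path = _as_path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    with h5py.File(path, "r") as fh:
        if "irf" not in fh:
            raise FormatError(f"{path}: missing dataset 'irf'")
        values = fh["irf"][()]
        normalized = bool(fh["irf"].attrs.get("normalized", False))
    return IRFVector(values=values, normalized=normalized)


def write_irf(irf: IRFVector, path) -> None:
    with h5py.File(_as_path(path), "w") as fh:
        ds = fh.create_dataset("irf", data=irf.values)
        ds.attrs["normalized"] = irf.normalized


# ---------------------------------------------------------------------------
# parameter maps (ASC dialect)
# ---------------------------------------------------------------------------


def _format_asc(matrix: np.ndarray) -> str:
    lines = []
    for row in np.atleast_2d(matrix):
        lines.append(" ".join("NaN" if not np.isfinite(v) else f"{v:.9g}" for v in row))
    return "\n".join(lines) + "\n"


def write_param_maps(maps: FitParamMaps, directory) -> None:
    """Write one ``<name>.asc`` text matrix per parameter into *directory*."""
    directory = _as_path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in PARAM_NAMES:
        (directory / f"{name}.asc").write_text(_format_asc(getattr(maps, name)))


def read_param_maps(directory, zero_is_nan: bool = False) -> FitParamMaps:
    """Read the seven ``.asc`` parameter matrices from *directory*.

    Unfitted pixels may be encoded either as ``NaN`` (the native convention)
    or as 0 (``zero_is_nan=True``, matching exports that blank rejected
    pixels with zeros).
    """
    directory = _as_path(directory)
    grids: dict[str, np.ndarray] = {}
    for name in PARAM_NAMES:
        f = directory / f"{name}.asc"
        if not f.exists():
            raise FormatError(f"missing parameter file: {f.name}")
        try:
            grid = np.loadtxt(f, ndmin=2)
        except ValueError as exc:
            raise FormatError(f"{f.name}: not a numeric matrix ({exc})") from exc
        grids[name] = grid
    shapes = {name: g.shape for name, g in grids.items()}
    if len(set(shapes.values())) != 1:
        raise FormatError(f"parameter maps disagree on dimensions: {shapes}")
    if zero_is_nan:
        blank = np.ones(grids["t1"].shape, dtype=bool)
        for g in grids.values():
            blank &= g == 0
        for g in grids.values():
            g[blank] = np.nan
    return FitParamMaps.from_dict(grids)


# ---------------------------------------------------------------------------
# intensity images and masks
# ---------------------------------------------------------------------------


def read_intensity_image(path) -> np.ndarray:
    """Read a single-page grayscale TIFF as a non-negative float image."""
    path = _as_path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    img = tifffile.imread(path)
    if img.ndim != 2:
        raise FormatError(
            f"{path}: expected a single-page grayscale image, got shape "
            f"{img.shape}; select one channel before loading"
        )
    img = np.asarray(img, dtype=float)
    if np.any(img < 0):
        raise FormatError(f"{path}: intensity image contains negative values")
    return img


def read_mask(path) -> np.ndarray:
    """Read a binary mask stored as a 0/1 or 0/255 single-page TIFF."""
    path = _as_path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    img = tifffile.imread(path)
    if img.ndim != 2:
        raise FormatError(
            f"{path}: expected a single-page mask, got shape {img.shape}; "
            "select one channel before loading"
        )
    values = set(np.unique(img).tolist())
    if values <= {0, 1}:
        return img.astype(bool)
    if values <= {0, 255}:
        return (img > 0).astype(bool)
    raise FormatError(f"{path}: mask values must be 0/1 or 0/255; found {sorted(values)[:8]}")


def write_image(image: np.ndarray, path) -> None:
    tifffile.imwrite(_as_path(path), np.asarray(image))


def write_mask(mask: np.ndarray, path) -> None:
    tifffile.imwrite(_as_path(path), (np.asarray(mask, dtype=bool)).astype(np.uint8) * 255)
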