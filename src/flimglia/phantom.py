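"""Synthetic FLIM fields of view with ground truth.

Every downstream stage of the detection workflow (fitting, feature
extraction, network training, threshold calibration, detection scoring) is
exercised on phantoms produced here: images of branched cells from two
lifetime classes on an autofluorescent background, rendered into TCSPC
photon-count cubes by IRF convolution of per-pixel bi-exponential decays
followed by Poisson draws.

A phantom emulates the study conditions of label-free NAD(P)H imaging of
mixed glial preparations: the target class ("microglia") carries a higher
free-NAD(P)H fraction (a1%) and a shorter bound lifetime (tau2) than the
other glial class, while the background holds intermediate values.  The
default class triples are package assumptions chosen to give a separable
but noisy problem — plausible NAD(P)H ranges, not measured biology — and
everything is configurable.  A "tissue" preset raises parameter
heterogeneity and background brightness to mimic the harder in-slice
setting; a per-acquisition decay-bin shift (optionally jittered per FOV)
mimics detector timing drift between imaging sessions.

Cells are drawn per class as a filled-ellipse soma plus random-walk branch
processes 1–2 px wide, so detection rules that accept overlap with "the
cell body or the processes" are exercised.  Each cell draws one lifetime
triple from its class distribution (cells are internally coherent) and
pixels add Gaussian jitter at 20% of the class sd.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .decay_fit import shift_curves, _convolver
from .tcspc_io import (
    DEFAULT_BIN_WIDTH_NS,
    DEFAULT_N_BINS,
    DecayCube,
    FitParamMaps,
    IRFVector,
)

__all__ = [
    "CellClassSpec",
    "BackgroundSpec",
    "PhantomConfig",
    "PhantomFOV",
    "PhantomError",
    "generate_irf",
    "generate_phantom",
    "apply_shift",
    "culture_preset",
    "tissue_preset",
]


class PhantomError(RuntimeError):
    """Raised when a phantom cannot be generated under its configuration."""


@dataclasses.dataclass
class CellClassSpec:
    """Lifetime distribution and morphology of one cell class.

    ``tau1``/``tau2``/``a1_pct`` are (mean, sd) pairs; one triple is drawn
    per cell, with per-pixel jitter at 20% of the (heterogeneity-scaled) sd.
    """

    name: str
    tau1: tuple[float, float]
    tau2: tuple[float, float]
    a1_pct: tuple[float, float]
    photons_per_pixel: float
    soma_radius: tuple[int, int] = (3, 6)
    n_processes: tuple[int, int] = (3, 6)
    process_length: tuple[int, int] = (8, 18)
    target: bool = False

    def __post_init__(self):
        if not (0 < self.tau1[0] < self.tau2[0]):
            raise ValueError("need 0 < mean tau1 < mean tau2")
        if not (0 < self.a1_pct[0] < 100):
            raise ValueError("mean a1% must lie in (0, 100)")
        if min(self.tau1[1], self.tau2[1], self.a1_pct[1]) < 0:
            raise ValueError("sds must be >= 0")
        if self.photons_per_pixel <= 0:
            raise ValueError("photons_per_pixel must be positive")


@dataclasses.dataclass
class BackgroundSpec:
    """Diffuse autofluorescence behind the cells."""

    photons_per_pixel: float = 500.0
    tau1: tuple[float, float] = (0.4, 0.05)
    tau2: tuple[float, float] = (2.7, 0.2)
    a1_pct: tuple[float, float] = (73.0, 4.0)


@dataclasses.dataclass
class PhantomConfig:
    shape: tuple[int, int] = (128, 128)
    classes: tuple[CellClassSpec, ...] = ()
    n_cells: tuple[int, ...] = ()
    background: BackgroundSpec = dataclasses.field(default_factory=BackgroundSpec)
    n_bins: int = DEFAULT_N_BINS
    bin_width: float = DEFAULT_BIN_WIDTH_NS
    irf_sigma_bins: float = 2.0
    irf_t0_bins: float = 10.0
    shift_bins: float = 0.0
    #: sd of per-FOV Gaussian jitter added to shift_bins (0 = none)
    shift_jitter_sd: float = 0.0
    #: multiplier on every parameter sd ("tissue" > "culture")
    heterogeneity: float = 1.0

    def __post_init__(self):
        if len(self.classes) != len(self.n_cells):
            raise ValueError("classes and n_cells must have equal length")
        if self.background.photons_per_pixel < 0:
            raise ValueError("photon means must be >= 0")
        side = min(self.shape)
        for spec in self.classes:
            if 2 * (spec.soma_radius[1] + 1) >= side:
                raise PhantomError(
                    f"cells of class {spec.name!r} cannot fit inside a "
                    f"{self.shape} image"
                )


@dataclasses.dataclass
class PhantomFOV:
    """One generated field of view with its ground truth."""

    cube: DecayCube
    mask: np.ndarray          # union of target-class footprints
    class_map: np.ndarray     # 0 = background, 1.. = class index + 1
    true_maps: FitParamMaps   # generating parameters per pixel
    manifest: list[dict]      # per-cell draws (class, center, triple)
    irf: IRFVector


def generate_irf(n_bins: int, sigma_bins: float, t0_bins: float) -> IRFVector:
    """Unit-area Gaussian IRF centered at ``t0_bins`` with width ``sigma_bins``."""
    if sigma_bins <= 0:
        raise ValueError("sigma_bins must be positive")
    if not (0 <= t0_bins < n_bins):
        raise ValueError("t0_bins must lie within the time axis")
    k = np.arange(n_bins)
    values = np.exp(-0.5 * ((k - t0_bins) / sigma_bins) ** 2)
    return IRFVector(values / values.sum(), normalized=True)


def apply_shift(cube: DecayCube, shift_bins: float) -> DecayCube:
    """Shift every pixel's histogram by ``shift_bins`` (sub-bin, circular).

    Linear interpolation conserves each pixel's total count exactly; the
    result has real-valued counts (no re-rounding), as appropriate for
    simulation use.
    """
    if abs(shift_bins) >= cube.n_bins / 2:
        raise ValueError("|shift_bins| must be < n_bins / 2")
    if shift_bins == 0.0:
        return cube
    shifted = shift_curves(cube.counts, shift_bins, axis=2)
    return DecayCube(counts=shifted, bin_width=cube.bin_width,
                     pixel_size=cube.pixel_size,
                     shift_bins=cube.shift_bins + shift_bins)


# ---------------------------------------------------------------------------
# morphology rasterization
# ---------------------------------------------------------------------------


def _draw_cell(rng: np.random.Generator, shape: tuple[int, int],
               spec: CellClassSpec) -> np.ndarray:
    """Rasterize one cell (soma ellipse + branch processes) as a bool image."""
    h, w = shape
    r_lo, r_hi = spec.soma_radius
    margin = r_hi + 2
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        raise PhantomError(f"image {shape} too small for soma radius {r_hi}")
    cy = int(rng.integers(margin, h - margin))
    cx = int(rng.integers(margin, w - margin))
    ry = float(rng.uniform(r_lo, r_hi))
    rx = float(rng.uniform(r_lo, r_hi))
    theta = float(rng.uniform(0, math.pi))

    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    ct, st = math.cos(theta), math.sin(theta)
    u = dy * ct + dx * st
    v = -dy * st + dx * ct
    footprint = (u / ry) ** 2 + (v / rx) ** 2 <= 1.0

    n_proc = int(rng.integers(spec.n_processes[0], spec.n_processes[1] + 1))
    for _ in range(n_proc):
        length = int(rng.integers(spec.process_length[0], spec.process_length[1] + 1))
        width2 = rng.random() < 0.5  # ~half the processes are 2 px wide
        angle = rng.uniform(0, 2 * math.pi)
        # walk starts at the soma center so the chain (step <= 1 px per
        # axis) is always 8-connected to the cell body
        py, px = float(cy), float(cx)
        length += int(max(ry, rx))
        for _ in range(length):
            angle += rng.normal(0, 0.35)  # gentle random walk
            py += math.cos(angle)
            px += math.sin(angle)
            iy, ix = int(round(py)), int(round(px))
            if not (0 <= iy < h and 0 <= ix < w):
                break  # processes truncate at the image border
            footprint[iy, ix] = True
            if width2 and 0 <= iy + 1 < h:
                footprint[iy + 1, ix] = True
    return footprint


# ---------------------------------------------------------------------------
# phantom generation
# ---------------------------------------------------------------------------


def _draw_triple(rng, spec_tau1, spec_tau2, spec_a1, het) -> tuple[float, float, float]:
    tau1 = max(0.05, rng.normal(spec_tau1[0], spec_tau1[1] * het))
    tau2 = max(tau1 * 1.05, rng.normal(spec_tau2[0], spec_tau2[1] * het))
    a1p = float(np.clip(rng.normal(spec_a1[0], spec_a1[1] * het), 1.0, 99.0))
    return float(tau1), float(tau2), a1p


def generate_phantom(config: PhantomConfig, seed: int) -> PhantomFOV:
    """Generate one synthetic FOV; identical output under the same seed."""
    rng = np.random.default_rng(seed)
    h, w = config.shape
    het = config.heterogeneity

    # --- geometry: later-placed cells overwrite earlier ones -------------
    class_map = np.zeros((h, w), dtype=np.int16)
    tau1_map = np.empty((h, w))
    tau2_map = np.empty((h, w))
    a1p_map = np.empty((h, w))
    photons = np.full((h, w), float(config.background.photons_per_pixel))

    bg = config.background
    tau1_map[:] = np.maximum(0.05, rng.normal(bg.tau1[0], bg.tau1[1] * het * 0.2, (h, w)))
    tau2_map[:] = rng.normal(bg.tau2[0], bg.tau2[1] * het * 0.2, (h, w))
    a1p_map[:] = rng.normal(bg.a1_pct[0], bg.a1_pct[1] * het * 0.2, (h, w))
    # background pixels also vary at the full (scaled) sd across the FOV
    tau2_map += rng.normal(0, bg.tau2[1] * het * 0.1)
    tau2_map = np.maximum(tau2_map, tau1_map * 1.05)
    a1p_map = np.clip(a1p_map, 1.0, 99.0)

    manifest: list[dict] = []
    occupied = np.zeros((h, w), dtype=bool)
    for ci, (spec, n) in enumerate(zip(config.classes, config.n_cells)):
        for _ in range(n):
            # placement retries keep cells from overwriting each other, so
            # ground truth stays a set of distinct, countable cells
            for _attempt in range(200):
                footprint = _draw_cell(rng, (h, w), spec)
                if not (footprint & occupied).any():
                    break
            else:
                raise PhantomError(
                    f"could not place a {spec.name!r} cell without overlap "
                    f"after 200 draws; the field is too crowded")
            occupied |= footprint
            tau1, tau2, a1p = _draw_triple(rng, spec.tau1, spec.tau2, spec.a1_pct, het)
            class_map[footprint] = ci + 1
            npix = int(footprint.sum())
            # per-pixel jitter at 20% of the class sd
            tau1_map[footprint] = np.maximum(
                0.05, tau1 + rng.normal(0, spec.tau1[1] * het * 0.2, npix))
            t2pix = tau2 + rng.normal(0, spec.tau2[1] * het * 0.2, npix)
            tau2_map[footprint] = np.maximum(t2pix, tau1_map[footprint] * 1.05)
            a1p_map[footprint] = np.clip(
                a1p + rng.normal(0, spec.a1_pct[1] * het * 0.2, npix), 1.0, 99.0)
            photons[footprint] = spec.photons_per_pixel
            ys, xs = np.nonzero(footprint)
            manifest.append({
                "class": spec.name, "class_index": ci + 1, "target": spec.target,
                "center": (float(ys.mean()), float(xs.mean())), "n_pixels": npix,
                "tau1": tau1, "tau2": tau2, "a1_pct": a1p,
            })

    mask = np.zeros((h, w), dtype=bool)
    for ci, spec in enumerate(config.classes):
        if spec.target:
            mask |= class_map == ci + 1

    # --- expected decays: IRF (x) bi-exponential, scaled to photon budget -
    irf = generate_irf(config.n_bins, config.irf_sigma_bins, config.irf_t0_bins)
    t = (np.arange(config.n_bins) + 0.5) * config.bin_width
    a1 = a1p_map / 100.0
    flat_t1 = tau1_map.reshape(-1, 1)
    flat_t2 = tau2_map.reshape(-1, 1)
    decays = (a1.reshape(-1, 1) * np.exp(-t[None, :] / flat_t1)
              + (1.0 - a1.reshape(-1, 1)) * np.exp(-t[None, :] / flat_t2))
    conv = _convolver(irf.values, config.n_bins)
    expected = conv(decays)
    np.maximum(expected, 0.0, out=expected)
    totals = expected.sum(axis=1, keepdims=True)
    expected *= photons.reshape(-1, 1) / np.maximum(totals, 1e-300)

    shift = config.shift_bins
    if config.shift_jitter_sd > 0:
        shift += float(rng.normal(0, config.shift_jitter_sd))
    if shift != 0.0:
        expected = shift_curves(expected, shift, axis=1)

    counts = rng.poisson(expected).astype(np.int32).reshape(h, w, config.n_bins)
    cube = DecayCube(counts=counts, bin_width=config.bin_width, shift_bins=shift)

    a1_true = a1
    a2_true = 1.0 - a1
    tm = a1_true * tau1_map + a2_true * tau2_map
    true_maps = FitParamMaps(
        t1=tau1_map, t2=tau2_map, tm=tm, a1=a1_true, a2=a2_true,
        a1pct=a1p_map, chi2=np.zeros((h, w)),
        valid=np.ones((h, w), dtype=bool),
    )
    return PhantomFOV(cube=cube, mask=mask, class_map=class_map,
                      true_maps=true_maps, manifest=manifest, irf=irf)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


def _default_classes(photons: float) -> tuple[CellClassSpec, CellClassSpec]:
    microglia = CellClassSpec(
        name="microglia", target=True,
        tau1=(0.4, 0.05), tau2=(2.4, 0.2), a1_pct=(78.0, 4.0),
        photons_per_pixel=photons,
        soma_radius=(3, 6), n_processes=(3, 6), process_length=(8, 18),
    )
    other = CellClassSpec(
        name="other_glia",
        tau1=(0.4, 0.05), tau2=(3.0, 0.2), a1_pct=(68.0, 4.0),
        photons_per_pixel=photons,
        soma_radius=(4, 8), n_processes=(2, 4), process_length=(6, 14),
    )
    return microglia, other


def culture_preset(shape: tuple[int, int] = (128, 128), photons: float = 3000.0,
                   n_microglia: int = 7, n_other: int = 7, **overrides) -> PhantomConfig:
    """Mixed glial culture: well-separated classes, dim background."""
    classes = _default_classes(photons)
    cfg = dict(
        shape=shape, classes=classes, n_cells=(n_microglia, n_other),
        background=BackgroundSpec(photons_per_pixel=photons / 6.0),
        heterogeneity=1.0,
    )
    cfg.update(overrides)
    return PhantomConfig(**cfg)


def tissue_preset(shape: tuple[int, int] = (128, 128), photons: float = 3000.0,
                  n_microglia: int = 7, n_other: int = 9, **overrides) -> PhantomConfig:
    """Fixed brain slice: brighter, more heterogeneous, denser field."""
    classes = _default_classes(photons)
    cfg = dict(
        shape=shape, classes=classes, n_cells=(n_microglia, n_other),
        background=BackgroundSpec(photons_per_pixel=photons / 2.5),
        heterogeneity=2.5,
    )
    cfg.update(overrides)
    return PhantomConfig(**cfg)
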