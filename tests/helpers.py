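"""Shared construction helpers for the test suite."""

from __future__ import annotations

import numpy as np

from flimglia import phantom
from flimglia.decay_fit import _convolver
from flimglia.tcspc_io import DEFAULT_BIN_WIDTH_NS, IRFVector

BW = DEFAULT_BIN_WIDTH_NS
N_BINS = 256


def delta_irf(n_bins: int = N_BINS) -> IRFVector:
    values = np.zeros(n_bins)
    values[0] = 1.0
    return IRFVector(values, normalized=True)


def gaussian_irf(sigma: float = 2.0, t0: float = 10.0, n_bins: int = N_BINS) -> IRFVector:
    return phantom.generate_irf(n_bins, sigma, t0)


def biexp_curve(irf: IRFVector, tau1: float, tau2: float, a1_pct: float,
                photons: float, bin_width: float = BW) -> np.ndarray:
    """Noiseless IRF-convolved two-component decay scaled to a photon budget.

    Built through an FFT convolution, independent of the recursion-based
    bases inside the fitting engine.
    """
    n = irf.n_bins
    t = (np.arange(n) + 0.5) * bin_width
    a1 = a1_pct / 100.0
    decay = a1 * np.exp(-t / tau1) + (1.0 - a1) * np.exp(-t / tau2)
    curve = _convolver(irf.values, n)(decay)
    return curve * photons / curve.sum()


def tiny_culture_config(shape=(64, 64), photons=2000.0, n_microglia=3, n_other=3,
                        **overrides):
    """Culture-like conditions scaled down for fast tests.

    Same lifetime triples and background as the full preset, but smaller
    frames with fewer, smaller cells so the field stays sparse.
    """
    microglia = phantom.CellClassSpec(
        name="microglia", target=True,
        tau1=(0.4, 0.05), tau2=(2.4, 0.2), a1_pct=(78.0, 4.0),
        photons_per_pixel=photons,
        soma_radius=(3, 5), n_processes=(2, 4), process_length=(5, 10),
    )
    other = phantom.CellClassSpec(
        name="other_glia",
        tau1=(0.4, 0.05), tau2=(3.0, 0.2), a1_pct=(68.0, 4.0),
        photons_per_pixel=photons,
        soma_radius=(3, 6), n_processes=(2, 3), process_length=(4, 8),
    )
    cfg = dict(
        shape=shape, classes=(microglia, other),
        n_cells=(n_microglia, n_other),
        background=phantom.BackgroundSpec(photons_per_pixel=photons / 6.0),
    )
    cfg.update(overrides)
    return phantom.PhantomConfig(**cfg)
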