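"""Bi-exponential TCSPC decay fitting with IRF convolution.

The photon-arrival histogram of a NAD(P)H pixel is modeled as the discrete
convolution of the instrument response function (IRF) with a two-component
exponential decay plus a constant background::

    m(t) = IRF * [ a1 exp(-t / tau1) + a2 exp(-t / tau2) ] + offset

sampled at bin centers, optionally shifted along the time axis by a sub-bin
amount to absorb detector/electronics timing drift.  The short component
``tau1`` tracks free NAD(P)H, the long component ``tau2`` the protein-bound
form, and the amplitude fraction ``a1/(a1+a2)`` the free:bound balance —
the metabolic signature the downstream classifier feeds on.

Fitting minimizes Poisson-weighted least squares,
``sum (y - m)^2 / max(y, 1)``, via a variable-projection
Levenberg–Marquardt scheme: for fixed lifetimes the amplitudes and offset
are a (non-negative) weighted linear subproblem, so the nonlinear search
runs over ``(log tau1, log tau2)`` only.  The same vectorized engine fits a
single decay or an entire field of view at once.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import scipy.fft
import scipy.ndimage
import scipy.optimize

from .tcspc_io import DecayCube, FitParamMaps, IRFVector, RunConfig

try:  # compiled per-pixel kernel; the numpy engine below is the fallback
    from ._kernel import fit_batch_kernel as _fit_batch_kernel
except ImportError:  # pragma: no cover - numba not installed
    _fit_batch_kernel = None

__all__ = [
    "FitParams",
    "FitOptions",
    "model_decay",
    "shift_curves",
    "spatial_bin",
    "fit_pixel",
    "fit_cube",
    "estimate_shift",
    "mean_lifetime",
]


@dataclasses.dataclass
class FitParams:
    """Parameters of the two-component decay model for one pixel.

    ``tau1 <= tau2`` is enforced after fitting (components are swapped if the
    optimizer converges the other way round).  ``chi2`` is the reduced
    chi-square of the weighted fit; ``converged`` is False when the
    Levenberg–Marquardt loop hit its iteration cap.
    """

    tau1: float
    tau2: float
    a1: float
    a2: float
    offset: float = 0.0
    shift: float = 0.0
    chi2: float = math.nan
    converged: bool = True

    def __post_init__(self):
        if not (self.tau1 > 0 and self.tau2 > 0):
            raise ValueError(f"lifetimes must be positive; got {self.tau1}, {self.tau2}")
        if self.a1 < 0 or self.a2 < 0:
            raise ValueError("amplitudes must be non-negative")

    @property
    def a1_pct(self) -> float:
        total = self.a1 + self.a2
        if total == 0:
            return math.nan
        return 100.0 * self.a1 / total

    @property
    def tau_m(self) -> float:
        return mean_lifetime(self.a1, self.tau1, self.a2, self.tau2)


@dataclasses.dataclass
class FitOptions:
    """Numerical knobs for the Levenberg–Marquardt fit."""

    max_iter: int = 200
    rel_tol: float = 1e-8
    init_tau: tuple[float, float] = (0.5, 2.5)
    #: below this tau2/tau1 ratio the two components are unidentifiable and
    #: the pixel is refit with a single exponential (a2 = 0).
    min_tau_ratio: float = 1.5
    #: estimate one per-acquisition shift from the pooled decay (fit_cube).
    estimate_shift: bool = True
    shift_bound: float = 3.0
    #: final pass with model-based (Pearson) weights to de-bias low counts.
    reweight: bool = True


def mean_lifetime(a1, tau1, a2, tau2):
    """Amplitude-weighted mean lifetime ``(a1 tau1 + a2 tau2) / (a1 + a2)``.

    Works element-wise on arrays.  Raises for a zero total amplitude when
    called with scalars.
    """
    a1 = np.asarray(a1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    total = a1 + a2
    if total.ndim == 0:
        if total == 0:
            raise ValueError("a1 + a2 must be positive")
        return float((a1 * tau1 + a2 * tau2) / total)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(total > 0, (a1 * np.asarray(tau1) + a2 * np.asarray(tau2)) / total, np.nan)


def shift_curves(values: np.ndarray, shift_bins: float, axis: int = -1) -> np.ndarray:
    """Shift histograms along the time axis by a (sub-bin) amount.

    Positive shifts move the curve toward later bins.  Linear interpolation
    on a circular domain; the total of each histogram is conserved exactly.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[axis]
    pos = (np.arange(n) - shift_bins) % n
    i0 = np.floor(pos).astype(int) % n
    frac = pos - np.floor(pos)
    i1 = (i0 + 1) % n
    lo = np.take(values, i0, axis=axis)
    hi = np.take(values, i1, axis=axis)
    shape = [1] * values.ndim
    shape[axis] = n
    frac = frac.reshape(shape)
    return (1.0 - frac) * lo + frac * hi


def _convolver(irf_values: np.ndarray, n_bins: int):
    """Return f(decays) computing the causal IRF convolution, truncated to n_bins."""
    nfft = scipy.fft.next_fast_len(2 * n_bins)
    irf_f = np.fft.rfft(irf_values, nfft)

    def conv(x: np.ndarray) -> np.ndarray:
        out = np.fft.irfft(np.fft.rfft(x, nfft, axis=-1) * irf_f, nfft, axis=-1)
        return out[..., :n_bins]

    return conv


def model_decay(params: FitParams, irf: IRFVector, n_bins: int | None = None,
                bin_width: float = 12.5 / 256) -> np.ndarray:
    """Expected counts per bin for one pixel under the two-component model."""
    if n_bins is None:
        n_bins = irf.n_bins
    if irf.n_bins != n_bins:
        raise ValueError(f"IRF length {irf.n_bins} != n_bins {n_bins}")
    t = (np.arange(n_bins) + 0.5) * bin_width
    decay = params.a1 * np.exp(-t / params.tau1) + params.a2 * np.exp(-t / params.tau2)
    conv = _convolver(irf.values, n_bins)
    curve = conv(decay)
    if params.shift != 0.0:
        curve = shift_curves(curve, params.shift)
    curve = curve + params.offset
    return np.maximum(curve, 0.0)


def spatial_bin(cube: DecayCube, radius: int) -> DecayCube:
    """Sum each pixel's histogram over its (2r+1)x(2r+1) neighborhood.

    Neighborhoods are truncated at image edges (outside pixels contribute
    zero).  ``radius=0`` returns the cube unchanged.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return cube
    size = 2 * radius + 1
    counts = cube.counts.astype(float)
    # uniform_filter with zero padding gives mean over the full window,
    # including out-of-image zeros, so mean * window area = truncated sum.
    summed = scipy.ndimage.uniform_filter(
        counts, size=(size, size, 1), mode="constant", cval=0.0
    ) * (size * size)
    summed = np.maximum(summed, 0.0)
    if np.issubdtype(cube.counts.dtype, np.integer):
        summed = np.rint(summed).astype(cube.counts.dtype)
    return DecayCube(counts=summed, bin_width=cube.bin_width,
                     pixel_size=cube.pixel_size, shift_bins=cube.shift_bins)


# ---------------------------------------------------------------------------
# vectorized variable-projection Levenberg–Marquardt
# ---------------------------------------------------------------------------


def _nnls_normal(G: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Solve batched normal equations G c = b with c >= 0.

    Negative components are pinned to zero and the reduced system re-solved;
    excluded coordinates are replaced by identity rows so one batched small
    solve handles every pixel per cleanup round.
    """
    k = G.shape[-1]
    c = np.linalg.solve(G, b[..., None])[..., 0]
    keep = np.ones_like(c, dtype=bool)
    for _ in range(k):
        neg = c < -1e-14 * np.abs(c).max()
        if not neg.any():
            break
        keep &= ~neg
        pair = keep[:, None, :] & keep[:, :, None]
        G_mod = np.where(pair, G, 0.0)
        diag = np.arange(k)
        G_mod[:, diag, diag] = np.where(keep, G[:, diag, diag], 1.0)
        c = np.linalg.solve(G_mod, (b * keep)[..., None])[..., 0]
    return np.maximum(c, 0.0)


def _exp_bases(tau: np.ndarray, irf_values: np.ndarray, t: np.ndarray,
               derivative: bool = True):
    """IRF-convolved exponential bases by exact linear recursion.

    For g[m] = exp(-t[m]/tau) on uniform bins, the causal discrete
    convolution P = irf (*) g obeys P[k] = z P[k-1] + g[0] irf[k] with
    z = exp(-dt/tau), so the whole basis costs O(T) per pixel with no FFT.
    The log-lifetime derivative basis conv(irf, (t/tau) g) follows from the
    companion recursion R driven by j*irf[j]:
    Q[k] = (dt/tau) ((k + 1/2) P[k] - R[k]).

    tau: (n, m) lifetimes.  Returns (P, Q) in time-major layout (m, T, n) —
    contiguous (n,) slabs per recursion step; Q is None when ``derivative``
    is False.
    """
    n, m = tau.shape
    T = t.size
    dt = t[1] - t[0]
    z = np.exp(-dt / tau)          # (n, m)
    g0 = np.exp(-t[0] / tau)       # g at the first bin center
    P = np.empty((m, T, n))
    R = np.empty((m, T, n)) if derivative else None
    for j in range(m):
        zj, gj = z[:, j], g0[:, j]
        Pj = P[j]
        Pj[0] = gj * irf_values[0]
        if derivative:
            Rj = R[j]
            Rj[0] = 0.0
            g_drive = gj[None, :] * (np.arange(T)[:, None] * irf_values[:, None])
            for k in range(1, T):
                np.multiply(zj, Pj[k - 1], out=Pj[k])
                Pj[k] += gj * irf_values[k]
                np.multiply(zj, Rj[k - 1], out=Rj[k])
                Rj[k] += g_drive[k]
        else:
            for k in range(1, T):
                np.multiply(zj, Pj[k - 1], out=Pj[k])
                Pj[k] += gj * irf_values[k]
    if not derivative:
        return P, None
    kk = (np.arange(T) + 0.5)[None, :, None]
    Q = (dt / tau.T)[:, None, :] * (kk * P - R)
    return P, Q


_U_LO, _U_HI = np.log(1e-3), np.log(50.0)


def _lm_core(Y: np.ndarray, w2: np.ndarray, t: np.ndarray, irf_values: np.ndarray,
             u0: np.ndarray, options: FitOptions, n_comp: int,
             xtol: float | None = None):
    """Damped Gauss–Newton over u = log(tau) with projected amplitudes.

    ``w2`` carries the Poisson weights with zeros marking excluded bins, so
    the fit window and per-pixel bin masks need no special casing.  Uses
    Kaufman's approximation to the variable-projection Jacobian, which here
    converges linearly with nearly parallel successive steps; an Aitken
    extrapolation (amplify the step by 1/(1 - lambda), lambda estimated from
    the projection of the current step on the previous one) recovers most of
    the lost quadratic behavior.  The working set shrinks as pixels converge.

    All heavy arrays are time-major (T, n): normal equations, gradients and
    Hessians are built by fused multiply-reduce passes, never materializing
    a per-pixel design matrix.

    Returns (u, c, cost, converged).
    """
    N, T = Y.shape
    if xtol is None:
        # lifetimes stable to 1e-4 relative are converged for any practical
        # purpose (statistical error is orders of magnitude larger)
        xtol = max(options.rel_tol, 1e-4)
    ncols = n_comp + 1

    def solve_linear(B, Yt, w2t):
        """Projected amplitudes + residual diagnostics for bases B (m,T,n)."""
        n = Yt.shape[1]
        G = np.empty((n, ncols, ncols))
        b = np.empty((n, ncols))
        for j in range(n_comp):
            tmp = w2t * B[j]
            for l in range(j, n_comp):
                G[:, j, l] = G[:, l, j] = (tmp * B[l]).sum(axis=0)
            G[:, j, ncols - 1] = G[:, ncols - 1, j] = tmp.sum(axis=0)
            b[:, j] = (tmp * Yt).sum(axis=0)
        G[:, ncols - 1, ncols - 1] = w2t.sum(axis=0)
        b[:, ncols - 1] = (w2t * Yt).sum(axis=0)
        G += 1e-12 * np.eye(ncols)
        c = _nnls_normal(G, b)
        model = c[:, ncols - 1] + B[0] * c[:, 0]
        for j in range(1, n_comp):
            model += B[j] * c[:, j]
        resid = Yt - model
        cost = (w2t * resid * resid).sum(axis=0)
        return c, resid, cost

    def eval_light(u, Yt, w2t):
        B, _ = _exp_bases(np.exp(u), irf_values, t, derivative=False)
        return solve_linear(B, Yt, w2t)

    Yt_full = np.ascontiguousarray(Y.T)
    w2t_full = np.ascontiguousarray(w2.T)

    u = np.array(u0, dtype=float)
    c, _, cost = eval_light(u, Yt_full, w2t_full)
    mu = np.full(N, 1e-3)
    converged = np.zeros(N, dtype=bool)
    active = np.arange(N)
    prev_step = np.zeros((N, n_comp))
    eye = np.eye(n_comp)

    for _ in range(options.max_iter):
        if active.size == 0:
            break
        Yt = np.ascontiguousarray(Yt_full[:, active])
        w2t = np.ascontiguousarray(w2t_full[:, active])
        B, dB = _exp_bases(np.exp(u[active]), irf_values, t)
        ca, resid, cost_a = solve_linear(B, Yt, w2t)
        c[active] = ca
        cost[active] = cost_a

        # Kaufman Jacobian reductions: g_k = -c_k sum w2 r dB_k,
        # H_kl = c_k c_l sum w2 dB_k dB_l
        wres = w2t * resid
        g = np.empty((active.size, n_comp))
        H = np.empty((active.size, n_comp, n_comp))
        for j in range(n_comp):
            g[:, j] = -ca[:, j] * (wres * dB[j]).sum(axis=0)
            tmp = w2t * dB[j]
            for l in range(j, n_comp):
                H[:, j, l] = H[:, l, j] = \
                    ca[:, j] * ca[:, l] * (tmp * dB[l]).sum(axis=0)
        step = -np.linalg.solve(H + mu[active, None, None] * eye, g[..., None])[..., 0]
        step = np.clip(step, -1.0, 1.0)  # trust region in log-tau

        # Aitken boost: geometric step decay means the fixed point lies at
        # roughly step / (1 - lambda) ahead
        ps = prev_step[active]
        den = (ps * ps).sum(axis=1)
        lam = np.where(den > 0, (step * ps).sum(axis=1) / np.maximum(den, 1e-300), 0.0)
        boost = 1.0 / (1.0 - np.clip(lam, 0.0, 0.93))
        step_b = step * boost[:, None]

        u_try = np.clip(u[active] + step_b, _U_LO, _U_HI)
        _, _, cost_t = eval_light(u_try, Yt, w2t)
        better = cost_t <= cost_a
        if not better.all():
            # boosted step overshot for some pixels: retry those unboosted
            f = np.nonzero(~better)[0]
            u_try2 = np.clip(u[active[f]] + step[f], _U_LO, _U_HI)
            _, _, cost2 = eval_light(
                u_try2, np.ascontiguousarray(Yt[:, f]),
                np.ascontiguousarray(w2t[:, f]))
            u_try[f] = u_try2
            cost_t[f] = cost2
            step_b[f] = step[f]
            better[f] = cost2 <= cost_a[f]

        rel = (cost_a - cost_t) / np.maximum(cost_a, 1e-300)
        tiny_step = np.abs(step).max(axis=1) < xtol

        acc = active[better]
        u[acc] = u_try[better]
        cost[acc] = cost_t[better]
        mu[acc] = np.maximum(mu[acc] / 3.0, 1e-10)
        prev_step[acc] = step_b[better]
        rej = active[~better]
        mu[rej] = mu[rej] * 4.0
        prev_step[rej] = 0.0

        done = tiny_step | (better & (rel < options.rel_tol)) | (mu[active] > 1e8)
        ok = tiny_step | (better & (rel < options.rel_tol))
        converged[active[done & ok]] = True
        active = active[~done]

    # final amplitudes consistent with the final lifetimes
    c_fin, _, cost_fin = eval_light(u, Yt_full, w2t_full)
    return u, c_fin, cost_fin, converged


def _fit_batch(Y: np.ndarray, irf_values: np.ndarray, bin_width: float,
               options: FitOptions, single: bool = False) -> dict[str, np.ndarray]:
    """Fit N decays (rows of Y) at once; returns per-pixel parameter arrays.

    Two passes: the first fits all bins from just before the IRF rise;
    the second re-fits with bins beyond the last ~1 expected count removed
    (per pixel, judged from the first-pass model).  Dropping the empty tail
    matters because the Poisson weights ``1/max(y, 1)`` over-weight
    zero-count bins and would otherwise bias the long lifetime low.

    Dispatches to the compiled per-pixel kernel when numba is available;
    the vectorized numpy path below implements the identical algorithm.
    """
    Y = np.asarray(Y, dtype=float)
    if _fit_batch_kernel is not None and not single:
        t0 = 0.5 * bin_width
        tau1, tau2, a1, a2, offset, chi2, _, conv = _fit_batch_kernel(
            np.ascontiguousarray(Y), np.ascontiguousarray(irf_values, dtype=float),
            t0, bin_width, options.init_tau[0], options.init_tau[1],
            options.max_iter, options.rel_tol, options.reweight,
            options.min_tau_ratio)
        return {"tau1": tau1, "tau2": tau2, "a1": a1, "a2": a2,
                "offset": offset, "chi2": chi2, "converged": conv}
    N, T = Y.shape
    t = (np.arange(T) + 0.5) * bin_width

    def model_of(u_, c_):
        B, _ = _exp_bases(np.exp(u_), irf_values, t, derivative=False)
        model = np.full(B.shape[1:], 0.0) + c_[:, n_comp]
        for j in range(n_comp):
            model += B[j] * c_[:, j]
        return np.ascontiguousarray(model.T)

    mode = int(np.argmax(irf_values))
    start = max(0, mode - 2)
    w2 = 1.0 / np.maximum(Y, 1.0)  # Poisson weights (1/variance)
    w2[:, :start] = 0.0

    n_comp = 1 if single else 2
    if single:
        u0 = np.full((N, 1), np.log(math.sqrt(options.init_tau[0] * options.init_tau[1])))
    else:
        u0 = np.tile(np.log(np.asarray(options.init_tau)), (N, 1))

    # pass 1: coarse fit with data-based weights over the full tail
    coarse = dataclasses.replace(options, max_iter=min(options.max_iter, 80))
    u, c, cost, converged = _lm_core(Y, w2, t, irf_values, u0, coarse, n_comp,
                                     xtol=max(options.rel_tol, 3e-4))

    # per-pixel fit window: keep bins up to the last one with >= 1 expected
    # count (from the first-pass model; at least 32 bins past the start)
    model = model_of(u, c)
    big = model >= 1.0
    big[:, :start] = False
    any_big = big.any(axis=1)
    last = np.where(any_big, T - 1 - np.argmax(big[:, ::-1], axis=1), T - 1)
    last = np.maximum(last, min(start + 32, T - 1))
    keep = np.arange(T)[None, :] <= last[:, None]
    w2 = w2 * keep

    # pass 2: polish on the trimmed window.  With model-based (Pearson)
    # weights: data-based weights over-weight downward count fluctuations
    # and bias lifetimes low at modest photon budgets.
    if options.reweight:
        w2p = np.where(w2 > 0, 1.0 / np.maximum(model, 1.0), 0.0)
    else:
        w2p = w2
    u, c, cost, converged = _lm_core(Y, w2p, t, irf_values, u, options, n_comp)

    # reduced chi-square reported with the conventional data-based weights
    tau = np.exp(u)
    resid2 = (Y - model_of(u, c)) ** 2 / np.maximum(Y, 1.0)
    n_free = 2 * n_comp + 1  # lifetimes + amplitudes + offset
    n_bins_used = (w2 > 0).sum(axis=1)
    chi2 = (resid2 * (w2 > 0)).sum(axis=1) / np.maximum(n_bins_used - n_free, 1)
    if single:
        return {
            "tau1": tau[:, 0], "tau2": tau[:, 0],
            "a1": c[:, 0], "a2": np.zeros(N),
            "offset": c[:, 1], "chi2": chi2, "converged": converged,
        }

    tau1, tau2 = tau[:, 0], tau[:, 1]
    a1, a2 = c[:, 0], c[:, 1]
    swap = tau1 > tau2
    result = {
        "tau1": np.where(swap, tau2, tau1), "tau2": np.where(swap, tau1, tau2),
        "a1": np.where(swap, a2, a1), "a2": np.where(swap, a1, a2),
        "offset": c[:, 2], "chi2": chi2, "converged": converged,
    }

    # identifiability guard: near-equal lifetimes collapse to one component
    with np.errstate(invalid="ignore", divide="ignore"):
        degenerate = (result["tau2"] / np.maximum(result["tau1"], 1e-12)) \
            < options.min_tau_ratio
    if np.any(degenerate):
        mono = _fit_batch(Y[degenerate], irf_values, bin_width, options, single=True)
        idx = np.nonzero(degenerate)[0]
        for key in ("tau1", "tau2", "a1", "a2", "offset", "chi2", "converged"):
            result[key] = np.asarray(result[key])
            result[key][idx] = mono[key]
    return result


def _pooled_shift_objective(pooled: np.ndarray, irf: IRFVector, bin_width: float,
                            options: FitOptions):
    small = dataclasses.replace(options, max_iter=60)

    def objective(shift: float) -> float:
        irf_s = shift_curves(irf.values, shift)
        res = _fit_batch(pooled[None, :], irf_s, bin_width, small)
        return float(res["chi2"][0])

    return objective


def estimate_shift(decay: np.ndarray, irf: IRFVector, bin_width: float,
                   options: FitOptions | None = None) -> float:
    """Estimate the acquisition decay shift (in bins) from a pooled decay.

    Scans the bounded shift range, minimizing the fit chi-square of the
    pooled histogram; refined with a bounded scalar search.
    """
    options = options or FitOptions()
    obj = _pooled_shift_objective(np.asarray(decay, dtype=float), irf, bin_width, options)
    bound = options.shift_bound
    coarse = np.linspace(-bound, bound, 13)
    vals = [obj(s) for s in coarse]
    k = int(np.argmin(vals))
    lo = coarse[max(0, k - 1)]
    hi = coarse[min(len(coarse) - 1, k + 1)]
    res = scipy.optimize.minimize_scalar(obj, bounds=(lo, hi), method="bounded",
                                         options={"xatol": 1e-3})
    return float(res.x)


def _params_from_row(res: dict[str, np.ndarray], i: int, shift: float) -> FitParams:
    return FitParams(
        tau1=float(res["tau1"][i]), tau2=float(res["tau2"][i]),
        a1=float(res["a1"][i]), a2=float(res["a2"][i]),
        offset=float(res["offset"][i]), shift=shift,
        chi2=float(res["chi2"][i]), converged=bool(res["converged"][i]),
    )


def fit_pixel(decay: np.ndarray, irf: IRFVector, init: FitParams | None = None,
              options: FitOptions | None = None, bin_width: float = 12.5 / 256,
              fit_shift: bool = False) -> FitParams:
    """Fit one decay histogram; returns FitParams with a convergence flag.

    ``fit_shift=True`` additionally optimizes the sub-bin time shift
    (bounded to ±``options.shift_bound`` bins) as a nuisance parameter.
    """
    decay = np.asarray(decay, dtype=float)
    if decay.ndim != 1:
        raise ValueError("decay must be a 1-D histogram")
    if decay.sum() <= 0:
        raise ValueError("cannot fit an all-zero decay")
    options = options or FitOptions()
    if init is not None:
        options = dataclasses.replace(options, init_tau=(init.tau1, init.tau2))
    shift = 0.0
    irf_use = irf
    if fit_shift:
        shift = estimate_shift(decay, irf, bin_width, options)
        irf_use = IRFVector(shift_curves(irf.values, shift))
    res = _fit_batch(decay[None, :], irf_use.values, bin_width, options)
    return _params_from_row(res, 0, shift)


def fit_cube(cube: DecayCube, irf: IRFVector, config: RunConfig | None = None,
             options: FitOptions | None = None) -> FitParamMaps:
    """Fit every pixel above the photon threshold; returns the seven maps.

    Pixels are spatially binned (``config.bin_radius``) before fitting; the
    photon threshold is applied to each pixel's own (unbinned) total count.
    When ``options.estimate_shift`` is set, one per-acquisition shift is
    estimated from the pooled decay of all valid pixels and folded into the
    IRF before the per-pixel fits.
    """
    config = config or RunConfig()
    options = options or FitOptions()
    if irf.n_bins != cube.n_bins:
        raise ValueError(f"IRF length {irf.n_bins} != cube bins {cube.n_bins}")

    valid = cube.total_counts >= config.photon_threshold
    shape = cube.shape
    nan_map = np.full(shape, np.nan)
    maps = {name: nan_map.copy() for name in
            ("t1", "t2", "tm", "a1", "a2", "a1pct", "chi2")}
    if not np.any(valid):
        return FitParamMaps(**maps, valid=valid)

    binned = spatial_bin(cube, config.bin_radius)
    Y = binned.counts[valid].astype(float)

    shift = 0.0
    irf_use = irf
    if options.estimate_shift:
        pooled = Y.sum(axis=0)
        shift = estimate_shift(pooled, irf, cube.bin_width, options)
        if abs(shift) > 1e-3:
            irf_use = IRFVector(shift_curves(irf.values, shift))

    res = _fit_batch(Y, irf_use.values, cube.bin_width, options)
    total = res["a1"] + res["a2"]
    with np.errstate(invalid="ignore", divide="ignore"):
        a1pct = np.where(total > 0, 100.0 * res["a1"] / total, np.nan)
    tm = mean_lifetime(res["a1"], res["tau1"], res["a2"], res["tau2"])
    values = {"t1": res["tau1"], "t2": res["tau2"], "tm": tm,
              "a1": res["a1"], "a2": res["a2"], "a1pct": a1pct, "chi2": res["chi2"]}
    for name, vec in values.items():
        maps[name][valid] = vec
    return FitParamMaps(**maps, valid=valid)
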