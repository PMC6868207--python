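"""Weighted histogram analysis method (WHAM) for umbrella-sampling data.

Given per-window biased histograms n_i(z_b) with harmonic biases
w_i(z) = k_i/2 (z - z_i)^2, WHAM solves the self-consistent equations

    p(z_b) ∝ Σ_i n_i(z_b) / Σ_i N_i exp[(f_i - w_i(z_b)) / k_B T]
    exp(-f_i / k_B T) = Σ_b p(z_b) exp(-w_i(z_b) / k_B T)

by direct iteration, and reports the potential of mean force
ΔG(z) = -k_B T ln p(z), zeroed on average over a bulk reference region.
Unsampled bins are *gaps* (NaN), never zeros.  Uncertainty bands come from
a moving-block bootstrap within each window (umbrella samples are strongly
autocorrelated, so an iid bootstrap would be badly overconfident).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_TEMPERATURE, kbt
from .diffusion import integrated_correlation_time
from .dynamics import UmbrellaWindow
from .errors import ConvergenceError, ValidationError
from .profiles import PMFProfile

__all__ = [
    "BiasedHistogram",
    "build_histograms",
    "wham_solve",
    "bootstrap_pmf",
    "barrier_height",
    "peak_position",
    "compare_barriers",
    "RelativeBarrier",
]

DEFAULT_BIN_WIDTH = 0.05      # nm; histogram resolution of the PMF grid
DEFAULT_TOL = 1e-6            # kJ/mol on the window free energies f_i
DEFAULT_MAX_ITER = 100_000
DEFAULT_BULK_FRACTION = 0.9   # |z| >= fraction * outermost window centre = bulk reference


@dataclass
class BiasedHistogram:
    """Binned samples of one umbrella window on the common PMF grid."""

    edges: np.ndarray             # uniform bin edges (nm), shared across windows
    counts: np.ndarray            # integer counts per bin
    center: float                 # bias centre z_i (nm)
    force_constant: float         # k_i (kJ mol^-1 nm^-2); 0 = unbiased
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.edges.ndim != 1 or self.edges.size != self.counts.size + 1:
            raise ValidationError("edges must have one more element than counts")
        if not np.all(np.diff(self.edges) > 0):
            raise ValidationError("bin edges must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def build_histograms(windows: list[UmbrellaWindow], bin_width: float = DEFAULT_BIN_WIDTH,
                     edges: np.ndarray | None = None) -> list[BiasedHistogram]:
    """Bin all windows onto one common uniform grid.

    The grid spans all samples, aligned to multiples of ``bin_width``.  A
    fixed ``edges`` array can be supplied instead (used by the bootstrap so
    replicates share the base grid).  Warns when an adjacent window pair
    shares fewer than 3 occupied bins.
    """
    if not windows:
        raise ValidationError("no windows given")
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    temps = {w.temperature for w in windows}
    if len(temps) > 1:
        raise ValidationError(f"windows mix temperatures: {sorted(temps)}")
    for i, w in enumerate(windows):
        if w.samples.size == 0:
            raise ValidationError(f"window {i} (center {w.center:g}) is empty")
    if edges is None:
        lo = min(w.samples.min() for w in windows)
        hi = max(w.samples.max() for w in windows)
        first = math.floor(lo / bin_width) * bin_width
        n_bins = max(1, math.ceil((hi - first) / bin_width + 1e-9))
        edges = first + bin_width * np.arange(n_bins + 1)
    hists = [
        BiasedHistogram(
            edges=edges,
            counts=np.histogram(w.samples, bins=edges)[0],
            center=w.center,
            force_constant=w.force_constant,
            temperature=w.temperature,
        )
        for w in windows
    ]
    order = np.argsort([h.center for h in hists])
    for a, b in zip(order[:-1], order[1:]):
        shared = np.sum((hists[a].counts > 0) & (hists[b].counts > 0))
        if shared < 3:
            warnings.warn(
                f"windows at {hists[a].center:g} and {hists[b].center:g} nm share only "
                f"{shared} occupied bins; the PMF may be poorly connected there",
                stacklevel=2,
            )
    return hists


def _connected_components(occupied: np.ndarray) -> list[list[int]]:
    """Components of the window graph; windows touch if they share an occupied bin."""
    n = occupied.shape[0]
    seen = np.zeros(n, dtype=bool)
    comps = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            i = stack.pop()
            comp.append(i)
            overlap = (occupied & occupied[i]).any(axis=1)
            for j in np.nonzero(overlap & ~seen)[0]:
                seen[j] = True
                stack.append(int(j))
        comps.append(sorted(comp))
    return comps


def wham_solve(histograms: list[BiasedHistogram], temperature: float | None = None,
               tol: float = DEFAULT_TOL, max_iter: int = DEFAULT_MAX_ITER,
               bulk_fraction: float = DEFAULT_BULK_FRACTION,
               f_init: np.ndarray | None = None) -> PMFProfile:
    """Solve the WHAM equations and return the PMF profile.

    Iterates until the largest change in any window free energy f_i falls
    below ``tol`` (kJ/mol); raises :class:`ConvergenceError` (with the final
    residual) after ``max_iter`` iterations.  The PMF is shifted so its
    count-weighted mean over the bulk reference region — sampled bins with
    |z| >= ``bulk_fraction`` times the outermost window centre — is zero.
    A single window with k = 0 reduces exactly to Boltzmann inversion of its
    histogram.
    """
    if not histograms:
        raise ValidationError("no histograms given")
    if tol <= 0:
        raise ValidationError("tol must be positive")
    edges = histograms[0].edges
    for h in histograms[1:]:
        if h.edges.shape != edges.shape or not np.allclose(h.edges, edges):
            raise ValidationError("histograms must share one common grid")
    if temperature is None:
        temperature = histograms[0].temperature
    kt = kbt(temperature)

    z = histograms[0].centers
    counts = np.array([h.counts for h in histograms], dtype=float)   # (n_win, n_bins)
    n_tot = counts.sum(axis=0)
    n_i = counts.sum(axis=1)
    occupied_any = n_tot > 0
    if not occupied_any.any():
        raise ValidationError("all histograms are empty")

    comps = _connected_components(counts > 0)
    if len(comps) > 1:
        raise ValidationError(
            "umbrella windows do not form a connected overlap graph; components "
            f"(by window index): {comps}"
        )

    centers_i = np.array([h.center for h in histograms])
    ks = np.array([h.force_constant for h in histograms])
    # bias energies w_ib and their (always <= 1) Boltzmann factors
    w = 0.5 * ks[:, None] * (z[None, :] - centers_i[:, None]) ** 2
    expu = np.exp(-w / kt)

    g = np.zeros(len(histograms)) if f_init is None else np.asarray(f_init, float) / kt
    g = g - g[0]
    residual = np.inf
    for iteration in range(1, max_iter + 1):
        denom = (n_i * np.exp(g)) @ expu                  # (n_bins,)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(occupied_any, n_tot / denom, 0.0)
        s = expu @ p                                       # (n_win,)
        g_new = -np.log(s)
        g_new -= g_new[0]
        residual = float(np.max(np.abs(g_new - g)) * kt)
        g = g_new
        if residual < tol:
            break
    else:
        raise ConvergenceError(
            f"WHAM did not converge in {max_iter} iterations (residual {residual:.3g} kJ/mol)",
            residual=residual,
        )

    with np.errstate(divide="ignore"):
        dg = np.where(occupied_any, -kt * np.log(np.where(occupied_any, p, 1.0)), np.nan)
    # Bulk reference: outermost sampled region.  The scale is taken from the
    # outermost window *centres* (well-populated by construction) rather than
    # the raw sampled extent, and the mean is count-weighted — bins in the
    # extreme tails carry few counts and a positive -kT ln(p) bias that would
    # otherwise shift the whole profile.
    z_extent = np.max(np.abs(z[occupied_any]))
    center_scale = float(np.max(np.abs(centers_i)))
    scale = center_scale if center_scale > 0 else z_extent
    ref = occupied_any & (np.abs(z) >= bulk_fraction * scale)
    if not ref.any():
        ref = occupied_any & (np.abs(z) >= bulk_fraction * z_extent)
    if not ref.any():
        raise ValidationError(
            "no sampled bins inside the bulk reference region "
            f"|z| >= {bulk_fraction:g} * max|z|; widen sampling or lower bulk_fraction"
        )
    dg -= float(np.average(dg[ref], weights=n_tot[ref]))

    return PMFProfile(
        z, dg,
        meta={
            "kind": "pmf",
            "units": "kJ/mol",
            "temperature_K": temperature,
            "bin_width_nm": float(edges[1] - edges[0]),
            "tol_kJ_mol": tol,
            "iterations": iteration,
            "residual_kJ_mol": residual,
            "reference_region": f"|z| >= {bulk_fraction:g} * sampled extent (mean set to zero)",
            "bulk_fraction": bulk_fraction,
            "n_gaps": int((~occupied_any).sum()),
            "window_free_energies_kJ_mol": (g * kt).tolist(),
            "edges_first_last": (float(edges[0]), float(edges[-1])),
        },
    )


# ---------------------------------------------------------------------------
# Bootstrap uncertainty
# ---------------------------------------------------------------------------

def moving_block_resample(x: np.ndarray, block_length: int, rng: np.random.Generator) -> np.ndarray:
    """Moving-block bootstrap resample of a series, same length as the input."""
    n = x.size
    if block_length >= n:
        raise ValidationError(f"block_length {block_length} must be < window length {n}")
    if block_length < 1:
        raise ValidationError("block_length must be >= 1")
    n_blocks = math.ceil(n / block_length)
    starts = rng.integers(0, n - block_length + 1, size=n_blocks)
    out = np.concatenate([x[s:s + block_length] for s in starts])
    return out[:n]


def estimate_block_length(window: UmbrellaWindow, factor: float = 5.0) -> int:
    """Default bootstrap block length: ``factor`` x the integrated correlation time."""
    tau_steps = integrated_correlation_time(window.samples) / 1.0  # in samples (dt=1)
    block = int(math.ceil(factor * max(tau_steps, 1.0)))
    return min(block, max(window.samples.size - 1, 1))


def bootstrap_pmf(windows: list[UmbrellaWindow], n_boot: int = 32,
                  block_length: int | None = None, seed: int = 0,
                  bin_width: float = DEFAULT_BIN_WIDTH, tol: float = DEFAULT_TOL,
                  max_iter: int = DEFAULT_MAX_ITER,
                  bulk_fraction: float = DEFAULT_BULK_FRACTION) -> PMFProfile:
    """WHAM point estimate with moving-block-bootstrap error bands.

    Each replicate resamples every window in blocks (default block length:
    5x that window's integrated autocorrelation time), re-bins on the base
    grid and re-solves WHAM warm-started from the base solution.  ``sigma``
    is the per-bin standard deviation of ΔG across replicates; bins defined
    in fewer than half the replicates keep sigma = NaN.  Fully deterministic
    given ``seed``.
    """
    if n_boot < 2:
        raise ValidationError("n_boot must be >= 2")
    base_h = build_histograms(windows, bin_width=bin_width)
    base = wham_solve(base_h, tol=tol, max_iter=max_iter, bulk_fraction=bulk_fraction)
    edges = base_h[0].edges
    f0 = np.array(base.meta["window_free_energies_kJ_mol"])

    blocks = [
        block_length if block_length is not None else estimate_block_length(w)
        for w in windows
    ]
    for b, w in zip(blocks, windows):
        if b >= w.samples.size:
            raise ValidationError(
                f"block_length {b} must be smaller than the window length {w.samples.size}"
            )

    rng = np.random.default_rng(seed)
    replicate_dg = np.full((n_boot, base.z.size), np.nan)
    for r in range(n_boot):
        rep_windows = []
        for w, b in zip(windows, blocks):
            res = moving_block_resample(w.samples, b, rng)
            rep_windows.append(
                UmbrellaWindow(w.center, w.force_constant, w.dt, res, w.temperature)
            )
        rep_h = build_histograms(rep_windows, bin_width=bin_width, edges=edges)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = wham_solve(rep_h, tol=tol, max_iter=max_iter,
                             bulk_fraction=bulk_fraction, f_init=f0)
        replicate_dg[r] = rep.values

    n_def = np.sum(np.isfinite(replicate_dg), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sigma = np.nanstd(replicate_dg, axis=0, ddof=1)
    sigma[n_def < max(2, n_boot // 2)] = np.nan

    out = PMFProfile(base.z, base.values, sigma=sigma, meta=dict(base.meta))
    out.meta.update(
        n_boot=n_boot, block_lengths=blocks, bootstrap_seed=seed,
        bootstrap="moving-block within each window, paired re-binning on the base grid",
    )
    return out


# ---------------------------------------------------------------------------
# Barrier analytics
# ---------------------------------------------------------------------------

def barrier_height(pmf: PMFProfile) -> float:
    """Maximal barrier height (kJ/mol) above the (zero) bulk reference."""
    if "reference_region" not in pmf.meta and "bulk_fraction" not in pmf.meta:
        warnings.warn("PMF carries no declared bulk reference; assuming it is zeroed in bulk",
                      stacklevel=2)
    finite = np.isfinite(pmf.values)
    if not finite.any():
        raise ValidationError("profile is all gaps; no barrier to measure")
    return float(np.max(pmf.values[finite]))


def _moving_average(v: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return v.copy()
    kernel = np.ones(window) / window
    filled = np.where(np.isfinite(v), v, 0.0)
    weight = np.convolve(np.isfinite(v).astype(float), kernel, mode="same")
    smooth = np.convolve(filled, kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = smooth / weight
    out[weight < 1e-12] = np.nan
    return out


def peak_position(pmf: PMFProfile, smooth_window: int = 3,
                  ambiguity_margin: float | None = None) -> float:
    """Position (nm) of the PMF peak: global max of the smoothed profile.

    The profile is smoothed with a centred moving average of ``smooth_window``
    bins.  If several local maxima compete within ``ambiguity_margin`` of the
    global maximum (default: 5% of the smoothed peak-to-trough range) the
    result is flagged ambiguous via a warning and tie-broken to the candidate
    closest to z = 0.
    """
    sm = _moving_average(pmf.values, smooth_window)
    finite = np.isfinite(sm)
    if finite.sum() < 3:
        raise ValidationError("not enough defined bins to locate a peak")
    vmax = np.nanmax(sm)
    if ambiguity_margin is None:
        ambiguity_margin = 0.05 * float(vmax - np.nanmin(sm))
    # local maxima of the smoothed profile (plateau-tolerant)
    idx = np.nonzero(finite)[0]
    v = sm[idx]
    is_locmax = np.ones(idx.size, dtype=bool)
    is_locmax[1:] &= v[1:] >= v[:-1]
    is_locmax[:-1] &= v[:-1] >= v[1:]
    cand = idx[is_locmax & (v >= vmax - max(ambiguity_margin, 1e-12))]
    top = idx[is_locmax & (v >= vmax - 1e-12)]
    if cand.size > 1 and (cand.size > top.size or top.size > 1):
        warnings.warn(
            f"peak position is ambiguous: {cand.size} competing maxima within "
            f"{ambiguity_margin:.3g} kJ/mol; tie-broken toward z = 0",
            stacklevel=2,
        )
        pick = cand[np.argmin(np.abs(pmf.z[cand]))]
    else:
        pick = top[np.argmin(np.abs(pmf.z[top]))]
    return float(pmf.z[pick])


@dataclass(frozen=True)
class RelativeBarrier:
    """Curved/flat barrier ratio, with the table-rounded rendering."""

    value: float       # unrounded ratio
    rounded: float     # half-even rounded to `decimals`
    decimals: int = 2

    def __str__(self) -> str:
        return f"{self.rounded:.{self.decimals}f}"


def compare_barriers(flat, curved, decimals: int = 2) -> RelativeBarrier:
    """Relative barrier height curved/flat (dimensionless).

    Inputs may be barrier heights in kJ/mol or :class:`PMFProfile` objects
    (then :func:`barrier_height` is applied).  The rounded field uses
    banker's (half-even) rounding at ``decimals`` places, the convention for
    tabulated relative heights; the unrounded value is always retained.
    """
    flat_v = barrier_height(flat) if isinstance(flat, PMFProfile) else float(flat)
    curved_v = barrier_height(curved) if isinstance(curved, PMFProfile) else float(curved)
    if flat_v <= 0:
        raise ValidationError(f"flat barrier must be positive, got {flat_v:g}")
    ratio = curved_v / flat_v
    return RelativeBarrier(value=ratio, rounded=round(ratio, decimals), decimals=decimals)
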