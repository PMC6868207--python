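"""Overdamped Brownian dynamics on membrane landscapes.

The integrator is Euler–Maruyama in the Ito convention with the spurious
drift dD/dz included, so that for a time step small compared with all local
relaxation times the stationary density converges to the Boltzmann density
exp(-(G + bias)/k_B T).  Boundaries at ±box_half_width are reflective and
reflection events are counted.

An umbrella window is a trajectory under an additional harmonic bias
k/2 (z - z_i)^2; :func:`generate_umbrella_dataset` produces a full set of
windows with deterministically derived per-window seeds, which is the
synthetic stand-in for an umbrella-sampling MD campaign.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .constants import DEFAULT_TEMPERATURE
from .errors import ValidationError
from .membrane import MembraneModel, TabulatedModel

__all__ = ["UmbrellaWindow", "brownian_dynamics", "generate_umbrella_dataset"]

logger = logging.getLogger(__name__)

_EMPTY = np.empty(0, dtype=np.float64)


@dataclass
class UmbrellaWindow:
    """One biased trajectory: harmonic restraint centre, stiffness and samples."""

    center: float                 # bias centre z_i (nm)
    force_constant: float         # k_i (kJ mol^-1 nm^-2); 0 means unbiased
    dt: float                     # sampling interval (ns)
    samples: np.ndarray           # reaction-coordinate series z(t) (nm)
    temperature: float = DEFAULT_TEMPERATURE
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.force_constant < 0:
            raise ValidationError("force_constant must be >= 0")
        if self.dt <= 0:
            raise ValidationError("dt must be positive")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValidationError("a window needs at least two samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("window samples must all be finite")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)


@njit(cache=True)
def _em_loop(z0, n_total, n_equil, save_every, dt, normals,
             gauss_amp, gauss_mu, gauss_sig2, quad_kappa, ramp_slope,
             table_z0, table_dz, table_grad,
             d_bulk, d_mem, d_center, d_width,
             bias_k, bias_center, kbt, l_box, out):
    z = z0
    n_reflect = 0
    idx = 0
    sqrt2dt = math.sqrt(2.0 * dt)
    for i in range(n_total):
        # deterministic force -dG_tot/dz (kJ mol^-1 nm^-1)
        f = -quad_kappa * z + ramp_slope - bias_k * (z - bias_center)
        for j in range(gauss_amp.size):
            dzj = z - gauss_mu[j]
            f += gauss_amp[j] * dzj / gauss_sig2[j] * math.exp(-0.5 * dzj * dzj / gauss_sig2[j])
        if table_grad.size > 0:
            x = (z - table_z0) / table_dz
            k0 = int(math.floor(x))
            if k0 < 0:
                k0 = 0
            elif k0 > table_grad.size - 2:
                k0 = table_grad.size - 2
            w = x - k0
            if w < 0.0:
                w = 0.0
            elif w > 1.0:
                w = 1.0
            f -= table_grad[k0] * (1.0 - w) + table_grad[k0 + 1] * w
        # diffusivity and its gradient (Ito spurious drift)
        s1 = 1.0 / (1.0 + math.exp(-(z + d_center) / d_width))
        s2 = 1.0 / (1.0 + math.exp(-(d_center - z) / d_width))
        d = d_bulk + (d_mem - d_bulk) * s1 * s2
        dp = (d_mem - d_bulk) * (s1 * (1.0 - s1) * s2 - s1 * s2 * (1.0 - s2)) / d_width
        z = z + (d * f / kbt + dp) * dt + math.sqrt(d) * sqrt2dt * normals[i]
        while z > l_box or z < -l_box:
            if z > l_box:
                z = 2.0 * l_box - z
            else:
                z = -2.0 * l_box - z
            n_reflect += 1
        if i >= n_equil and (i - n_equil) % save_every == 0:
            out[idx] = z
            idx += 1
    return n_reflect


def _kernel_params(model) -> dict:
    if isinstance(model, MembraneModel):
        amps, mus, sig2 = model.gaussian_terms()
        slope, _ = model._bulk_ramp
        return dict(
            gauss_amp=amps, gauss_mu=mus, gauss_sig2=sig2,
            quad_kappa=model.quadratic_kappa, ramp_slope=slope,
            table_z0=0.0, table_dz=1.0, table_grad=_EMPTY,
        )
    if isinstance(model, TabulatedModel):
        zt = model.z_table
        dz = np.diff(zt)
        if not np.allclose(dz, dz[0], rtol=1e-9):
            raise ValidationError("TabulatedModel requires a uniform z_table for dynamics")
        grad = np.ascontiguousarray(np.gradient(model.g_table, zt))
        return dict(
            gauss_amp=_EMPTY, gauss_mu=_EMPTY, gauss_sig2=_EMPTY,
            quad_kappa=0.0, ramp_slope=0.0,
            table_z0=float(zt[0]), table_dz=float(dz[0]), table_grad=grad,
        )
    raise ValidationError(f"unsupported model type {type(model).__name__}")


def brownian_dynamics(model, *, z0: float, n_steps: int, dt: float, seed: int,
                      bias: tuple[float, float] | None = None, n_equil: int = 0,
                      save_every: int = 1, return_info: bool = False):
    """Simulate an overdamped trajectory on ``model``; returns the sample series.

    Parameters
    ----------
    model:
        :class:`MembraneModel` or :class:`TabulatedModel` ground truth.
    bias:
        Optional harmonic restraint ``(center_nm, k)`` with k in
        kJ mol^-1 nm^-2 added to the landscape.
    z0, n_steps, dt, seed:
        Start position (nm), number of recorded steps (after discarding
        ``n_equil``), time step (ns) and RNG seed.  The trajectory is fully
        deterministic given the seed.
    save_every:
        Record every ``save_every``-th step (the effective sampling interval
        is ``dt * save_every``).
    return_info:
        Also return a dict with the reflection count and effective dt.

    Notes
    -----
    The update is z' = z + [-D(z) G_tot'(z)/k_B T + D'(z)] dt
    + sqrt(2 D(z) dt) eta with eta ~ N(0,1); its stationary density tends to
    exp(-G_tot/k_B T) as dt -> 0.  A warning is emitted when
    D_max * dt is not small compared with the squared barrier width.
    """
    if dt <= 0:
        raise ValidationError("dt must be positive")
    if n_steps < 1 or n_equil < 0 or save_every < 1:
        raise ValidationError("n_steps >= 1, n_equil >= 0, save_every >= 1 required")
    d_max = max(model.d_bulk, model.d_mem)
    width2 = (model.peak_width if isinstance(model, MembraneModel) else model.d_transition_width) ** 2
    if d_max * dt > 0.05 * width2:
        warnings.warn(
            f"time step dt={dt:g} ns is coarse: D_max*dt = {d_max * dt:.3g} nm^2 "
            f"is not small compared with the squared barrier width {width2:.3g} nm^2",
            stacklevel=2,
        )
    bias_center, bias_k = (0.0, 0.0) if bias is None else (float(bias[0]), float(bias[1]))
    if bias_k < 0:
        raise ValidationError("bias force constant must be >= 0")

    n_total = n_equil + n_steps
    n_out = 1 + (n_steps - 1) // save_every
    normals = np.random.default_rng(seed).standard_normal(n_total)
    out = np.empty(n_out, dtype=np.float64)
    pars = _kernel_params(model)
    n_reflect = _em_loop(
        float(z0), n_total, n_equil, save_every, float(dt), normals,
        pars["gauss_amp"], pars["gauss_mu"], pars["gauss_sig2"],
        float(pars["quad_kappa"]), float(pars["ramp_slope"]),
        float(pars["table_z0"]), float(pars["table_dz"]), pars["table_grad"],
        float(model.d_bulk), float(model.d_mem), float(model.half_width),
        float(model.d_transition_width), bias_k, bias_center,
        float(model.kbt), float(model.box_half_width), out,
    )
    if n_reflect:
        logger.info("brownian_dynamics: %d reflective boundary events", n_reflect)
    if return_info:
        return out, {"n_reflections": int(n_reflect), "dt_effective": dt * save_every}
    return out


def default_window_centers(model, n_windows: int = 29, span: float | None = None) -> np.ndarray:
    """Evenly spaced umbrella centres over ±span (default 0.875 * box half-width)."""
    if span is None:
        span = 0.875 * model.box_half_width
    return np.linspace(-span, span, n_windows)


def generate_umbrella_dataset(model, window_centers, force_constant: float = 150.0,
                              n_steps: int = 1_000_000, n_equil: int = 20_000,
                              dt: float = 2e-4, seed: int = 0,
                              save_every: int = 1) -> list[UmbrellaWindow]:
    """Generate one umbrella window per centre by Brownian dynamics.

    Each window starts at its bias centre, discards ``n_equil`` equilibration
    steps and records ``n_steps`` further positions.  Per-window seeds are
    derived from the master ``seed`` with a counter-based
    :class:`numpy.random.SeedSequence`, so the dataset is reproducible and
    each window is independent of the others and of their order.

    A warning is emitted when the harmonic width sigma = sqrt(k_B T/k) drops
    below half the window spacing (adjacent stationary distributions then
    overlap poorly); generation fails outright only when adjacent stationary
    distributions would be essentially disjoint (spacing > 8 sigma).
    """
    centers = np.asarray(window_centers, dtype=float)
    if centers.ndim != 1 or centers.size < 1:
        raise ValidationError("window_centers must be a non-empty 1-D sequence")
    if np.any(np.diff(centers) <= 0):
        raise ValidationError("window_centers must be strictly increasing")
    if force_constant <= 0:
        raise ValidationError("force_constant must be positive")
    sigma = math.sqrt(model.kbt / force_constant)
    if centers.size > 1:
        spacing = float(np.max(np.diff(centers)))
        if spacing > 8.0 * sigma:
            raise ValidationError(
                f"adjacent windows would not overlap: spacing {spacing:.3g} nm "
                f"> 8 sigma = {8 * sigma:.3g} nm at k={force_constant:g}"
            )
        if sigma < spacing / 2.0:
            warnings.warn(
                f"window overlap is marginal: sigma = {sigma:.3g} nm is below half "
                f"the spacing {spacing / 2:.3g} nm",
                stacklevel=2,
            )
    windows = []
    for i, c in enumerate(centers):
        child_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0])
        samples = brownian_dynamics(
            model, z0=float(c), n_steps=n_steps, dt=dt, seed=child_seed,
            bias=(float(c), force_constant), n_equil=n_equil, save_every=save_every,
        )
        windows.append(
            UmbrellaWindow(
                center=float(c), force_constant=force_constant, dt=dt * save_every,
                samples=samples, temperature=model.temperature, seed=child_seed,
                meta={"master_seed": seed, "index": i, "n_equil": n_equil,
                      "model": getattr(model, "name", "unknown")},
            )
        )
    return windows
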