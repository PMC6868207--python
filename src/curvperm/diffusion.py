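"""Position-dependent diffusion coefficients from umbrella-window fluctuations.

Inside a stiff harmonic window on a locally flat landscape the reaction
coordinate is an Ornstein–Uhlenbeck process, for which the positional
autocovariance is C(t) = sigma^2 exp(-t/tau) with tau = sigma^2 / D.  The
estimator used here inverts that relation without assuming the exponential
form:

    D(z_i) = sigma_i^4 / ∫_0^∞ C_i(t) dt      (= sigma_i^2 / tau_i),

which is exact in expectation for an OU window and is the standard
positional-autocorrelation estimator for umbrella-sampling data (Hummer
type).  The integral is truncated at the first zero crossing or the first
drop below a small fraction of C(0), with an optional exponential tail
correction; estimates are attributed by default to the *sample mean* of the
window rather than the bias centre, because the window slides downhill on a
tilted landscape.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from statsmodels.tsa.stattools import acovf

from .dynamics import UmbrellaWindow
from .errors import ValidationError
from .profiles import Profile

__all__ = [
    "acf",
    "integrated_correlation_time",
    "DiffusionEstimate",
    "estimate_D_window",
    "assemble_D_profile",
]

logger = logging.getLogger(__name__)

DEFAULT_ACF_THRESHOLD = 0.01   # integrate C(t) until it falls below this * C(0)


def acf(samples: np.ndarray, max_lag: int | None = None) -> np.ndarray:
    """Autocovariance C(t) of a series at lags 0..max_lag.

    Uses the unbiased (per-lag 1/(n-k)) normalization via FFT; C(0) is the
    sample variance.  Raises for constant (zero-variance) or too-short input.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or x.size < 10:
        raise ValidationError("need a 1-D series of at least 10 samples")
    if np.ptp(x) == 0.0 or np.var(x) == 0.0:
        raise ValidationError("series is constant: autocovariance is undefined")
    if max_lag is None:
        max_lag = x.size - 1
    max_lag = int(min(max_lag, x.size - 1))
    if max_lag < 1:
        raise ValidationError("max_lag must be >= 1")
    return acovf(x, adjusted=True, demean=True, fft=True, nlag=max_lag)


def _cutoff_index(c: np.ndarray, threshold: float) -> int | None:
    """First lag where C crosses zero or drops below threshold * C(0)."""
    limit = threshold * c[0]
    below = np.nonzero((c[1:] <= limit) | (c[1:] < 0.0))[0]
    if below.size == 0:
        return None
    return int(below[0]) + 1


def _integrate_acf(c: np.ndarray, dt: float, threshold: float,
                   tail_correction: bool) -> tuple[float, float] | None:
    """(integral of C dt, cutoff time); None when C never decays below threshold."""
    cut = _cutoff_index(c, threshold)
    if cut is None:
        return None
    integral = float(np.trapezoid(c[: cut + 1], dx=dt))
    if tail_correction and c[cut] > 0.0 and c[cut - 1] > c[cut]:
        # attach the analytic tail of a locally fitted exponential decay
        tau_tail = dt / math.log(c[cut - 1] / c[cut])
        if math.isfinite(tau_tail) and tau_tail > 0:
            integral += float(c[cut]) * tau_tail
    return integral, cut * dt


def integrated_correlation_time(samples: np.ndarray, dt: float = 1.0,
                                max_lag: int | None = None,
                                threshold: float = DEFAULT_ACF_THRESHOLD) -> float:
    """Integrated autocorrelation time tau = ∫C dt / C(0), in units of ``dt``.

    Falls back to the truncated integral (no tail) when the autocovariance
    never decays below the threshold within ``max_lag``.
    """
    x = np.asarray(samples, dtype=float)
    if max_lag is None:
        max_lag = max(10, min(x.size - 1, x.size // 5))
    c = acf(x, max_lag=max_lag)
    res = _integrate_acf(c, dt, threshold, tail_correction=True)
    if res is None:
        integral = float(np.trapezoid(c, dx=dt))
        return max(integral / c[0], dt)
    return max(res[0] / c[0], dt * 1e-12)


@dataclass
class DiffusionEstimate:
    """Local diffusion coefficient from one umbrella window."""

    z: float                      # attribution position (nm)
    D: float                      # nm^2/ns; NaN when invalid
    variance: float               # sigma_i^2 (nm^2)
    tau: float                    # integrated correlation time (ns)
    cutoff: float                 # ACF integration cutoff actually used (ns)
    valid: bool = True
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.valid and not (self.D > 0 and self.tau > 0):
            raise ValidationError("a valid estimate requires D > 0 and tau > 0")


def estimate_D_window(window: UmbrellaWindow, threshold: float = DEFAULT_ACF_THRESHOLD,
                      max_lag: int | None = None, tail_correction: bool = True,
                      attribute: str = "mean") -> DiffusionEstimate:
    """Estimate D at one umbrella window from its positional autocovariance.

    Parameters
    ----------
    threshold:
        The ACF is integrated up to its first zero crossing or first drop
        below ``threshold * C(0)``, whichever comes first.
    tail_correction:
        Add the analytic tail of a locally fitted exponential beyond the
        cutoff (reduces the truncation bias of slowly decaying windows).
    attribute:
        ``"mean"`` attributes the estimate to the sample mean of the window
        (default; accounts for the window sliding off-centre on tilted
        landscapes), ``"center"`` to the bias centre.

    A window whose ACF never decays below the threshold within ``max_lag``
    yields an *invalid* estimate (``valid=False``, D = NaN) rather than an
    exception, so profile assembly can skip and log it.
    """
    if window.force_constant <= 0:
        raise ValidationError("diffusion estimation needs an active harmonic bias (k > 0)")
    if attribute not in ("mean", "center"):
        raise ValidationError("attribute must be 'mean' or 'center'")
    x = window.samples
    if max_lag is None:
        max_lag = max(10, min(x.size - 1, x.size // 5))
    c = acf(x, max_lag=max_lag)
    var = float(c[0])
    z_attr = float(np.mean(x)) if attribute == "mean" else float(window.center)
    res = _integrate_acf(c, window.dt, threshold, tail_correction)
    if res is None or res[0] <= 0:
        return DiffusionEstimate(
            z=z_attr, D=float("nan"), variance=var, tau=float("nan"),
            cutoff=float("nan"), valid=False,
            flags=["acf-never-decayed" if res is None else "nonpositive-acf-integral"],
        )
    integral, cutoff = res
    tau = integral / var
    return DiffusionEstimate(
        z=z_attr, D=var * var / integral, variance=var, tau=tau, cutoff=cutoff,
        valid=True, flags=[],
    )


def assemble_D_profile(estimates: list[DiffusionEstimate], grid: np.ndarray,
                       interpolation: str = "pchip") -> Profile:
    """Interpolate per-window D estimates onto a profile grid.

    Uses monotone-cubic (PCHIP) interpolation, which cannot overshoot the
    neighbouring estimates — essential because the resistance
    exp(G/k_B T)/D is exponentially sensitive and an overshoot of D near the
    barrier corrupts the permeability.  Beyond the outermost valid estimate
    the profile is extended as a constant.  Invalid estimates are excluded
    and logged.
    """
    grid = np.asarray(grid, dtype=float)
    valid = [e for e in estimates if e.valid and np.isfinite(e.D)]
    n_excluded = len(estimates) - len(valid)
    if n_excluded:
        logger.info("assemble_D_profile: excluded %d invalid estimates", n_excluded)
    if len(valid) < 2:
        raise ValidationError(f"need >= 2 valid estimates, have {len(valid)}")
    order = np.argsort([e.z for e in valid])
    zs = np.array([valid[i].z for i in order])
    ds = np.array([valid[i].D for i in order])
    if np.any(np.diff(zs) <= 0):
        keep = np.concatenate([[True], np.diff(zs) > 1e-12])
        zs, ds = zs[keep], ds[keep]
        if zs.size < 2:
            raise ValidationError("estimates collapse onto a single position")
    if interpolation == "pchip":
        interp = PchipInterpolator(zs, ds, extrapolate=False)
        vals = interp(np.clip(grid, zs[0], zs[-1]))
    elif interpolation == "linear":
        vals = np.interp(grid, zs, ds)
    else:
        raise ValidationError(f"unknown interpolation {interpolation!r}")
    vals = np.where(grid < zs[0], ds[0], np.where(grid > zs[-1], ds[-1], vals))
    if not np.all(vals > 0):
        raise ValidationError("assembled diffusivity profile is not strictly positive")
    return Profile(
        grid, vals,
        meta={
            "kind": "diffusivity", "units": "nm^2/ns",
            "interpolation": interpolation, "n_estimates": len(valid),
            "n_excluded": n_excluded,
            "attribution_span_nm": (float(zs[0]), float(zs[-1])),
        },
    )
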