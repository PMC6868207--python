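"""Profiles: functions of the membrane-normal coordinate on a grid.

A :class:`Profile` holds values (free energy, diffusivity, resistance ...)
on a strictly increasing grid of z positions (nm), with optional per-point
uncertainty and free-form metadata.  Undefined points (e.g. unsampled WHAM
bins) are stored as NaN and treated as *gaps*, never as zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import ValidationError


@dataclass
class Profile:
    """A sampled function of the membrane-normal coordinate z.

    Parameters
    ----------
    z:
        Grid positions in nm, strictly increasing.
    values:
        Function values at ``z``; NaN marks a gap (undefined point).
    sigma:
        Optional 1-sigma uncertainty per point (same units as ``values``).
    meta:
        Free-form provenance/settings metadata carried into output headers.
    """

    z: np.ndarray
    values: np.ndarray
    sigma: np.ndarray | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.z.ndim != 1 or self.z.shape != self.values.shape:
            raise ValidationError(
                f"z and values must be 1-D and equally shaped, got {self.z.shape} and {self.values.shape}"
            )
        if self.z.size < 2:
            raise ValidationError("a profile needs at least two grid points")
        if not np.all(np.diff(self.z) > 0):
            raise ValidationError("profile grid must be strictly increasing")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.z.shape:
                raise ValidationError("sigma must match the grid shape")
            if np.nanmin(self.sigma) < 0:
                raise ValidationError("sigma must be non-negative")

    # -- gaps ---------------------------------------------------------------
    @property
    def gap_mask(self) -> np.ndarray:
        """Boolean mask of undefined (NaN) points."""
        return ~np.isfinite(self.values)

    @property
    def n_gaps(self) -> int:
        return int(self.gap_mask.sum())

    def largest_gap_free_run(self) -> tuple[int, int]:
        """(start, stop) index slice of the longest contiguous finite block."""
        finite = np.isfinite(self.values)
        if not finite.any():
            raise ValidationError("profile has no defined points")
        best = (0, 0)
        i = 0
        n = finite.size
        while i < n:
            if finite[i]:
                j = i
                while j < n and finite[j]:
                    j += 1
                if j - i > best[1] - best[0]:
                    best = (i, j)
                i = j
            else:
                i += 1
        return best

    # -- arithmetic helpers -------------------------------------------------
    def interpolate_to(self, grid: np.ndarray) -> "Profile":
        """Linear interpolation onto ``grid``, clamped at the ends.

        Gap points are dropped before interpolating; target points that fall
        strictly inside a gap wider than two source bins become gaps again.
        """
        grid = np.asarray(grid, dtype=float)
        finite = np.isfinite(self.values)
        if finite.sum() < 2:
            raise ValidationError("need at least two defined points to interpolate")
        zf, vf = self.z[finite], self.values[finite]
        if grid.min() > zf.max() or grid.max() < zf.min():
            raise ValidationError("target grid does not overlap the profile range")
        out = np.interp(grid, zf, vf, left=vf[0], right=vf[-1])
        return Profile(grid, out, meta=dict(self.meta))

    def copy(self) -> "Profile":
        return Profile(
            self.z.copy(),
            self.values.copy(),
            None if self.sigma is None else self.sigma.copy(),
            dict(self.meta),
        )


class PMFProfile(Profile):
    """Potential of mean force ΔG(z) in kJ/mol, zeroed over a bulk reference."""


class ResistanceProfile(Profile):
    """Permeation resistance R(z) = exp(ΔG/k_B T)/D in ns/nm^2.

    ``cumulative`` holds the running trapezoid integral of R from the left
    edge, skipping gap bins (which propagate as NaN in ``values``).
    """

    def __init__(self, z, values, cumulative, sigma=None, meta=None):
        super().__init__(z, values, sigma, meta or {})
        self.cumulative = np.asarray(cumulative, dtype=float)
        if self.cumulative.shape != self.z.shape:
            raise ValidationError("cumulative must match the grid shape")
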