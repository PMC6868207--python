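"""Inhomogeneous solubility-diffusion (ISD) permeability.

The membrane resistance per unit length is R(z) = exp(ΔG(z)/k_B T)/D(z)
(ns/nm^2) and the permeability coefficient follows from

    1/P = ∫_{z1}^{z2} R(z) dz ,

integrated with the trapezoid rule on the histogram-resolution PMF grid.
Because z is in nm and t in ns, P in nm/ns is numerically identical to P in
m/s, the conventional reporting unit.  Uncertainties are propagated by a
paired full-pipeline moving-block bootstrap: each replicate resamples the
raw windows once and feeds the *same* resample to both the PMF and the
diffusivity estimators, preserving their covariance.
"""

from __future__ import annotations


import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE, kbt
from .diffusion import assemble_D_profile, estimate_D_window
from .dynamics import UmbrellaWindow
from .errors import GapError, PipelineError, ValidationError
from .profiles import PMFProfile, Profile, ResistanceProfile
from . import wham as _wham

__all__ = [
    "resistance",
    "permeability",
    "PermeabilityResult",
    "propagate_errors",
    "permeability_ratio",
    "PermeabilityRatio",
    "run_pipeline",
    "PipelineOutput",
    "curvature_table",
    "ComparisonTable",
]


def resistance(pmf: PMFProfile, d_profile: Profile,
               temperature: float | None = None) -> ResistanceProfile:
    """Pointwise permeation resistance R(z) = exp(ΔG/k_B T)/D on the PMF grid.

    The diffusivity profile is resampled onto the PMF grid if the grids
    differ (error if their ranges are disjoint).  PMF gaps propagate as NaN
    and are excluded from the cumulative integral with a warning.
    """
    if temperature is None:
        temperature = float(pmf.meta.get("temperature_K", DEFAULT_TEMPERATURE))
    kt = kbt(temperature)
    if d_profile.z.shape == pmf.z.shape and np.allclose(d_profile.z, pmf.z):
        d_vals = d_profile.values
    else:
        d_vals = d_profile.interpolate_to(pmf.z).values
    if np.any(~(d_vals > 0)):
        raise ValidationError("diffusivity must be strictly positive on the PMF grid")
    with np.errstate(over="raise"):
        r = np.exp(pmf.values / kt) / d_vals
    gaps = ~np.isfinite(pmf.values)
    if gaps.any():
        warnings.warn(
            f"{int(gaps.sum())} PMF gap bins propagate into the resistance profile "
            "and are excluded from integration",
            stacklevel=2,
        )
    cumulative = np.full_like(r, np.nan)
    run = 0.0
    cumulative[0] = 0.0 if np.isfinite(r[0]) else np.nan
    for i in range(1, r.size):
        if np.isfinite(r[i]) and np.isfinite(r[i - 1]):
            run += 0.5 * (r[i] + r[i - 1]) * (pmf.z[i] - pmf.z[i - 1])
        cumulative[i] = run if np.isfinite(r[i]) else np.nan
    return ResistanceProfile(
        pmf.z, r, cumulative,
        meta={
            "kind": "resistance", "units": "ns/nm^2",
            "temperature_K": temperature,
            "pmf_meta": dict(pmf.meta), "d_meta": dict(d_profile.meta),
        },
    )


@dataclass
class PermeabilityResult:
    """Permeability coefficient with provenance.

    ``p`` is computed in nm/ns, which equals the value in m/s; ``sigma_p``
    is the bootstrap standard deviation when available.
    """

    p: float
    sigma_p: float | None
    z1: float
    z2: float
    temperature: float
    units: str = "m/s"
    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.p > 0):
            raise ValidationError(f"permeability must be positive, got {self.p}")
        if self.sigma_p is not None and self.sigma_p < 0:
            raise ValidationError("sigma_p must be >= 0")

    def __str__(self) -> str:
        err = f" ± {self.sigma_p:.2e}" if self.sigma_p is not None else ""
        return f"P = {self.p:.2e}{err} {self.units} over [{self.z1:g}, {self.z2:g}] nm"


def permeability(r_profile: ResistanceProfile, z1: float | None = None,
                 z2: float | None = None,
                 refinement_threshold: float = 1e-3) -> PermeabilityResult:
    """Integrate the resistance profile: P = 1/∫R dz (trapezoid rule).

    Default limits are the largest gap-free extent of the grid.  Explicit
    limits that enclose a gap raise :class:`GapError` listing the gap bins.
    A Richardson-style comparison against the half-resolution trapezoid
    estimates the discretization error; a warning is raised when it exceeds
    ``refinement_threshold`` (0.1%) of P.
    """
    z, r = r_profile.z, r_profile.values
    if z1 is None or z2 is None:
        lo, hi = r_profile.largest_gap_free_run()
        z1 = float(z[lo]) if z1 is None else z1
        z2 = float(z[hi - 1]) if z2 is None else z2
    if z1 >= z2:
        raise ValidationError(f"need z1 < z2, got [{z1}, {z2}]")
    if z1 < z[0] - 1e-9 or z2 > z[-1] + 1e-9:
        raise ValidationError(
            f"limits [{z1:g}, {z2:g}] exceed the profile grid [{z[0]:g}, {z[-1]:g}]"
        )
    sel = (z >= z1 - 1e-12) & (z <= z2 + 1e-12)
    if sel.sum() < 2:
        raise ValidationError("fewer than two grid points inside the integration limits")
    gap_bins = np.nonzero(sel & ~np.isfinite(r))[0]
    if gap_bins.size:
        raise GapError(
            f"resistance has {gap_bins.size} gap bins inside [{z1:g}, {z2:g}] at "
            f"z = {np.round(z[gap_bins], 4).tolist()}"
        )
    zi, ri = z[sel], r[sel]
    integral = float(np.trapezoid(ri, zi))
    coarse = float(np.trapezoid(ri[::2], zi[::2])) if zi.size >= 5 else integral
    p = 1.0 / integral
    est_rel_err = abs(1.0 / coarse - p) / (3.0 * p) if coarse > 0 else 0.0
    if est_rel_err > refinement_threshold:
        warnings.warn(
            f"trapezoid discretization error on P estimated at {est_rel_err:.2%}; "
            "refine the PMF grid (smaller bin width)",
            stacklevel=2,
        )
    return PermeabilityResult(
        p=p, sigma_p=None, z1=float(z1), z2=float(z2),
        temperature=float(r_profile.meta.get("temperature_K", DEFAULT_TEMPERATURE)),
        settings={
            "integration": "trapezoid",
            "estimated_discretization_rel_error": est_rel_err,
            "n_grid_points": int(sel.sum()),
        },
    )


# ---------------------------------------------------------------------------
# Full pipeline and paired bootstrap
# ---------------------------------------------------------------------------

@dataclass
class PipelineOutput:
    """All artefacts of one windows -> permeability analysis."""

    pmf: PMFProfile
    d_profile: Profile
    d_estimates: list
    resistance: ResistanceProfile
    permeability: PermeabilityResult


def run_pipeline(windows: list[UmbrellaWindow], bin_width: float = _wham.DEFAULT_BIN_WIDTH,
                 tol: float = _wham.DEFAULT_TOL, max_iter: int = _wham.DEFAULT_MAX_ITER,
                 bulk_fraction: float = _wham.DEFAULT_BULK_FRACTION,
                 acf_threshold: float = 0.01, tail_correction: bool = True,
                 attribute: str = "mean", z1: float | None = None,
                 z2: float | None = None, temperature: float | None = None,
                 f_init: np.ndarray | None = None,
                 edges: np.ndarray | None = None) -> PipelineOutput:
    """Windows -> WHAM PMF -> D(z) -> resistance -> permeability, point estimate."""
    hists = _wham.build_histograms(windows, bin_width=bin_width, edges=edges)
    pmf = _wham.wham_solve(hists, temperature=temperature, tol=tol, max_iter=max_iter,
                           bulk_fraction=bulk_fraction, f_init=f_init)
    estimates = [
        estimate_D_window(w, threshold=acf_threshold, tail_correction=tail_correction,
                          attribute=attribute)
        for w in windows
    ]
    d_profile = assemble_D_profile(estimates, pmf.z)
    r = resistance(pmf, d_profile, temperature=temperature)
    p = permeability(r, z1=z1, z2=z2)
    return PipelineOutput(pmf=pmf, d_profile=d_profile, d_estimates=estimates,
                          resistance=r, permeability=p)


def propagate_errors(windows: list[UmbrellaWindow], n_boot: int = 16, seed: int = 0,
                     block_length: int | None = None,
                     max_failure_fraction: float = 0.2,
                     **pipeline_kwargs) -> PermeabilityResult:
    """Full-pipeline paired bootstrap of the permeability.

    Each replicate draws one moving-block resample per window and re-runs
    WHAM, the diffusion estimator and the integration on it, so PMF and
    D(z) fluctuations stay paired and their covariance is preserved in
    sigma_P.  Failed replicates (e.g. a disconnected resample) are dropped
    and counted; more than ``max_failure_fraction`` failures aborts.
    Deterministic given ``seed``.
    """
    if n_boot < 2:
        raise ValidationError("n_boot must be >= 2")
    if n_boot < 10:
        warnings.warn("n_boot < 10: sigma_P will be too noisy to report", stacklevel=2)
    base = run_pipeline(windows, **pipeline_kwargs)
    edges0 = base.pmf.meta["edges_first_last"]
    bw = base.pmf.meta["bin_width_nm"]
    n_bins = int(round((edges0[1] - edges0[0]) / bw))
    edges = edges0[0] + bw * np.arange(n_bins + 1)
    f0 = np.array(base.pmf.meta["window_free_energies_kJ_mol"])
    z1b, z2b = base.permeability.z1, base.permeability.z2

    blocks = [
        block_length if block_length is not None else _wham.estimate_block_length(w)
        for w in windows
    ]
    rng = np.random.default_rng(seed)
    ps, failures = [], 0
    for _ in range(n_boot):
        rep_windows = [
            UmbrellaWindow(w.center, w.force_constant, w.dt,
                           _wham.moving_block_resample(w.samples, b, rng),
                           w.temperature)
            for w, b in zip(windows, blocks)
        ]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep = run_pipeline(rep_windows, f_init=f0, edges=edges,
                                   z1=z1b, z2=z2b, **{
                                       k: v for k, v in pipeline_kwargs.items()
                                       if k not in ("z1", "z2", "f_init", "edges")
                                   })
            ps.append(rep.permeability.p)
        except Exception:
            failures += 1
    if failures > max_failure_fraction * n_boot:
        raise PipelineError(
            f"{failures}/{n_boot} bootstrap replicates failed (> {max_failure_fraction:.0%})"
        )
    sigma = float(np.std(ps, ddof=1)) if len(ps) > 1 else 0.0
    result = base.permeability
    return PermeabilityResult(
        p=result.p, sigma_p=sigma, z1=result.z1, z2=result.z2,
        temperature=result.temperature,
        settings={
            **result.settings,
            "error_model": "paired full-pipeline moving-block bootstrap",
            "n_boot": n_boot, "n_failed_replicates": failures,
            "block_lengths": blocks, "bootstrap_seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# Ratios and comparison tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermeabilityRatio:
    """Curved/flat permeability ratio with its table rendering."""

    value: float
    rounded: float
    decimals: int = 1

    def __str__(self) -> str:
        return f"{self.rounded:.{self.decimals}f}"


def permeability_ratio(p_flat, p_curved, decimals: int = 1) -> PermeabilityRatio:
    """Permeability ratio curved/flat; half-even rounded to 1 decimal for tables.

    Accepts floats (m/s) or :class:`PermeabilityResult` objects.
    """
    pf = p_flat.p if isinstance(p_flat, PermeabilityResult) else float(p_flat)
    pc = p_curved.p if isinstance(p_curved, PermeabilityResult) else float(p_curved)
    if pf <= 0 or pc <= 0:
        raise ValidationError("permeabilities must be positive")
    ratio = pc / pf
    return PermeabilityRatio(value=ratio, rounded=round(ratio, decimals), decimals=decimals)


def _curvature_sort_key(c: float) -> tuple:
    # flat first, then positive curvatures ascending, then negative descending
    return (c != 0.0, c < 0, abs(c))


@dataclass
class ComparisonTable:
    """Barrier heights or permeabilities across curvatures with relative values.

    Rows are curvatures (flat first), columns ligands; each cell renders the
    absolute value with its relative value (vs the flat membrane of the same
    ligand) in parentheses, the layout conventional for curvature studies.
    """

    quantity: str                 # "barrier" (kJ/mol) or "permeability" (m/s)
    data: pd.DataFrame            # tidy: ligand, curvature, value, sigma, relative, rel_rounded

    def to_wide(self) -> pd.DataFrame:
        def cell(row):
            if row.isna()["value"]:
                return "—"
            if self.quantity == "barrier":
                s = f"{row['value']:.1f}"
            else:
                s = f"{row['value']:.1e}"
                if np.isfinite(row.get("sigma", np.nan)):
                    s += f" ± {row['sigma']:.1e}"
            if row["curvature"] != 0.0:
                nd = 2 if self.quantity == "barrier" else 1
                s += f" ({row['rel_rounded']:.{nd}f})"
            return s

        df = self.data.copy()
        df["cell"] = df.apply(cell, axis=1)
        wide = df.pivot(index="curvature", columns="ligand", values="cell")
        wide = wide.reindex(sorted(wide.index, key=_curvature_sort_key))
        wide = wide[sorted(wide.columns)].fillna("—")
        wide.index.name = "curvature_nm^-1"
        return wide

    def render(self) -> str:
        unit = "kJ/mol" if self.quantity == "barrier" else "m/s"
        head = ("Maximal barrier heights" if self.quantity == "barrier"
                else "Permeability coefficients")
        rel = ("relative height vs flat" if self.quantity == "barrier"
               else "ratio vs flat")
        body = self.to_wide().to_string()
        return f"{head} ({unit}); parentheses: {rel}.\n{body}"

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# quantity = {self.quantity}\n")
            self.data.to_csv(fh, sep="\t", index=False)


def curvature_table(records: list[dict], quantity: str = "permeability") -> ComparisonTable:
    """Build the cross-curvature comparison table.

    ``records`` are dicts with keys ``ligand``, ``curvature``, ``value`` and
    optional ``sigma`` (value: barrier in kJ/mol or permeability in m/s).
    Every ligand must include a flat (curvature = 0) entry; duplicate
    (ligand, curvature) pairs are rejected.  Relative values are rounded
    half-even to 2 decimals for barriers and 1 decimal for permeability
    ratios; unrounded values are kept in the ``relative`` column.
    """
    if quantity not in ("barrier", "permeability"):
        raise ValidationError("quantity must be 'barrier' or 'permeability'")
    if not records:
        raise ValidationError("no records given")
    df = pd.DataFrame.from_records(records)
    for col in ("ligand", "curvature", "value"):
        if col not in df.columns:
            raise ValidationError(f"records lack required key {col!r}")
    if "sigma" not in df.columns:
        df["sigma"] = np.nan
    dup = df.duplicated(subset=["ligand", "curvature"])
    if dup.any():
        pairs = df.loc[dup, ["ligand", "curvature"]].to_records(index=False).tolist()
        raise ValidationError(f"duplicate (ligand, curvature) entries: {pairs}")
    rel, rel_rounded = [], []
    nd = 2 if quantity == "barrier" else 1
    for _, row in df.iterrows():
        flat = df[(df.ligand == row.ligand) & (df.curvature == 0.0)]
        if flat.empty:
            raise ValidationError(f"ligand {row.ligand!r} has no flat (curvature 0) entry")
        fv = float(flat.value.iloc[0])
        if fv <= 0:
            raise ValidationError(f"flat value for {row.ligand!r} must be positive")
        r = float(row.value) / fv
        rel.append(r)
        rel_rounded.append(round(r, nd))
    df = df.assign(relative=rel, rel_rounded=rel_rounded)
    df = df.sort_values(
        ["ligand", "curvature"],
        key=lambda s: s.map(_curvature_sort_key) if s.name == "curvature" else s,
    ).reset_index(drop=True)
    return ComparisonTable(quantity=quantity, data=df)
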