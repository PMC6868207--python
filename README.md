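# curvperm

Membrane curvature and passive permeability: an umbrella-sampling analysis
pipeline for the membrane-normal reaction coordinate, with a synthetic
Brownian-dynamics generator so the whole pipeline is testable without
molecular dynamics.

Passive permeation of ions, water and small hydrophilic drugs across a lipid
bilayer is controlled by the free-energy barrier the membrane presents.
Bending the membrane repacks its two leaflets — the convex monolayer loosens,
the concave one densifies — which lowers the barrier, shifts its peak toward
the concave leaflet, and can raise the permeability by orders of magnitude.
`curvperm` provides the standard analysis chain used to quantify this from
biased simulations, for people who have umbrella-sampling data (real
pull-coordinate output or synthetic) and want permeabilities with honest
error bars:

1. **WHAM** — reconstruct the potential of mean force ΔG(z) from biased
   window histograms by the self-consistent weighted-histogram equations,
   with moving-block-bootstrap uncertainty bands;
2. **D(z)** — estimate the position-dependent diffusion coefficient per
   window from positional fluctuations, D = σ⁴/∫C(t)dt (exact for an
   Ornstein–Uhlenbeck window), assembled with overshoot-free monotone
   interpolation;
3. **ISD** — integrate the inhomogeneous solubility-diffusion model,
   1/P = ∫ exp(ΔG(z)/k_BT)/D(z) dz, propagating errors with a paired
   full-pipeline bootstrap;
4. **Synthetic membranes** — a parametric curved-membrane family
   (water-/ion-/drug-like presets; curvature scales the barrier and shifts
   its peak toward the concave monolayer) sampled by overdamped
   Euler–Maruyama dynamics with the exact spurious-drift term, plus an
   analytic permeability oracle for validation.

Units: z in nm, t in ns, energies in kJ/mol, D in nm²/ns; P in nm/ns is
numerically equal to P in m/s.  Default temperature 320 K.  Curvature sign:
positive means the outer monolayer (z > 0) is convex.

## Worked example

```python
import curvperm as cp

model = cp.preset("drug", curvature=0.2)          # drug-like, bent membrane
windows = cp.generate_umbrella_dataset(
    model, cp.default_window_centers(model), n_steps=200_000, seed=3)

out = cp.run_pipeline(windows)                     # WHAM -> D(z) -> ISD
result = cp.propagate_errors(windows, n_boot=12, seed=3)
print(result)
print(f"oracle: {cp.analytic_permeability(model, result.z1, result.z2):.2e} m/s")
```

prints (examples/05_permeability_pipeline.py, demo scale):

```
P = 8.10e-12 ± 3.57e-12 m/s over [-3.975, 3.975] nm
analytic oracle: 8.02e-12 m/s -> pipeline/oracle = 1.01
100.0% of the membrane resistance accrues within |z| < 1 nm
```

The pipeline estimate agrees with the exact ISD permeability of the
generating model within its bootstrap error; the resistance profile shows
why the barrier region alone sets P.  Comparing presets across curvatures
(examples/01, 06) reproduces the familiar pattern: relative barrier heights
below 1 for bent membranes and permeability ratios above 1, e.g. a 10%
barrier drop multiplying P by ~13.

More narrative scripts live in `examples/` (one per capability: landscape
presets, dataset generation, WHAM, D(z), full pipeline, comparison tables).
A thin CLI wraps the same stages for shell use:

```sh
curvperm simulate --preset water --curvature 0.2 --seed 1 --out-dir data/
curvperm pipeline --manifest data/manifest.tsv --out-dir run/
curvperm compare --input barriers.tsv --quantity barrier
```

Window files are plain two-column text (`#`/`@` comments, xvg-like), so real
pull-coordinate output can be ingested unchanged.

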