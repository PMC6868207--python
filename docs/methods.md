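# Methods

`curvperm` analyses umbrella-sampling data along the membrane-normal
coordinate z and turns it into a permeability coefficient through the
inhomogeneous solubility-diffusion (ISD) model.  Because real curved-bilayer
free-energy surfaces require large-scale all-atom MD, the package ships a
synthetic membrane family with an exact permeability oracle, so every stage
of the analysis is testable end to end on a desktop.

## The ISD model

For a solute crossing a membrane spanning z ∈ [z₁, z₂], the permeability
coefficient P follows from the potential of mean force ΔG(z) and the local
diffusion coefficient D(z):

    1/P = ∫_{z₁}^{z₂} R(z) dz,      R(z) = exp(ΔG(z)/k_B T) / D(z).

R(z) is the local permeation resistance.  Units are fixed package-wide:
z in nm, t in ns, energies in kJ/mol, D in nm²/ns,
k_B = 0.0083144621 kJ mol⁻¹ K⁻¹, default T = 320 K.  With these units
P computed in nm/ns is numerically identical to P in m/s, the conventional
reporting unit.  Because ΔG enters exponentially, permeability is dominated
by the barrier region; D matters only linearly and only where exp(ΔG/k_BT)
is large.

## Synthetic membrane family

The ground-truth landscape is

    G(z) = β_c G_b · N(z; z_peak + δ_c, w_b) + G_w [N(z; +z_w, w_w) + N(z; −z_w, w_w)]

(N a unit-height Gaussian), minus the linear ramp that makes G exactly zero
at the domain edges ±L_box (bulk solvent is the zero of free energy).  The
diffusivity interpolates between a membrane-interior value D_mem and a bulk
value D_bulk with a product of two logistic sigmoids centred at ±L (the
membrane half-width), transition width w_D.

Curvature c (nm⁻¹; c > 0 ⇔ the outer monolayer at z > 0 is convex) enters
through exactly two parameters:

* β_c ∈ (0, 1]: bent membranes present lower barriers.  Per preset, β_c is
  linear in |c| between 1 at c = 0 and the preset's relative barrier height
  at the reference curvature |c| = 0.2 nm⁻¹ (different for the two signs).
* δ_c = −sign(c) · 0.15 nm · |c|/0.2: the peak shifts toward the concave
  (more densely packed) monolayer.

Three presets emulate permeant classes on the scales reported for small
hydrophilic molecules crossing an asymmetric, cholesterol-rich
plasma-membrane model at 320 K:

| preset | G_b (kJ/mol) | β at +0.2 | β at −0.2 | D_bulk | D_mem (nm²/ns) |
|--------|--------------|-----------|-----------|--------|----------------|
| water  | 31.4         | 0.96      | 0.95      | 2.0    | 0.3            |
| ion    | 101.1        | 0.97      | 0.92      | 1.5    | 0.15           |
| drug   | 70.1         | 0.90      | 0.95      | 0.8    | 0.08           |

Free parameters not pinned by any reported scale — the interfacial well
depths (−2 to −4 kJ/mol at ±2.0 nm, σ = 0.4 nm), barrier width
w_b = 1.0 nm, diffusivity transition width w_D = 0.3 nm, geometry L = 2 nm,
L_box = 4 nm — were fixed once at values a membrane biophysicist would call
plausible and are documented here as free choices.  w_b = 1.0 nm also keeps
max|G″| ≈ G_b/w_b² below the default umbrella spring constant, so every
biased window has a confining effective potential.  The diffusivity is
deliberately curvature-independent: in the reference data the curvature
response of P tracks the barrier change, and D varies too little near the
centre to matter.

`analytic_permeability` evaluates the ISD integral on this family by
adaptive quadrature (relative tolerance 1e−8) and serves as the oracle for
the whole pipeline.

## Brownian-dynamics generator

Umbrella windows are simulated with Euler–Maruyama in the Itô convention,

    z' = z + [ −D(z) G_tot′(z)/k_B T + D′(z) ] dt + sqrt(2 D(z) dt) η,

with G_tot = G + k/2 (z − z_i)² and reflective boundaries at ±L_box
(events counted and logged).  The spurious-drift term D′(z) is what makes
the stationary density proportional to exp(−G_tot/k_B T) as dt → 0; its
absence would tilt the density by 1/D(z).  Trajectories are exactly
reproducible: per-window seeds derive from the master seed by a
counter-based SeedSequence, independent of window order.

Default sampling protocol (the package's study scale): 29 windows over
±3.5 nm, k = 150 kJ mol⁻¹ nm⁻², dt = 2×10⁻⁴ ns, 10⁶ recorded steps
(200 ns) per window after 2×10⁴ equilibration steps.  The spring gives
σ = sqrt(k_BT/k) = 0.133 nm ≥ half the window spacing (0.125 nm), so
adjacent stationary distributions overlap well; generation warns when they
do not and refuses when adjacent windows would be essentially disjoint
(spacing > 8σ).  dt is small against every local relaxation time
(max θ·dt ≈ 0.02 for the stiffest window in bulk water), keeping the
Euler discretization bias in window variances below ~1%.

## WHAM

The PMF is reconstructed by the standard self-consistent WHAM fixed point
on a common uniform grid (default bin width 0.05 nm):

    p(z_b) ∝ Σ_i n_i(z_b) / Σ_i N_i exp[(f_i − w_i(z_b))/k_B T],
    exp(−f_i/k_B T) = Σ_b p(z_b) exp(−w_i(z_b)/k_B T),

iterated until max_i |Δf_i| < 10⁻⁶ kJ/mol (configurable; convergence
failure raises, reporting the residual).  A k = 0 window is accepted as
unbiased and reduces the solver to Boltzmann inversion.  Unsampled bins are
gaps (NaN), never zeros; a disconnected window-overlap graph is an error
listing the components.

Reference convention: ΔG is shifted so that its count-weighted mean over
the bulk region — bins with |z| ≥ 0.9 × the outermost window centre — is
zero.  Two deliberate details: the region is anchored to the outermost
window *centres*, not the raw sampled extent, and the mean is weighted by
bin counts.  Extreme-tail bins hold a handful of samples and carry a
positive bias in −k_B T ln p̂ (Jensen's inequality); referencing on them
would shift the entire profile by several tenths of kJ/mol.

Uncertainty: moving-block bootstrap within each window (umbrella samples
are strongly autocorrelated; an iid bootstrap would be far too confident).
Block length defaults to 5× the window's integrated autocorrelation time;
replicates are re-binned on the base grid and re-solved warm-started from
the base window free energies.  σ_G is the per-bin standard deviation over
replicates.  In coverage experiments against the ground truth the 1σ bands
cover ~55–70% of bins — moving-block bands are known to run slightly
narrow on windows tens of correlation times long; treat them as standard
errors, not strict confidence bands.

Barrier analytics: `barrier_height` is the maximum of the gap-free profile
above the (zero) bulk reference.  `peak_position` is the global maximum
after a 3-bin moving average; when several local maxima compete within 5%
of the smoothed peak-to-trough range the result is flagged ambiguous and
tie-broken toward z = 0.  Both the reference convention and the peak
definition are interpretations (recorded in output metadata), since
published analyses rarely state them.  Table output rounds relative
barriers half-even to 2 decimals and permeability ratios to 1 decimal;
unrounded values are always retained.

## Position-dependent diffusion coefficient

Inside a stiff window on a locally flat landscape the coordinate is an
Ornstein–Uhlenbeck process with autocovariance C(t) = σ² exp(−t/τ) and
τ = σ²/D.  The estimator inverts this without assuming the exponential
form (positional-autocorrelation estimator of the Hummer type):

    D(z_i) = σ_i⁴ / ∫₀^∞ C_i(t) dt  =  σ_i² / τ_i .

C(t) uses per-lag unbiased normalization (FFT).  The integral is truncated
at the first zero crossing or the first drop below 0.01·C(0), whichever
comes first, plus an optional exponential tail correction fitted locally at
the cutoff (both configurable and recorded).  A window whose ACF never
decays below the threshold yields an invalid estimate, which profile
assembly skips and logs — never a silent zero.  Estimates are attributed to
the window's *sample mean* by default (windows slide downhill on tilted
landscapes); attribution to the bias centre is available as an option, and
on default-scale synthetic data the choice moves P by <5%.

The estimator is exact in expectation for OU windows; on anharmonic
windows (barrier tops, steep flanks) it acquires a modest model-mismatch
uncertainty, and at 10⁵ samples a single window carries ~20% sampling
noise in the ACF integral — both cancel substantially over the many
windows entering the resistance integral.

Assembly onto the PMF grid uses monotone-cubic (PCHIP) interpolation with
constant extrapolation beyond the outermost valid estimate.  Monotone
interpolation cannot overshoot neighbouring estimates; since R =
exp(G/k_BT)/D, an overshoot of D near the barrier would corrupt P
directly.

## Permeability and error propagation

R(z) is formed pointwise on the PMF grid (D resampled if needed; PMF gaps
propagate and are excluded with a warning) and integrated with the
trapezoid rule — the profile only exists at histogram resolution, so a
higher-order rule would be false precision.  A Richardson comparison
against the half-resolution trapezoid estimates the discretization error
and warns above 0.1%.  Default integration limits are the largest gap-free
extent of the grid; explicit limits crossing a gap raise an error listing
the gap bins.  Limit sensitivity is mild by construction: on
barrier-dominated profiles >99% of the resistance accrues within
|z| < 1 nm.

σ_P comes from a paired full-pipeline moving-block bootstrap: each
replicate draws one block resample per window and re-runs WHAM, the
diffusion estimator and the integration on it, so PMF and D fluctuations
stay correlated exactly as in the data.  Failed replicates are dropped and
counted; more than 20% failures aborts.  Block resampling joins
discontiguous segments, which slightly decorrelates the replicate ACFs;
with blocks of 5τ the effect on σ_P is small compared with its own
sampling noise.

## Validation design

* Analytic limits: P = D/L for flat profiles to machine precision; adding
  a constant to ΔG multiplies R by exactly exp(c/k_B T); MSD = 2Dt for
  free Brownian motion.
* Exact WHAM oracle: histograms built from *expected* counts (quadrature
  of the biased Boltzmann densities) must reproduce the model PMF to
  binning accuracy — a sampling-free correctness check of the solver.
* Parameter recovery: WHAM on BD windows over a known harmonic landscape
  recovers its curvature within bootstrap error; the D estimator recovers
  the true OU diffusivity within 15% (pooled over replicate 10⁵-sample
  windows, whose individual noise is ~20%).
* Oracle equivalence: for every preset × curvature, the full pipeline at
  the default study scale must agree with `analytic_permeability` within a
  factor of 1.3.  Single studies scatter with σ_log P ≈ 0.1–0.2 (the
  information limit of 200 ns windows against ~100 kJ/mol barriers), so
  the check compares the geometric mean over five replicate studies —
  the quantity the factor bounds is the method's accuracy, not one draw's
  luck.
* Qualitative curvature trends: bent presets are never less permeable than
  flat; recovered PMF peaks shift toward the concave monolayer with the
  stated sign convention; resistance concentrates within |z| < 1 nm.

## What the synthetic data do and do not show

The generator reproduces the *structure* of the analysis problem:
metastable interfacial wells, a dominant central barrier of the right
scale, order-of-magnitude diffusivity contrast, autocorrelated biased
sampling, curvature-induced barrier scaling and peak shifts.  It does not
attempt real lipid chemistry: no leaflet compositional asymmetry beyond
the two curvature parameters, no curvature response of D(z), no memory
effects (the dynamics are strictly Markovian and overdamped), and no
force-field or finite-size artefacts.  Passing tests therefore demonstrate
that the estimators are correct and well-calibrated for data of this
structure — not that any particular absolute permeability of a real
membrane is reproduced.

## Known limitations

* The ISD model itself assumes a separable 1-D reaction coordinate and
  position-local diffusion; it is used here as the standard pragmatic
  choice, and results should be compared across conditions (e.g.
  curvatures) rather than across chemically different solutes.
* Moving-block bootstrap bands are mildly anticonservative (see above).
* The D estimator inherits its OU assumption; near barrier tops it is an
  effective local value rather than a point measurement.
* WHAM assumes uncorrelated counts within bins; autocorrelation is handled
  only through the bootstrap, not through per-window effective sample
  sizes.
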