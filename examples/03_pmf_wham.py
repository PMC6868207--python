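"""Reconstruct a potential of mean force by WHAM, with bootstrap bands.

Generates a demo-scale umbrella dataset on the water-like preset, solves
the WHAM equations and prints the recovered barrier height and peak
position against the ground truth, plus the moving-block-bootstrap
uncertainty near the barrier top.
"""

import numpy as np

import curvperm as cp

model = cp.preset("water", 0.2)
windows = cp.generate_umbrella_dataset(
    model, cp.default_window_centers(model), n_steps=150_000, seed=7)

pmf = cp.bootstrap_pmf(windows, n_boot=16, seed=7)
print(f"WHAM converged in {pmf.meta['iterations']} iterations "
      f"(residual {pmf.meta['residual_kJ_mol']:.1e} kJ/mol, "
      f"{pmf.n_gaps} gap bins)")

barrier = cp.barrier_height(pmf)
peak = cp.peak_position(pmf)
true_barrier = model.pmf(np.array([model.effective_peak]))[0]
sig_top = pmf.sigma[np.nanargmax(pmf.values)]
print(f"barrier: {barrier:.1f} ± {sig_top:.1f} kJ/mol "
      f"(ground truth {true_barrier:.1f})")
print(f"peak position: {peak:+.2f} nm (ground truth {model.effective_peak:+.2f};"
      " shifted toward the concave monolayer at z<0)")
# Bootstrap bands quantify how umbrella-sampling noise propagates into the
# profile; the barrier estimate should sit within ~2 bands of the truth.
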