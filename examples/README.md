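# Examples

Short narrative scripts, one per capability; each builds a small input,
runs the method and prints what it computes.  Run from the repository root:

```sh
python examples/01_model_landscapes.py     # presets, curvature, exact ISD oracle
python examples/02_simulate_umbrella.py    # Brownian-dynamics umbrella dataset -> files
python examples/03_pmf_wham.py             # WHAM PMF with bootstrap bands
python examples/04_diffusion_profile.py    # position-dependent D(z) estimation
python examples/05_permeability_pipeline.py  # end-to-end P with error propagation
python examples/06_curvature_tables.py     # cross-curvature comparison tables
```

All scripts run at demo scale (seconds to ~1 minute each) and print the
ground truth next to every estimate where one exists.
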