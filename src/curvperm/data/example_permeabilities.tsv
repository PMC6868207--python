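# Reference permeability coefficients (m/s) with 1-sigma uncertainties for
# small hydrophilic permeants crossing an asymmetric cholesterol-rich
# plasma-membrane model, flat and cylindrically bent (curvature in 1/nm;
# positive = outer monolayer convex).  Input fixture for the `compare`
# workflow; ratios vs the flat membrane are computed by the package.
ligand	curvature	value	sigma
water	0.0	2.5e-6	3.6e-8
water	0.2	5.5e-6	7.2e-8
water	-0.2	3.7e-6	5.3e-8
Na+	0.0	1.5e-17	1.2e-18
Na+	0.2	8.4e-17	6.9e-18
Na+	-0.2	1.7e-15	1.3e-16
Cl-	0.0	4.6e-17	2.4e-18
Cl-	0.2	1.5e-16	8.7e-18
Cl-	-0.2	6.4e-16	3.3e-17
CPT	0.0	2.3e-12	6.2e-14
CPT	0.2	5.0e-11	1.6e-12
CPT	-0.2	7.0e-12	3.1e-13
Gem	0.0	8.3e-14	3.6e-15
Gem	0.2	1.4e-11	4.2e-13
Gem	-0.2	4.5e-12	1.5e-13
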