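# Reference maximal free-energy barrier heights (kJ/mol) for small hydrophilic
# permeants crossing an asymmetric cholesterol-rich plasma-membrane model,
# for a flat membrane and two cylindrically bent states (curvature in 1/nm;
# positive = outer monolayer convex).  Input fixture for the `compare`
# workflow; relative heights are computed by the package, not stored here.
ligand	curvature	value
Na+	0.0	101.1
Na+	0.2	98.3
Na+	-0.2	92.7
Cl-	0.0	101.6
Cl-	0.2	96.4
Cl-	-0.2	93.4
water	0.0	31.4
water	0.2	30.2
water	-0.2	29.9
CPT	0.0	70.1
CPT	0.2	63.1
CPT	-0.2	66.7
Gem	0.0	77.5
Gem	0.2	64.8
Gem	-0.2	67.6
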