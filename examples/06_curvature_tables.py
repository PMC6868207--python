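"""Cross-curvature comparison tables from the packaged reference values.

Loads the packaged barrier-height and permeability tables (flat membrane
plus curvatures of +/-0.2 1/nm) and renders them with relative barrier
heights and permeability ratios versus the flat membrane — the layout used
to summarize curvature effects across permeants.
"""

from importlib.resources import files

import pandas as pd

import curvperm as cp

data = files("curvperm.data")
barriers = pd.read_csv(data / "example_barriers.tsv", sep="\t", comment="#")
perms = pd.read_csv(data / "example_permeabilities.tsv", sep="\t", comment="#")

bt = cp.curvature_table(barriers.to_dict("records"), quantity="barrier")
pt = cp.curvature_table(perms.to_dict("records"), quantity="permeability")

print(bt.render())
print()
print(pt.render())
print()
print("Bending always lowers the barrier (relative heights < 1) and raises")
print("the permeability (ratios > 1); which bending sign helps more depends")
print("on the permeant.")
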