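"""Phenotype phase plane: growth rate over acetate x CO2 uptake.

Scans the demonstration network under the mixotrophic preset, fixing both
exchange fluxes cell by cell.  Each matrix entry is the biomass optimum
(1/h); the maximum sits at the corner of largest allowed uptake of both
substrates, and growth responds additively to the two carbon sources here.
"""

import numpy as np

from chlamydyn import ScanSpec, condition_preset, demo_network, scan, summarize_optimum

net = demo_network()
spec = ScanSpec(
    axis1=("EX_ac_e", -10.0, 0.0, 6),
    axis2=("EX_co2_e", -12.0, 0.0, 5),
    condition=condition_preset("mixotrophic"),
)
res = scan(net, spec)

print("acetate flux (rows) x CO2 flux (columns), mu in 1/h:")
header = "        " + "  ".join(f"{v:6.1f}" for v in res.grid2)
print(header)
for v1, row in zip(res.grid1, res.mu):
    print(f"{v1:6.1f}  " + "  ".join(f"{m:6.3f}" for m in row))

opt = summarize_optimum(res)
i, j = opt.argmax_cells[0]
print(f"\noptimum mu = {opt.max_mu:.3f} 1/h at acetate flux {res.grid1[i]:.1f}, "
      f"CO2 flux {res.grid2[j]:.1f} (plateau of {int(np.sum(opt.plateau_mask))} cell(s))")
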