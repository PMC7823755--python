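"""Generate a synthetic multibreed dairy-goat herd and inspect its structure.

The generator emulates a Saanen-dominated seasonal herd: a small sire pool,
mostly unphenotyped base dams, crossbred does with one 305-day lactation
record each, and SNP genotypes on roughly half of the does.  Ground truth
(true breeding values, QTL effects, variance components) rides along.
"""

import numpy as np

from goatbv import SimulationConfig, heterosis, simulate_herd

herd = simulate_herd(SimulationConfig(n_does=400, n_markers=500, seed=11))

ped = herd.pedigree
does = [r.animal_id for r in herd.records]
sires = {ped.parents(a)[0] for a in does} - {""}
milk = np.array([r.milk_yield for r in herd.records])
het = np.array([heterosis(herd.composition, a) for a in does])
bv = np.array([herd.truth.true_bv[a] for a in does])

print(f"pedigree animals: {ped.n}  phenotyped does: {len(does)}")
print(f"sires in use: {len(sires)}  genotyped does: {len(herd.genotyped_ids)}")
print(f"milk yield mean {milk.mean():.0f} kg, sd {milk.std():.0f} kg")
print(f"mean heterosis covariate {het.mean():.3f} (0 = purebred, 0.5 = F1)")
print(f"true breeding value sd {bv.std():.0f} kg "
      f"(parametric genetic sd {np.sqrt(herd.truth.sigma_g2_total):.0f} kg)")
# The phenotypic sd should exceed the genetic sd by roughly 1/sqrt(h2):
# with h2 = 0.25 the ratio of the two numbers above is about 2.
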