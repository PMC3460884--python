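"""Cross-validated fitting and TSS evaluation of the six model families.

Fits every method on one virtual species under 5 repeated stratified
75/25 splits, thresholds each model's scores on the ROC curve, and
prints the mean validation True Skill Statistic per method.  TSS = 1 is
a perfect prediction; 0 is no better than random.
"""

import pandas as pd

from ensemblesdm import (
    cross_validate_species,
    derive_bioclim,
    generate_climate,
    generate_virtual_species,
)

current, _ = generate_climate((20, 20), 1, 1, seed=5)
clim = derive_bioclim(current)
species, occ = generate_virtual_species(1, clim, seed=5)

records = cross_validate_species(
    occ.species[0], occ.values[0].astype(int), clim.matrix(), k=5, seed=5
)
df = pd.DataFrame(
    [{"method": r.method, "repeat": r.repeat, "threshold": r.threshold,
      "tss": r.tss} for r in records]
)
print(f"species {occ.species[0]}: {occ.values[0].sum()} presences "
      f"on {clim.grid.n_cells} cells\n")
print(df.groupby("method")[["threshold", "tss"]].mean().round(3))
print("\nEach row is a model family's mean ROC threshold and mean "
      "held-out TSS over 5 repeats; skilled families score well above 0.")
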