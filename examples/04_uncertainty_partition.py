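"""Partitioning forecast disagreement with ANOVA without replication.

First decomposes a tiny worked table by hand, then runs a small pipeline
and attributes the per-cell variation in forecast richness to modelling
methods, climate models and emission scenarios.
"""

import numpy as np

from ensemblesdm import anova_ss, run_pipeline

table = np.array([[1.0, 2.0], [3.0, 4.0]])
ss = anova_ss(table, ["rows", "cols"])
print("2x2 worked example [[1,2],[3,4]]:")
for k, v in ss.items():
    print(f"  SS_{k:8s} = {v:.1f}")
print("rows explain 4/5 of the variation, columns 1/5, no interaction.\n")

res = run_pipeline({
    "n_rows": 12, "n_cols": 12, "n_species": 3,
    "methods": ["GLM", "GAM", "RF"], "climate_models": ["GCM1", "GCM2"],
    "k_repeats": 3, "seed": 4,
})
print("pooled attribution of forecast-richness variation (percent):")
for factor, pct in res.attribution.items():
    print(f"  {factor:14s} {pct:6.1f}")
print("\nMethod choice typically dominates the disagreement, echoing the "
      "usual ranking method >> climate model > scenario.")
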