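"""Fixed-effects descriptions of GEI on a two-way table of means.

Simulates a maize-like multi-environment trial, then walks through the
additive ANOVA benchmark, Finlay-Wilkinson joint regression, and the
AMMI bilinear decomposition with biplot coordinates.
"""

import numpy as np

import gxetools as g

spec = g.maize_stress_spec(seed=1)
_, _, table, _ = g.simulate_dataset(spec)
print(f"table: {table.n_genotypes} genotypes x {table.n_environments} environments\n")

# additive benchmark: everything not in the main effects lands in the
# residual, which on a table of means is GEI confounded with error
print("additive model ANOVA")
print(g.fit_additive(table).to_frame().round(2).to_string(index=False))

# joint regression: one slope per genotype on the environment index.
# b' > 1 marks genotypes that exploit good environments more than average
fw = g.fit_finlay_wilkinson(table)
print("\nFinlay-Wilkinson: interaction split into slopes + residual")
print(fw.anova.to_frame().round(2).to_string(index=False))
extremes = fw.slopes_prime.sort_values()
print(f"least responsive genotype:  {extremes.index[0]} (b' = {extremes.iloc[0]:.2f})")
print(f"most responsive genotype:   {extremes.index[-1]} (b' = {extremes.iloc[-1]:.2f})")

# AMMI: SVD of the double-centered table; two axes usually suffice
ammi = g.fit_ammi(table, 2)
explained = ammi.axis_ss.sum() / (ammi.axis_ss.sum() + ammi.residual_ss)
print(f"\nAMMI2 explains {100 * explained:.0f}% of the interaction SS")
gcoord, ecoord, _ = g.biplot_coords(ammi)
print("environment biplot coordinates (symmetric scaling):")
print(ecoord.round(2))
print(
    "environments whose axes point the same way interact similarly;\n"
    "a genotype projecting above an environment's origin has positive GEI there"
)
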