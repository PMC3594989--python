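"""Generate a synthetic multi-environment QTL data set and write it out.

The preset mimics the scale of a published maize stress experiment
(211 F2 families, 10 chromosomes, 132 markers, 8 environments with
heterogeneous residual variance, one crossover QTL).  All files are
plain CSV in the formats the loaders read back.
"""

from pathlib import Path

import gxetools as g

out = Path("scratch/simulated")
out.mkdir(parents=True, exist_ok=True)

spec = g.maize_stress_spec(seed=0)
gmap, markers, table, truth = g.simulate_dataset(spec)

g.save_genetic_map(gmap, out / "map.csv")
g.save_marker_matrix(markers, out / "markers.csv")
g.save_gxe_table(table, out / "phenotypes.csv", layout="long")
truth.rename_axis("individual").to_csv(out / "truth.csv")

print(f"wrote {out}/map.csv        ({len(gmap.markers)} markers, "
      f"{len(gmap.chromosomes)} chromosomes)")
print(f"wrote {out}/markers.csv    ({len(markers.individuals)} individuals; "
      "codes A/H/B/C/D/-)")
print(f"wrote {out}/phenotypes.csv ({table.n_genotypes} x "
      f"{table.n_environments} means, long layout)")
print(f"wrote {out}/truth.csv      (true allele counts at "
      f"{truth.shape[1]} QTLs, for recovery checks)")

missing = (markers.scores.to_numpy() == "-").mean()
print(f"\nmarker degradation: {100 * missing:.1f}% missing scores")
print("reload with load_genetic_map / load_marker_matrix / load_gxe_table,")
print("or run the same thing from the shell:  gxetools simulate --seed 0 --out DIR")
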