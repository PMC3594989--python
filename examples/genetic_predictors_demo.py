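"""From incomplete marker scores to genetic predictors.

Shows how the chromosome HMM turns codominant, dominant and missing
marker observations into conditional genotype probabilities, and how
those become the additive (expected paternal allele count) and
dominance (heterozygosity probability) predictors used in QTL models.
"""

import pandas as pd

import gxetools as g

gmap = g.GeneticMap(pd.DataFrame({
    "marker": ["m1", "m2", "m3"],
    "chromosome": ["1", "1", "1"],
    "position_cM": [0.0, 15.0, 40.0],
}))

# three F2 individuals: fully observed, dominant-coded, missing middle
markers = g.MarkerMatrix(pd.DataFrame(
    [["B", "H", "A"],    # codominant everywhere
     ["C", "D", "-"],    # 'C' = not-A, 'D' = not-B: dominant scores
     ["B", "-", "B"]],   # middle marker missing
    index=["ind1", "ind2", "ind3"], columns=["m1", "m2", "m3"],
), population_type="F2")

for pos in [0.0, 7.5, 15.0, 27.5]:
    triples = g.conditional_probs(markers, gmap, ("1", pos))
    print(f"position 1@{pos:g} cM  P(M1M1), P(M1m1), P(m1m1):")
    for ind, t in zip(markers.individuals, triples):
        print(f"  {ind}: ({t[0]:.3f}, {t[1]:.3f}, {t[2]:.3f})")

preds = g.genetic_predictors(markers, gmap, g.make_grid(gmap, 5.0))
print("\nadditive predictor X_add (expected # paternal alleles, 0..2):")
print(preds.x_add.round(2).to_string())
print("\ndominance predictor X_dom (heterozygosity probability, 0..1):")
print(preds.x_dom.round(2).to_string())
print(
    "\nat an observed codominant marker the predictor is the exact allele\n"
    "count; between markers and under dominant/missing scores it shrinks\n"
    "toward the population expectation (1 and 0.5 in an F2)"
)
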