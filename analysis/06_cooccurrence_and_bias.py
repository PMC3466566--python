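#!/usr/bin/env python
"""Gene co-occurrence across synthetic operons and the plasmid-bias regression.

Co-occurrence uses Pearson R on 0/1 columns (the phi coefficient) with
permutation p-values. The bias regression fits percent-with-plasmids against
percent-chromosome-only, both for the synthetic catalog and for the published
survey's 16 printed percent pairs (expected slope slightly above 1: several
transport genes ride plasmids).
"""

from pathlib import Path

from merphylo import cooccurrence_matrix, plasmid_bias_regression
from merphylo.matrixstats import bias_regression_from_pairs
from merphylo.survey import survey_percent_pairs
from merphylo.traits import read_operon_table

OUT = Path("results/cooccurrence")
OUT.mkdir(parents=True, exist_ok=True)

catalog = read_operon_table("results/synthetic/operon_catalog.tsv")
res = cooccurrence_matrix(catalog, n_perm=999, seed=1)
with open(OUT / "cooccurrence.tsv", "w") as fh:
    fh.write("# Pearson R\n")
    res.r.round(3).to_csv(fh, sep="\t")
    fh.write("# permutation p\n")
    res.p.round(3).to_csv(fh, sep="\t")
print("synthetic-catalog co-occurrence (R):")
print(res.r.round(2).to_string())

slope, intercept, pairs = plasmid_bias_regression(catalog)
print(f"\nsynthetic catalog bias regression: slope={slope:.3f}, "
      f"intercept={intercept:.2f}")

slope_s, intercept_s, pairs_s = bias_regression_from_pairs(survey_percent_pairs())
pairs_s.to_csv(OUT / "survey_bias_pairs.tsv", sep="\t", index=False)
enriched = ", ".join(pairs_s.loc[pairs_s.plasmid_enriched, "trait"])
print(f"published survey pairs:         slope={slope_s:.3f}, "
      f"intercept={intercept_s:.2f}")
print(f"plasmid-enriched genes (above the 1:1 line): {enriched}")
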