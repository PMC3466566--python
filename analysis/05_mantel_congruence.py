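#!/usr/bin/env python
"""Mantel congruence between the gene tree and the species tree.

Patristic (singleton Rao) dissimilarities on the chromosomal taxa of each
tree; a high permutation r indicates predominantly vertical inheritance of
the gene.
"""

from pathlib import Path

from merphylo import mantel, patristic_matrix, prune, read_newick_file
from merphylo.traits import read_operon_table, subset_by_replicon

OUT = Path("results/mantel")
OUT.mkdir(parents=True, exist_ok=True)

gene = read_newick_file("results/smooth/gene_chronogram.nwk")
species = read_newick_file("results/synthetic/species_tree.nwk")
catalog = read_operon_table("results/synthetic/operon_catalog.tsv")
chrom = set(subset_by_replicon(catalog, "chromosome").taxa)
shared = [t for t in gene.tip_labels if t in chrom]

d_gene = patristic_matrix(prune(gene, shared)).submatrix(shared)
d_species = patristic_matrix(prune(species, shared)).submatrix(shared)
res = mantel(d_gene, d_species, n_perm=999, seed=1)
print(f"Mantel r = {res.r:.3f}, p = {res.p:.4f} "
      f"({res.n_labels} chromosomal taxa, {res.n_permutations} permutations)")
with open(OUT / "mantel.tsv", "w") as fh:
    fh.write("r\tp\tn_labels\tn_permutations\n")
    fh.write(f"{res.r:.4f}\t{res.p:.4f}\t{res.n_labels}\t{res.n_permutations}\n")
print(f"wrote {OUT / 'mantel.tsv'}")
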