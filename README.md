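# merphylo

Comparative phylogenetics of mercury-resistance (*mer*) operon gene content.

Microbial mercury detoxification is organized as an operon around the mercuric
reductase gene *merA*, with a variable complement of regulatory (*merR*,
*arsR*, *merD*), Hg binding/transport (*merP*, *merT*, *merC*, *merF*, *merE*,
*merH*, TRASH) and organomercury (*merB*, *merG*) genes. How that complement
evolved — vertical descent, plasmid-borne lateral transfer, gene loss — can be
read off a MerA gene tree: genes inherited vertically cluster in clades, genes
that ride plasmids scatter across them. `merphylo` is for microbial ecologists
and molecular evolution researchers who want to run that analysis end to end:

- **Operon complexity index** — the fraction of the 13 scored *mer* gene types
  an operon carries (`k/13`, so 0.077 for a bare *merA* operon).
- **Blomberg's K** for presence/absence traits on a tree, with a tip-shuffling
  permutation test on the variance of phylogenetically independent contrasts.
  `K = (MSE0/MSE) / E_BM[MSE0/MSE]` with `MSE0` the variance of tip values
  about the GLS phylogenetic mean `â = (1'C⁻¹x)/(1'C⁻¹1)`, `MSE` the GLS
  mean-squared error under the Brownian covariance `C`, and
  `E_BM[MSE0/MSE] = [tr(C) − n/(1'C⁻¹1)]/(n−1)`. K ≈ 1 under Brownian motion;
  K → 0 for random or convergent traits.
- **With/without-plasmid differential K** — paired signal per gene on the full
  tree versus the chromosomal-only tree; positive ΔK marks genes whose vertical
  signal is diluted by plasmid-borne operons.
- **Penalized-likelihood rate smoothing** — phylogram → ultrametric chronogram
  by minimizing `−Σ[b_j log(r_j t_j) − r_j t_j] + λ·roughness(r)` (roughness =
  squared rate changes between adjacent branches plus the variance of the
  root-child rates), root age normalized to 1.
- **Mantel congruence** between gene-tree and species-tree (Rao/patristic)
  distance matrices, with permutation p-values.
- **Trait co-occurrence** — pairwise Pearson R on 0/1 columns (the phi
  coefficient) with permutation p-values, and the plasmid-bias regression of
  per-gene percentages with vs without plasmid operons.
- A fully seeded **synthetic-data generator** (Yule chronograms, Brownian
  liability traits, lateral transfer, loss, plasmid subsets) so every stage is
  testable without downloads.

## Worked example

Simulate a 64-operon dataset with plasmid-restricted lateral transfer, smooth
the gene tree, and measure the differential signal (the `analysis/` scripts run
exactly this, step by step):

```sh
merphylo simulate --n-tips 64 --lgt-rate 0.3 --loss-rate 0.05 \
    --plasmid-fraction 0.2 --plasmid-multiplier 10 --seed 1 --outdir sim
merphylo run-all --gene-tree sim/gene_tree.nwk \
    --operon-table sim/operon_catalog.tsv --outdir out --seed 1 --n-perm 999
```

or in Python, mirroring `analysis/04_phylogenetic_signal.py`, which prints:

```
with/without-plasmid differential (sorted by delta):
trait  K_with  p_with  K_without  p_without  delta_k
 merB   0.045   0.493      0.585      0.001    0.541
 merP   0.037   0.484      0.229      0.006    0.193
 merC   0.091   0.145      0.264      0.006    0.173
 merT   0.031   0.613      0.179      0.027    0.148
 merD   0.111   0.088      0.156      0.086    0.045
```

Read: with plasmid operons included every gene looks unstructured (K ≤ 0.11,
none significant); excluding them recovers significant clade-level signal for
four of five genes. That is the signature of plasmid-borne transfer obscuring
vertical inheritance. `analysis/05_mantel_congruence.py` on the same dataset
reports `Mantel r = 0.996, p = 0.0010` between gene-tree and species-tree
distances, and `analysis/07_calibration.py` verifies the machinery: mean
K = 0.995 over 200 continuous Brownian traits and a 4.2% type-I error rate at
the nominal 5% level.

The published survey counts for 272 *mer* operons (53 plasmid-borne) ship with
the package: `analysis/01_survey_percentages.py` reproduces every percent cell
from its own presence/absence counts, and `analysis/06_cooccurrence_and_bias.py`
fits the plasmid-bias regression over the 16 printed percent pairs
(slope 1.058 — transport genes sit above the 1:1 line).

## Layout

- `src/merphylo/` — the library: `treeio` (Newick, patristic/VCV matrices),
  `chronos` (rate smoothing), `traits` (operon catalog), `physignal`
  (K + permutation tests), `matrixstats` (Rao, Mantel, co-occurrence, bias
  regression), `synthetic` (generator), `survey` (published counts),
  `experiments`, `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers writing tables under `results/`.
- `docs/methods.md` — models, assumptions, numerical choices, limitations.
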