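# Methods

## Data model

An **operon catalog** has one row per *mer* operon — not per genome, since some
genomes carry two or three operons — with a taxon label joining it to a tree
tip, a genome id, a replicon (`chromosome`/`plasmid`), and a 0/1 column per
scored trait. Thirteen **core gene types** enter the complexity denominator:
merA, arsR, merR, merP, merT, merC, merF, merE, merG, merH, merB, merD, TRASH.
The orientation/copy variants (merR convergent/divergent/multiple, merB
multiple) are auxiliary traits: analyzable, never counted toward complexity,
with core merR defined as convergent OR divergent. The survey literature never
enumerates the thirteen types behind its divisor; including merA itself and
collapsing the merR variants is this package's inference (it is the unique
reading that yields exactly 13), and the registry is configurable.

**Trees** are rooted phylograms with unique non-empty tip labels and
non-negative branch lengths. Tip order is first-encounter (left-to-right
Newick) order and is canonical for all matrices and permutations. Missing
branch lengths are an error unless explicitly defaulted — silent defaults
corrupt distance matrices. Zero-length branches are permitted; contrasts
extend them by a configurable epsilon (1e-8).

## Rate smoothing (chronos)

Trait-based statistics assume branch lengths proportional to time, so the
input phylogram is converted to an ultrametric chronogram by penalized
likelihood. With input lengths `b_j`, estimated durations `t_j` and rates
`r_j`, the objective is

    minimize  −Σ_j [ b_j·log(r_j·t_j) − r_j·t_j ]
              + λ·[ Σ_{j: parent edge} (r_j − r_parent(j))² + Var(root-child rates) ]

over node ages (root fixed, default 1.0: relative evolutionary units; tips at
0) and per-branch rates. λ defaults to 0.8 with up to 1000 iterations. The
root-child variance term is required, not cosmetic: without it the root's two
subtrees decouple, and each can rescale its rates against its subtree-root age
along an exactly flat ridge (`a·r = h`), destroying identifiability.

Numerics: ages are parameterized as fractions of the parent age (preorder),
rates in log space, both box-constrained; the optimizer is L-BFGS-B with
analytic gradients (the profiled likelihood is flat in ages — only the
roughness term identifies them — so finite-difference gradients stall).
Initialization is deterministic: ages from node heights rescaled to the root
age, rates from `b_j/t_j`. Zero-length input branches contribute via the
convention `0·log(·) = 0`. The returned objective never exceeds the
initialization's, and the optimum is validated in the tests against an
independent vectorized grid search on 3-tip instances rather than against any
particular optimizer.

## Phylogenetic signal (physignal)

Presence/absence is scored as numeric 0/1 with no continuity correction. K is
computed by two independent routes — a dense C-matrix route (`tr(C)`,
`1'C⁻¹1`, GLS residuals, with a ridge of `1e-12·tr(C)/n` only if C is
numerically singular) and a Felsenstein-pruning route in which the contrasts
are assembled as a linear operator `L` with `contrasts = L·x`,
`â = w·x` and `1'C⁻¹1 = 1/v_root` — and the two agree to 1e-10 on random
trees (a standing property test).

The permutation test shuffles taxa labels uniformly across tips. Its statistic
is the **PIC variance**, defined here as the mean squared standardized
contrast `Σc²/(n−1)` (the Brownian rate estimator; contrasts have expectation
zero under the null, so no mean is subtracted). Significance means *low*
observed contrast variance; ties count as extreme, and the p-value uses the
add-one rule `(1+count)/(1+n_perm)`, so p ≥ 1/(n_perm+1) always. Each trait
draws its random stream from the master seed plus a CRC of the trait name, so
multi-trait tables are independent of column order. Raw p-values are reported
by default (an optional Benjamini–Hochberg column is available); 1000
permutations is the default.

The differential report runs both replicon arms with the same seed policy and
sorts by `ΔK = K_without_plasmids − K_with_plasmids`.

## Matrix statistics (matrixstats)

Rao dissimilarity between weighted tip groups is `D_ij = Σ_kl p_ik p_jl d(k,l)`
over patristic distances; singleton groups reduce exactly to patristic
distance. The returned matrix keeps a zero diagonal (so it remains a valid
dissimilarity object); the within-group quadratic entropy is exposed
separately. Mantel correlation is Pearson over upper-triangle entries with
joint row/column permutations of the second matrix, one-sided (greater) by
default because the scientific claim is directional positive congruence; a
two-sided flag exists. Co-occurrence is Pearson on 0/1 columns — identical to
the phi coefficient of the 2×2 table — with two-sided permutation p-values.
The plasmid-bias regression rounds both percentages half-up to one decimal
*before* fitting, so a printed summary table reproduces the fit inputs
exactly; an empty plasmid class degenerates to the 1:1 line, while an empty
chromosomal class is an error (the x-axis would be undefined).

Percent cells everywhere use decimal half-up rounding to one decimal, which
reproduces every published percent cell from its own counts.

## Synthetic data (synthetic)

The generator emulates exactly the processes the analysis is meant to detect:

- **Species tree**: Yule (or birth–death) chronogram, root age 1. The
  simulator conditions on the tip count and then runs time forward by the
  waiting time to the next event, so no zero-length cherry is produced.
- **Gene tree**: same topology with per-branch lognormal rate factors
  (sdlog 0.3) — a realistic non-clock input for the smoother.
- **Traits**: Brownian liability on the species chronogram, thresholded so the
  top `⌈prevalence·n⌉` tips are present (ties broken by tip order); then
  lateral transfer as a Poisson(rate × total branch length) number of
  copy-donor-state-onto-recipient events; then independent loss of presences.
  Transfer acts on trait states only — topology transfer is out of scope, and
  state-level transfer suffices to produce the ΔK depression the analysis
  interprets.
- **Plasmids**: a fixed fraction of operons (default 0.2, the survey's 53/272
  share) is plasmid-borne and receives extra transfer events bringing its rate
  to `multiplier × base`.

Defaults are the package's study conditions: 64 tips, σ² = 1 (irrelevant after
thresholding), prevalence 0.5, five traits plus an always-present merA,
multiplier 10, loss 0.05, transfer rate 0.3 in the transfer condition. All
stages draw from seeds spawned off the master seed; identical config + seed
gives byte-identical files.

What the generator does *not* emulate: sequence evolution and tree estimation
error, topology-changing transfer, correlated gain/loss between genes,
lineage-specific prevalence, and plasmid phylogenies. Passing tests therefore
show the statistics behave correctly on trees of this scale under the stated
processes — not that any particular real dataset satisfies those assumptions.

## Published survey inputs

The printed per-trait presence/absence counts of a December-2011 survey of 272
*mer* operons (53 plasmid-borne, 246 genomes, 23 of them multi-operon) ship
with the package. `build_survey_catalog` expands them into a **synthetic**
catalog whose row counts, replicon split, genome multiplicities and per-trait
marginals all match the survey, with the merR orientation variants assigned
disjointly so core merR reproduces its own counts, and the genome
multiplicities forced by arithmetic (3×3 + 20×2 + 223×1 = 272). The joint
operon-by-operon gene content is an arbitrary marginals-consistent assignment:
it supports count and percentage computations, but gene–gene co-occurrence on
it reflects the assignment, not biology — that requires the full per-operon
supplementary catalog, which is not redistributed here.

## Known limitations

- **Discrete-trait K is sample-size dependent.** For thresholded-liability
  binary traits, expected K rises as tips are removed (continuous Brownian
  traits show no such shift). The with/without-plasmid contrast compares arms
  of different sizes, so even with zero transfer the chromosomal arm sits
  slightly ahead: at 64 tips and a 0.2 plasmid fraction the zero-transfer mean
  ΔK is ≈ +0.05–0.12, with a 95% CI excluding 0. A ΔK attributable to
  plasmid transfer must therefore exceed this offset; the calibration driver
  and the acceptance script report both conditions side by side.
- K values here are small in absolute terms for binary traits (well below 1
  even under pure vertical inheritance at prevalence 0.5); interpretation
  should be comparative (between arms, against the permutation null), not
  against the K = 1 Brownian benchmark.
- The smoother fits a fixed λ; cross-validation and fossil/tip-date
  calibrations are out of scope.
- Newick round-trips are canonical at 10 significant digits; trees with
  support values as internal labels are read, and the labels ignored.
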