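# Methods

## Scope and data model

`rhizonet` analyses an OTU count table (samples × OTUs) with per-sample
metadata (compartment: root endosphere `G` / rhizosphere soil `T`; host
species; replicate), QIIME-style seven-rank taxonomy lineages per OTU, a
per-sample soil-chemistry table and a guild reference table. It does not
touch reads: quality control, merging, OTU picking and taxonomic
assignment are upstream concerns of established tools, and the package
starts where they end.

## Diversity

All samples are rarefied to a common depth (default: the minimum library
size) by multivariate-hypergeometric subsampling without replacement, so
per-OTU marginal expectations are `depth/total × count`. Indices follow
the Mothur conventions: Shannon in natural-log units over nonzero
proportions, Pielou evenness H/ln S (defined as 1 when S = 1, the 0/0
case), Good's coverage 1 − F₁/N with F₁ the singleton count. Group
contrasts are nonparametric throughout: the two-sided Wilcoxon rank-sum
test uses exact enumeration when both groups have n ≤ 10 and the pooled
data is tie-free, otherwise the normal approximation with tie-corrected
variance and continuity correction; three or more groups use the
tie-corrected Kruskal–Wallis H with a χ² reference on k − 1 df. Two-sided
tests are used everywhere. No multiple-testing correction is applied
inside the alpha-diversity module; the per-taxon contrasts run by the
pipeline (top 15 taxa per rank by mean relative abundance) report raw
p-values alongside Benjamini–Hochberg adjusted ones.

## Ordination and PERMANOVA

Bray–Curtis dissimilarity BC(u, v) = Σ|uᵢ−vᵢ| / Σ(uᵢ+vᵢ) is computed on
(rarefied) counts. PCoA is the classical eigendecomposition of the
Gower-centred matrix −½ J D² J; negative eigenvalues are reported but not
corrected (no Lingoes/Cailliez), coordinates are eigenvectors scaled by
√λ over positive eigenvalues only, and axis percentages are fractions of
the positive-eigenvalue sum. PERMANOVA is single-factor: SS_total =
Σ_{i<j} d²ᵢⱼ/n, SS_within from within-group pairs, pseudo-F =
(SS_b/(k−1))/(SS_w/(n−k)), and p = (1 + #{F_perm ≥ F_obs})/(1 + B) under
B label permutations (default 999, seeded). The study's two groupings
(compartment, species) are analysed as separate single-factor runs.

## Guild annotation

Each OTU is matched against the reference at the most specific resolved
rank (species before genus before family, …), case-insensitively; the
first hit wins. Records whose guild string contains two or more
`|`-separated guilds are excluded from guild abundances (the single-guild
rule); compound trophic modes such as `pathotroph-saprotroph` on
single-guild records are kept under the compound label to avoid double
counting. The confidence ranking is carried through but not filtered on by
default; a `min_confidence` flag is provided. Unassigned and excluded
mass is tracked explicitly so included + excluded + unassigned OTU counts
always partition the table.

## Co-occurrence networks and node roles

Networks are built per compartment (the biological contrast of interest),
over OTUs whose total read proportion is strictly above 0.005% of that
compartment's table. Edges connect OTU pairs whose Spearman correlation of
relative abundances satisfies |ρ| ≥ 0.6 with BH-adjusted p < 0.05; the
correlation sign is kept as an edge attribute and isolated nodes are
dropped. The correlation statistic, threshold, α and adjustment are all
configurable; the defaults are the common community choice for OTU
co-occurrence analysis. Modularity and node roles are computed on the
unsigned, unweighted graph. Modules come from greedy agglomerative
(Clauset–Newman–Moore) modularity maximisation, deterministic for a given
graph, with module ids relabelled by descending size. For each node, Zi is
the z-score of its within-module degree against the other members of its
module (population SD; Zi = 0 when the SD is 0) and Pi = 1 − Σₜ (kᵢₜ/kᵢ)².
Roles use strict inequalities at Zi = 2.5 and Pi = 0.62 — boundary values
fall to the lower class — giving peripherals, connectors (Pi > 0.62),
module hubs (Zi > 2.5) and network hubs (both); non-peripheral nodes are
keystone candidates and keystone sets can be intersected across networks
by role.

Whether rarefaction should precede network construction is not settled
practice; the pipeline rarefies before networks by default and exposes
`rarefy_networks: false` to build them from raw counts instead.

## OTU–environment association

The bipartite network correlates each abundant OTU with each soil factor
under the same |ρ|/BH thresholds (BH across all OTU × factor tests);
factor degree is its number of incident edges. The diversity regression is
per-factor simple OLS of Shannon on the factor (slope, intercept, R²,
two-sided slope t-test on n − 2 df), run separately per compartment by
default; for simple regression R² equals the squared Pearson correlation.

## Synthetic data generator

The generator emulates the 2-compartment × 4-species × 3-replicate design
(24 samples, 30,000 reads each, 200 endosphere / 500 rhizosphere OTUs) and
plants, per compartment network:

* **one star module** (hub + 9 spokes, the hub-per-module count and sizes
  configurable): the hub correlates with every spoke at ~0.8 while
  spoke–spoke correlations stay below the 0.6 edge gate, so the recovered
  module is a star and the hub's within-module degree z-score is
  ≈ √(star size − 1) ≈ 3;
* **three near-clique modules** of 16 members each (two per clique
  anti-correlated, providing negative edges), members sharing their module
  factor so pairwise correlations land near the configured
  `module_within_corr` (default 0.8);
* **three connector OTUs**, shared between the compartments' OTU sets,
  correlated with all three clique modules at once through a common
  direction in the clique factors plus a near-centre "gateway" member per
  clique — their recovered edges spread over three modules and the
  participation coefficient lands near 2/3;
* **a TOC gradient** aligned with one clique factor, so TOC collects the
  most bipartite edges and Shannon co-varies with it; TN is pure noise;
* **compartment effects**: the rhizosphere log-abundance profile is
  shrunk by 1/`diversity_effect` (a flatter rank-abundance curve, hence
  higher Shannon) and its OTU pool is larger (higher richness).

Two implementation choices matter and are deliberate:

1. **Rank-space design.** With only 12 samples per network, the Spearman
   correlation of a single draw from a Pearson-space factor model scatters
   by roughly ±0.3 around its target, which makes planted hub/connector
   geometry unreachable. Planted profiles are therefore constructed
   directly as permutations of the sample ranks with prescribed pairwise
   rank correlations (rejection sampling plus local transposition repair
   against explicit windows), and abundances are equally log-spaced in
   rank (step 0.42), so realized Spearman values equal their designed
   values up to small multinomial jitter. The geometry is a fixed design
   constant; the user seed drives only read sampling, a small lognormal
   jitter and environmental noise, so identical seeds give byte-identical
   tables.
2. **Closure balancers.** Compositional normalisation subtracts a
   per-sample log constant whose variation (≈0.6 SD here) would otherwise
   contaminate every profile and destroy negative correlations. A few
   "balancer" background OTUs absorb the per-sample mass fluctuation so
   the closure constant is exactly constant and planted profiles survive
   normalisation unchanged.

The Shannon–TOC slope is realised by scaling the TOC axis to the
design-level Shannon response (rank-based edge detection is invariant to
affine scaling of a factor), so the regression slope matches `toc_slope`
(default 0.05 nats per g/kg) by construction; with `toc_slope = 0` the
TOC values are seed-driven noise uncoupled from the community. The ground
truth records module membership, hubs, connectors, the planted pair list
with designed correlations, per-sample design Shannon and the realised
environmental slopes.

What the generator does **not** emulate: compositional count overdispersion
beyond multinomial, phylogenetically coherent taxonomies, sparse
block-structured ecological interactions, or sequencing artefacts
(chimeras, index hopping). Passing the planted-recovery tests therefore
demonstrates that the pipeline's machinery is correct and calibrated, not
that the default thresholds are optimal for any particular real survey.

## Numerical choices and degenerate inputs

Strict inequality at the 0.005% abundance filter (a value exactly at the
threshold is excluded). Constant OTU columns and constant environmental
factors are excluded from correlation with a warning; constant pooled data
in a rank test returns p = 1 with a warning. Rarefaction refuses depths
exceeding any library and names the offending samples. Zero-count OTU
columns are retained after rarefaction so OTU ids stay aligned across
subsets; only the abundance filter removes columns. The greedy-modularity
Q reported is recomputed from the final partition (agreement to 1e-12 is
tested). Summary JSON floats are rounded to 10 digits so reruns compare
byte-identically.

## Problem sizes used in the test-suite and acceptance measurements

Planted-structure recovery is measured over 20 seeds at the default
design; Wilcoxon power over 40–50 seeds; PERMANOVA null calibration over
1000 simulated null datasets of 12 samples with 199 permutations each;
exact-Wilcoxon enumeration over every tie-free configuration with group
sizes up to 7. These sizes give Monte-Carlo standard errors well inside
the asserted bands.

## Known limitations

Single-factor PERMANOVA only (no strata or multi-factor partitioning); no
compositionality-aware correlation (SparCC/SPIEC-EASI) — the networks are
plain rank correlations as in much of the applied literature; no
phylogenetic diversity or UniFrac; the guild reference must be supplied by
the user (the FUNGuild database itself is not shipped); modularity and
roles ignore edge weights and signs.
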