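# Methods

This note records the models, conventions and numerical choices behind
each stage of the pipeline — the decisions a reader needs to interpret the
outputs or to reproduce them with other software.

## Data model

The unit of observation is a **strain**: one isolate, from one site,
carrying one haplotype of a single-copy marker. Multiple strains can share
a haplotype, and haplotypes are tips of a rooted gene tree whose branch
lengths are expected substitutions per site. Sites carry coordinates,
environmental covariates, a glaciation flag and a colonization-time rank
(1 = longest time available). All statistics below are functions of the
(tree, strain map, site table) triple; "weighted" analyses use all
strains, "unweighted" analyses first collapse duplicate sequences (one
representative per unique haplotype per OTU per site).

## OTU definition

OTUs are defined on the tree at patristic threshold θ (default 0.01
substitutions/site, a divergence scale that tracks species boundaries for
*Streptomyces*-like taxa). Tree-based OTU callers differ in where the
threshold applies, so both rules are implemented and the choice is a
recorded config field:

* `node_depth` (default): maximal clades in which every tip lies within
  θ/2 of the clade root. Any two members are then ≤ θ apart through that
  node; OTUs are monophyletic by construction. Unabsorbed tips are
  singletons.
* `max_pairwise`: complete-linkage agglomeration on the patristic matrix,
  cut at θ (maximum pairwise distance ≤ θ; not necessarily monophyletic).

Distances are used as-is (no multiple-hit correction): the threshold is
defined on the same scale as the tree's branch lengths. OTU labels are
assigned in order of each OTU's lexicographically smallest member, making
the labelling deterministic.

## Alpha diversity

* **Faith's PD** is root-inclusive: the summed length of every branch on
  a path from a present tip to the root. The convention is recorded in
  output metadata because tools differ; root-inclusive PD is monotone in
  the taxon set and equals total tree length when all tips are present.
* **MPD / MNTD** are presence-based on the site's taxa (the pipeline uses
  one representative tip per OTU). The null model redraws the same number
  of taxa from the pool of all taxa present anywhere in the community
  matrix, without replacement, n = 999 by default. NRI = −(MPD_obs −
  mean)/sd and NTI likewise for MNTD, so positive values mean phylogenetic
  clustering. The permutation p is two-sided: the fraction of null values
  at least as far from the null mean as the observation, with the
  smoothed (1+b)/(1+n) estimator. When the pool is small the null can be
  enumerated exhaustively (every same-size subset), in which case p is the
  exact unsmoothed fraction. A site containing the whole pool has a
  degenerate null (sd = 0, detected with a relative tolerance); it is
  reported with z = 0, p = 1 and a flag. An abundance-weighted MPD/MNTD
  variant is available for the observed statistic; the null remains the
  presence-based draw, mirroring the weighted/unweighted strain-inclusion
  views rather than a different null model.
* **MRD** counts the nodes separating each present tip from the root
  (root counted, tip not — equivalently the number of ancestors) and
  averages over present tips. Higher values mean more derived
  assemblages.
* **Group contrasts** report means and SDs (n−1 denominator) plus
  two-sided p for both Welch's t and Mann-Whitney; Welch is the default
  and falls back to Mann-Whitney with a warning when a group has one
  member. **Rank correlations** are Spearman with mid-rank ties; p is by
  full permutation enumeration for n ≤ 10 and the t(n−2) approximation
  otherwise.

## Beta diversity and tests

* **Unweighted UniFrac** classifies every branch by whether its subtree
  intersects each site's taxa: distance = (branch length unique to one
  site) / (branch length spanned by the union), root-inclusive. The
  **abundance-weighted** variant is Σ b·|p_A − p_B| / Σ b·(p_A + p_B),
  where p is the fraction of a site's strains below branch b — bounded in
  [0, 1]. Pairwise significance permutes strain site-labels within the
  pair, preserving site totals (one-sided, smoothed).
* **Bray-Curtis** is Σ|x−y| / Σ(x+y) on strain counts (weighted view) or
  presences (unweighted view).
* **Geographic distance** is the great circle on the sphere with Earth
  radius 6371.0088 km. **Environmental distance** is Euclidean on
  z-scored variables; standardization uses the population SD (so two
  sites on one variable sit at z = ∓1, distance 2), and zero-variance
  variables are dropped with a warning.
* **Mantel**: Pearson r over upper-triangle entries; p one-sided
  (permuted r ≥ observed), permuting rows and columns of the second
  matrix jointly, smoothed; exhaustive over all n! relabelings on demand.
  The reported R² is r² with the sign carried by the statistic, since the
  distance-decay literature usually prints squared Mantel coefficients.
* **PERMANOVA** (one explanatory variable per call, matching
  single-factor tables): pseudo-F from the Gower-centered inner-product
  form G = −½·J·D²·J, SS_model = tr(HGH) for the hat matrix of
  [1, x], R² = SS_model/SS_total, p by permuting the variable. For a
  binary factor this reduces exactly to the classical within/among
  pairwise-d² partition (asserted against an independent oracle and
  cross-checked against scikit-bio in the tests). Note that with
  completely unstructured distances F = 1 and the *expected* R² is
  (a−1)/(n−1), not 0.
* All permutation p-values in the package use (1+b)/(1+n) and are
  reproducible under a fixed seed.

## OTU-sharing network

OTUs present in fewer than 2 sites are excluded (they carry no sharing
information). For classification, each OTU's strains are split glaciated/
nonglaciated and tested against all other retained OTUs' strains in a 2×2
two-sided Fisher exact test (point-probability method); an OTU is labelled
glacial or nonglacial only when its strain fraction from that class
exceeds 0.90 *and* p < 0.05. Counting strains (not site-presences) is the
default granularity; the 2×2 construction is isolated so a site-presence
alternative can be swapped in.

## Haplotype networks and nested clade analysis

* **Connection limit.** Pairs of haplotypes are connected only up to the
  number of mutational steps that parsimony can justify at 95%
  confidence. The criterion implemented is the finite-sites
  no-multiple-hit probability: the chance that j mutations landed on j
  distinct sites of an L-site sequence, P(j) = Π_{i=1}^{j−1}(1 − i/L);
  the limit is the largest j with P(j) above the confidence. It collapses
  to single steps as confidence → 1 and is non-decreasing in L; for
  L = 377 at 0.95 the limit is 6 steps.
* **Network building** joins pairs in increasing Hamming distance,
  bridging multi-step pairs with inferred (unsampled) intermediate nodes
  so every edge is one step. A pair is joined only when it adds
  information (different components, or current graph distance above its
  mutational distance); equally parsimonious alternatives discovered in
  the same round are all retained, producing ambiguity loops.
* **Loop resolution** removes, per cycle, the edge ranked worst by
  frequency (keep connections to high-frequency haplotypes), then
  interiority (keep connections to high-degree nodes), then geography
  (keep connections between co-occurring haplotypes), with a label
  tie-break — so runs are reproducible. Loops are resolved before
  nesting.
* **Nesting** is tip-first and label-ordered: each ungrouped tip unit
  absorbs its ungrouped one-step neighbors, interiors follow, a stranded
  unit stays a singleton clade, and the procedure iterates on the clade
  graph until each component is one clade.
* **Dc / Dn** use spherical geometry: a clade's center is the normalized
  mean of its strain observations' unit vectors (planar averaging
  distorts at continental scale), Dc the mean great-circle distance of
  members to their own center, Dn to the nesting clade's center
  (outermost clades: the whole-network centroid). Abundance enters by
  counting every strain observation once.
* **Significance** permutes strain observations among a nesting clade's
  subclades (sizes preserved), flagging Dc/Dn significantly small or
  large at α = 0.05 (smoothed one-sided p), plus interior-minus-tip
  contrasts. **Interpretation** condenses each nesting clade's flag
  pattern into named features and looks them up in an editable JSON
  decision table; only the two chains needed for the expansion /
  isolation-by-distance distinction ship by default, with
  "no significant association" and "inconclusive" as fallbacks. The full
  published inference key is deliberately not hard-coded.

## Synthetic data generator

The generator emulates the survey the pipeline is designed for; its
defaults are the study shape (12 latitude-ordered sites from 28° to 64°N,
77 strains per site, 208 haplotypes of a 377 bp marker, glaciation above
45°N).

* **Genealogy**: Yule (pure-birth) tree, birth rate 1/time unit,
  ultrametric; the process stops when the nth tip is born, so the mean
  root-to-tip depth is (1/b)·Σ_{k=2}^{n−1} 1/k (used as a test oracle).
* **Sequences**: Jukes-Cantor along the tree; the substitution rate
  (default 0.008 per site per time unit) sets typical pairwise divergence
  at a few percent, chosen so that the 0.01 OTU threshold produces a
  non-trivial clustering (roughly 0.6–0.7 OTUs per unique haplotype) and
  some tips collapse to identical sequences, as in real surveys of
  conserved markers. The emitted Newick tree is pre-scaled to
  substitutions/site so its branch lengths are dimensionally consistent
  with the OTU threshold and with PD/UniFrac outputs. Yule + JC is
  deliberately minimal: the statistics under test need clustering and
  gradient structure, not GTR realism.
* **Occupancy scenarios.** *Panmixia* draws every strain uniformly from
  the full haplotype pool — the calibration null. *Expansion* orders
  sites by latitude; the lowest-latitude site draws from the full pool
  and each higher site from a founder subset of its southern neighbor's
  pool (size = founder_fraction × parent pool, never below 2 so per-site
  statistics stay defined). Founder subsets are phylogenetically
  coherent — a uniformly drawn seed haplotype plus its patristically
  nearest parent-pool members — because a colonization event carries a
  lineage, not a random sample; uniformly random founders would lower PD
  but leave NRI at zero, which is not the gradient being modelled. The
  default founder fraction 0.8 keeps the northernmost pools around 20
  haplotypes, so site richness declines smoothly instead of collapsing
  to two taxa. *Clustered* gives each site the tips of one random
  subtree — clustering without a gradient. Latitude is the only driver:
  pH/SOM/temperature/precipitation are uncorrelated noise, providing a
  true-negative case for the environmental-distance tests.
* **Determinism**: every output is a pure function of the config; child
  seeds are derived per stage.

What passing tests on this generator do **not** show: robustness to tree
estimation error, recombination, selection, alignment artifacts, uneven
sampling effort, or environmental structure correlated with latitude —
real surveys have all of these, the generator has none.

## Verification strategy and problem sizes

Three layers (the acceptance suite): exact agreement with independent
brute-force/closed-form oracles on small instances (patristic matrix, PD,
MRD, UniFrac, NRI over all C(6,2) draws, Mantel over all 120 and PERMANOVA
over all 720 permutations, Fisher vs hypergeometric, rarefaction vs
hypergeometric, the parsimony product vs a log-space recomputation);
null calibration (NRI on 400 panmictic replicates and Mantel on 400
independent-matrix replicates reject at 0.05 within ±0.02; NCA Dc/Dn flag
rates stay near α on 200 geography-randomized replicates); and signal
recovery (100 expansion replicates at founder fraction 0.2 with 6 sites:
PD non-increasing in latitude, top-site NRI positive, and Bray-Curtis vs
geography Mantel r positive in ≥ 80–90% of replicates). Calibration
replicates use 24-tip trees and 199 permutations — small enough to run the
whole suite in about a minute while keeping the rejection-rate standard
errors below the asserted bands.

## Known limitations

* The nesting procedure implements the standard tip-first agglomeration,
  not every special-case rule of the original nesting prescriptions
  (stranded units stay singletons rather than joining a neighbor clade).
* The NCA inference table ships only the range-expansion and
  isolation-by-distance chains; other historical scenarios return
  "inconclusive" unless rules are added.
* The parsimony connection limit uses the no-multiple-hit product
  criterion described above; implementations differ in the exact
  probability model, so limits may differ by a step or two from legacy
  desktop tools.
* PERMANOVA is single-variable (sequential partitions with multiple
  covariates are out of scope), and partial Mantel is not provided.
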