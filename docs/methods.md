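# Methods

## Scope and model

`microbiogeo` implements the post-OTU-table stages of a two-region marine
amplicon survey: samples are rarefied to a common depth, characterized by
alpha diversity (richness, Shannon, Faith's PD, NTI), compared by
beta-diversity structure (Bray-Curtis, PCoA, ANOSIM, Procrustes/PROTEST,
Mantel), regressed against geography (distance decay, slope-difference
permutation tests), and finally classified pair by pair into five
community-assembly processes with the two-step phylogenetic null-model
framework of Stegen and colleagues:

1. **betaNTI.** For samples *x* and *y*, the between-community mean nearest
   taxon distance is

   betaMNTD(x, y) = ½ [ Σ_{i∈x} f_i · min_{j∈y} d_ij + Σ_{j∈y} f_j · min_{i∈x} d_ij ],

   with *d* the patristic (cophenetic) distance and *f* relative abundances
   (abundance weighting on by default, the framework convention; a flag
   disables it). The null shuffles tip identities on the cophenetic matrix;
   betaNTI is the z-score of the observed betaMNTD against `n_rand` shuffles.
   One shared shuffle per randomization serves all pairs — statistically
   equivalent to per-pair shuffles and ~n_pairs times faster. betaNTI > +2 is
   read as heterogeneous selection, betaNTI < −2 as homogeneous selection.

2. **RC_bray.** Pairs without a selection signal are scored against a
   probabilistic assembly null that preserves each sample's richness *S* and
   total count *N*: draw *S* taxa without replacement with probability
   proportional to occupancy, seed each with one individual, distribute the
   remaining *N − S* individuals with probability proportional to summed
   relative abundance, and compare observed Bray-Curtis against `n_rand` null
   pairs. RC_bray = 2·(fraction of null values below observed, ties counted
   half) − 1 ∈ [−1, 1]. RC > +0.95 is read as dispersal limitation,
   RC < −0.95 as homogenizing dispersal, and the rest as drift. Bray-Curtis
   values are rounded to 1e-9 before tie comparison because integer counts
   give rational values whose float images can differ in the last bit.
   Per-sample null draws are generated once and reused across the pairs a
   sample participates in; within any pair the null values remain i.i.d.

Classification thresholds (|betaNTI| > 2, |RC| > 0.95) are exposed as
arguments. Occupancy/abundance weights for the RC null are computed over the
analysis table by default; a `weights_table` argument supports running
regions separately or against a reference pool.

### Degenerate pairs

When two samples contain identical taxon sets, betaMNTD is zero under *every*
tip shuffle (each present taxon's nearest neighbour in the other sample is
itself), so the null is degenerate and the pair is reported NaN and excluded
from classification. The same applies to the alpha-diversity NTI of a sample
containing the entire taxon pool. Degeneracy is detected as
sd_null ≤ 1e-12 · max(|mean_null|, 1) to absorb floating-point jitter.
Undefined values propagate as NaN, never as zero.

## Statistical conventions

- Permutation p-values are `(exceedances + 1) / (n_perm + 1)`, one-sided for
  ANOSIM, Mantel, and PROTEST (vegan's convention; never exactly zero),
  two-sided for decay-slope and slope-difference tests.
- Ranks use average ties everywhere.
- Shannon is log base 2 by default (the QIIME-1 convention this analysis
  style inherits), switchable to natural log.
- Faith's PD includes the branches connecting the present-taxa subtree to the
  root (QIIME-1 convention); `include_root=False` restricts to the subtree
  below the MRCA.
- NTI = −(MNTD_obs − mean_null)/sd_null against unconstrained tip-label
  shuffles, so phylogenetically clustered samples score positive.
  Abundance-weighting is off by default for NTI (picante's default) and on
  for betaMNTD/betaNTI (Stegen convention); both are flags.
- Group comparisons of the two station groups use the unpaired rank-sum
  (Mann-Whitney) test, exact for small tie-free samples and a tie- and
  continuity-corrected normal approximation otherwise; a `paired` flag
  switches to the signed-rank test for genuinely paired designs.
- Spearman correlation matrices are Benjamini-Hochberg adjusted across all
  unique variable pairs; non-significant cells can be masked (the heatmap
  convention).
- PCoA reports negative eigenvalues unmodified and computes proportion
  explained over positive eigenvalues only. Coordinates are eigenvectors
  scaled by the square root of their eigenvalues.
- Procrustes is the symmetric variant (both configurations centered and
  scaled to unit trace), so M² ∈ [0, 1] and is invariant to argument order;
  PROTEST permutes rows of one configuration. Ordinations feed Procrustes
  with 2 axes by default (configurable).
- Mantel defaults to Spearman correlation.
- Distance-decay fits regress similarity (1 − Bray-Curtis) on great-circle
  distance (Earth radius 6371.0 km). Because pairwise points share samples,
  OLS t-tests are invalid; significance comes from Mantel-style permutations
  of sample identities. The slope-difference test pools the two
  (distance, similarity) pair sets in a canonical order and re-partitions
  them at random, which also makes the p-value exactly invariant under
  swapping two equally sized sets.

## The synthetic generator

The generator emulates the *structure* of a two-region oligotrophic-ocean
survey — a western and a central station group (13 + 16 by default) in a
tropical latitude band, hundreds of OTUs on a Yule phylogeny, counts at a
common depth — with explicitly controllable assembly forcings:

- **Phylogeny**: pure-birth tree, rate 1, tips `OTU_00001...`; the
  simulator's stem edge is dropped so the root carries no branch.
- **Niche optima**: Brownian motion from a root value of 0 with rate
  `trait_bm_sigma` (default 2.0), giving phylogenetically conserved niches
  (close relatives share optima).
- **Environment**: each variable is `slope · longitude + region_offset +
  N(0, sd)`; the first variable is the niche axis. Defaults produce a
  temperature-like gradient (~27–31 units) differing between regions.
- **Selection**: taxon weights are Gaussian in (env − optimum) with breadth
  `selection_sd` (∞ disables).
- **Region pools**: a fraction `pool_overlap` of taxa is shared; lognormal
  (sd_log = 1) metacommunity abundances per region, shared taxa averaged
  across regions so pools stay correlated.
- **Distance-limited dispersal**: a site samples an exponential-kernel
  mixture (scale `dispersal_lambda` km) of nearby sites' expected
  compositions (∞ disables distance effects entirely rather than averaging
  everything, so "no distance structure" means each site keeps its own
  expectation).
- **Homogenizing dispersal**: a fraction `mixing` of every site's sampling
  pool is the global mean composition.
- **Drift**: realized counts are one multinomial draw of `community_size`
  (J) individuals — drift as sampling noise, J as the knob.

Defaults: 500 taxa, J = 95,250 (the common rarefaction depth of the survey
design the generator emulates), all forcings off.

### Preset bundles and why their community sizes differ

The presets are calibration targets for the classifier, chosen so each
regime is *detectable in principle* under the Raup-Crick null, which
resamples **membership** by occupancy:

- `drift` (σ=∞, φ=1, λ=∞, m=0, J=5,000 at 300 taxa): J is set so per-sample
  richness nearly saturates the pool (~298/300). Below saturation, a
  shared-pool multinomial community is *more similar than random assembly*
  (common taxa never drop out of observed samples but do drop out of
  occupancy-weighted null draws), and the classifier correctly reports
  homogenizing dispersal rather than drift; at full saturation every pair is
  degenerate. Near-saturation is the regime where one-shot multinomial
  sampling genuinely matches the null's own turnover.
- `heterogeneous_selection` (σ=1, regions 8 niche units apart ≥ 4× env noise,
  slope 0, J=10⁵): each region filters a different clade, so cross-region
  phylogenetic turnover exceeds the tip-shuffle null (betaNTI > 2) while
  within-region pairs are held together (betaNTI < −2).
- `dispersal_limitation` (φ=0.2, λ=150 km, J=10⁵): region pools are mostly
  exclusive and mixing is short-range relative to the ~1,000–4,000 km
  between-region distances, so observed cross-region turnover exceeds the
  pooled-occupancy null (RC → +1).
- `homogenizing_dispersal` (φ=0.3, m=0.95, J=500): strong mixing homogenizes
  observed composition while the modest community size keeps richness below
  the pool, so the null's membership lottery expects more turnover than is
  observed (RC → −1). At J=10⁵ with a few hundred lognormal taxa every
  sample contains the whole pool and RC < −0.95 is unreachable by
  construction, so this preset runs at small J.

## Validation design

`microbiogeo.calibration` packages the checks a practitioner should run
before trusting the nulls:

- **Oracle equivalence**: the vectorized betaMNTD equals an explicit
  double-loop implementation on 200 random instances (≤ 8 taxa, ≤ 4
  samples); Mantel and exact rank-sum p-values match exhaustive enumeration
  at n = 6 and n = m = 5.
- **Self-calibration**: communities assembled at random with respect to the
  phylogeny trip |betaNTI| > 2 at ≈ 5%; pairs drawn by the Raup-Crick null
  itself trip |RC| > 0.95 at ≈ 5% (200 replicates, 999 randomizations each).
- **Type-I error**: ANOSIM, Mantel, PROTEST, decay-fit, and slope-difference
  tests each hold the 5% level within [0.03, 0.07] over 1,000 true-null
  simulations (199 permutations per test).
- **Regime recovery**: each preset's target process is modal or elevated
  relative to the drift preset at 20 samples × 300 taxa × 999
  randomizations.
- **Directional consistency**: the dispersal-limited preset shows a
  significant negative distance-decay slope; the selection preset yields
  region-separated PCoA clusters with ANOSIM p < 0.05; a low-diversity,
  small-J regime (100 taxa, J = 1,200) shows a higher drift fraction than a
  high-diversity, large-J structured regime — the small-populations-drift
  pattern.

Problem sizes (200 replicates, 1,000 simulations, 20 samples × 300 taxa)
were chosen as the smallest at which the binomial noise of the estimated
rates is well inside the asserted bands; they run on one CPU in a few
minutes. `scripts/acceptance.py` reruns all of the above from scratch under
a single master seed.

## What the synthetic data do not show

The generator produces idealized communities: no sequencing error, no
compositional bias from primers or copy number, no temporal dynamics,
speciation, or species interactions, one environmental niche axis, and
drift collapsed into a single multinomial draw rather than demographic
wander. Passing the recovery checks therefore demonstrates that the
*inference machinery* is correct and calibrated under its own assumptions —
not that real ocean communities satisfy those assumptions. In particular,
the boundary between "drift" and "homogenizing dispersal" depends strongly
on how sample richness relates to the pool (see the preset discussion
above), a sensitivity that applies equally to real rarefied OTU tables.

## Known limitations

- Cophenetic matrices are materialized densely; fine up to a few thousand
  tips, not for tens of thousands.
- The RC null's occupancy weighting compresses abundance information
  (occupancy saturates for common taxa), the classical behaviour of the
  published procedure; alternative weightings are not implemented.
- ANOSIM/Mantel permutations are uniform over label/row permutations;
  restricted (stratified) permutation schemes are not implemented.
- No iCAMP-style per-clade partitioning; the classifier is the five-way
  whole-community partition.
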