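# Methods

This note documents the models and procedures implemented in `germcore`,
their assumptions, the defaults that matter, and the design choices made
where the problem left the design open.

## Data model

A collection couples an accession × trait matrix of quantitative phenotypes
(missing cells allowed, NaN in memory, empty cell or `NA` on disk) with an
accession × allele matrix of dominant marker bands (strict 0/1, no missing —
band missingness is a load error, not an imputation problem) and a grouping
of band columns into primers. The accession ID joins all files; the
phenotype file's row order is canonical. All summary statistics use the
sample (n − 1) standard deviation.

## Multiple imputation (chained equations)

Missing quantitative traits are completed by Gibbs-style chained equations.
For each incomplete trait the conditional model is a linear regression on
all other quantitative traits. One sweep draws, per trait: σ² from its
scaled inverse-χ² posterior, β from N(β̂, σ²(XᵀX)⁻¹), and the missing cells
from the resulting predictive normal. Several independent chains are run
from randomised starts (missing cells seeded by resampling observed
values).

Defaults: 4 chains × 40 sweeps, 5 retained completed matrices taken from
the chain ends (round-robin), pooled per-cell mean used by every downstream
stage. Convergence is declared when the potential-scale-reduction statistic

R̂ = √(((n−1)/n · W + B/n) / W)

of the per-trait mean *and* SD trajectories of the imputed values lies in
[0.9, 1.1] for every trait (W = mean within-chain variance, B = n × variance
of chain means; W = 0 with B > 0 reports +∞). A complete matrix returns
unchanged with R̂ = 1 by convention.

Assumption and limitation: the conditional model is a *global* linear
regression. On clustered data this is a deliberate misspecification — the
imputation error for a cell is bounded below by the residual scale of the
global trait regression, √(1 − r²)·σ, regardless of how many draws are
pooled. With strongly collinear cluster structure (the default generator,
global r ≈ 0.98) this error is small; with clusters far off a common trend
it is not, and imputed accessions can drift toward neighbouring clusters.

## Embedding and weighted k-means

Quantitative traits are z-scored and multiplied by `phenotype_weight`;
band columns are multiplied by `genotype_weight/√L` (L = number of band
columns), so at the default weights (1, 1) each block contributes a
comparable share of total variance regardless of L. Zero-variance traits
are dropped with a warning.

Clustering is Lloyd's algorithm with farthest-point seeding: the first
centre of each restart is drawn from the seeded RNG, subsequent centres are
the points maximising their minimum distance to the chosen ones (ties to
the lowest index). Assignment ties go to the lowest cluster index; a
cluster emptied during iteration is re-seeded at the point farthest from
its centroid. Best of 20 restarts by within-cluster SS. These details are
fixed in-package (rather than delegated to a library k-means) so that
restarts, tie-breaks and the empty-cluster rule are reproducible parts of
the contract.

k\* is the smallest k in the scanned range whose solution exceeds all of:
normalised Shannon evenness of cluster proportions H′ > 0.90, Nei diversity
1 − Σp² > 0.80, and explained variance (between-SS/total-SS) > 0.75. Note
1 − 1/k ≤ 0.80 for k ≤ 5, so the Nei criterion alone forces k ≥ 6; the
contest is decided among k = 6, 7, …. If no k passes, the k with the
smallest total threshold shortfall is returned and flagged.

## Modified genetic distance

- `eul`: squared Euclidean distance over **raw** trait units (no
  standardisation) — the published distance magnitudes are only attainable
  on raw centimetre scales.
- `iof`: per qualitative variable, 0 on a level match and
  (ln f_i · ln f_i\*)² on a mismatch, with f the whole-collection occurrence
  **counts** of each accession's level (both members of the pair included).
  Natural logarithm. Each band column is one two-level variable.
- `mgd = eul + iof` entry-wise.

Choices worth noting: with counts, the mismatch weight (ln f₀ · ln f₁)² is
*largest* for evenly split variables and vanishes for a level seen once
(ln 1 = 0); a warning flags singleton levels. Proportions instead of counts
would flip this behaviour but produce magnitudes inconsistent with the
published distance range, so counts are used. MGD is not a metric; no
triangle inequality is claimed and d² values are used directly, without a
square root.

## Selection

Given cluster labels and a target size m (default: the fraction 22/207 of
the collection):

- **two_step_pg** — Step 1 (P): a cluster is *rare* iff its raw-trait
  centroid falls below the `rare_quantile` (default 0.05) or above the
  1 − `rare_quantile` pooled per-trait quantile on any trait, or its size is
  ≤ max(1, ⌈0.01 n⌉). Each rare cluster contributes exactly one accession:
  its medoid under the phenotype (`eul`) distance. Step 2 (G): the
  remaining quota is allocated over non-rare clusters by largest-remainder
  proportional allocation (floor `min_per_cluster` = 1, quotas capped at
  cluster sizes, seats assigned/retracted by largest/smallest deficit from
  the ideal share, ties by cluster index) and filled within each cluster by
  greedy maximin on the genotype (`iof`) distance.
- **p_only / g_only / traditional_pg** — the same allocation, with maximin
  run on `eul` / `iof` / full `mgd` respectively.
- **random** — seeded stratified sampling with the same allocation.

Greedy maximin starts from the farthest candidate pair (the medoid for
quota 1) and repeatedly adds the candidate maximising its minimum distance
to the already-selected set; ties break by input order, making every
strategy deterministic given its seed. On a metric the greedy objective is
within a factor 2 of the optimal p-dispersion value; since MGD is a squared
dissimilarity the guarantee applies on its square root.

## Evaluation

- Per-trait difference tests: Brown–Forsythe (median-centred Levene)
  statistic with a bootstrap p-value (default 1 000 resamples of the pooled,
  median-centred groups, seeded); the mean test is Student's t when the
  variance test is non-significant at α (default 0.05) and Welch's t
  otherwise. Identical constant groups report p = 1 by convention.
- Representativeness, with m traits: MD% = share of significant mean tests;
  VD% = mean |V_e − V_c|/V_c; CR% = mean R_c/R_e; VR% = mean CV_c/CV_e
  (all × 100). Because the opposite denominator convention for VD/VR also
  circulates in the literature, the swapped-ratio variants are reported
  alongside (`vd_pct_alt`, `vr_pct_alt`); traits with a zero denominator are
  excluded with a warning and m adjusted.
- Diversity of group proportions: H′ = −Σ p ln p / ln S and Nei = 1 − Σp².
  Applied to cluster proportions by default; binning continuous traits into
  classes (for per-trait diversity) uses Sturges' rule on the EC, applied
  identically to the CC, and is a reconstruction rather than a published
  procedure.
- Dominant-marker statistics: per allele q = presence fraction;
  PIC = mean over alleles of 1 − (q² + (1−q)²) (≤ 0.5 for dominant data),
  averaged over primers; Hexp = 1 − Σp² over a primer's band counts
  normalised within the primer; F_ST treats each band column as a two-level
  locus, computes H_S (mean within-subpopulation gene diversity) and H_T
  (gene diversity of the unweighted mean frequencies), averages both over a
  primer's loci, takes (H_T − H_S)/H_T per primer and averages over primers.
  Subpopulations default to cluster labels. All-monomorphic primers report
  F_ST = 0 with a warning.
- Cluster-share test: χ² homogeneity of the CC and EC count vectors, with a
  seeded Monte-Carlo p-value (10 000 draws from the pooled proportions)
  whenever an expected cell is below 5.
- Pedigree check: Pearson r (with r² and p) between per-ancestor mean
  contribution percentages in the EC-with-pedigree and CC-with-pedigree
  subsets; requires ≥ 3 ancestors with nonzero contribution.

## Synthetic data generator

The generator emulates the study design rather than any real dataset: 207
accessions in 7 clusters (sizes 37, 37, 33, 34, 30, 28, 8). Cluster trait
means run from short/small to tall/large along a common trend —
(20, 5.2), (30, 6.0), (46, 7.6), (59, 9.4), (72, 11.6), (85, 13.8) cm —
with within-cluster SDs of 2.2–2.6 cm (height) and 0.5–0.62 cm (diameter)
and within-cluster trait correlation 0.8. Cluster 7 is the planted rare
cluster: 8 dwarf accessions at (2.5, 1.2) cm, the smallest plants and
flowers in the collection, with *no* distinctive marker profile (its allele
frequencies are drawn from the same shift distribution as every other
cluster's, mirroring markers that cannot resolve the rare group). Bands:
65 alleles in 8 primers (contiguous blocks 9, 8, …, 8), base presence
frequencies U(0.15, 0.85), per-cluster shifts U(−0.15, 0.15), clipped to
(0.02, 0.98). Missingness is MAR at rate 0.20 per trait: flower diameter
is masked completely at random; plant height is masked only where diameter
is observed, with probability increasing logistically in the observed
diameter and an intercept calibrated to the marginal rate.

Geometry rationale (why these defaults): the first two clusters are placed
closest together (10 cm apart) so that at k = 6 the SS-optimal solution
merges them, producing an uneven partition whose Nei diversity falls below
the 0.80 criterion, while absorbing the 8-member dwarf cluster — the only
k = 6 alternative that would *pass* the criteria — costs roughly twice as
much within-cluster SS; at k = 7 all three criteria are met. The common
trait trend keeps the global height–diameter correlation near 0.98 so that
chained-equation imputation (global linear conditionals) recovers missing
cells to ~4 cm, small relative to the 10–13 cm gaps between neighbouring
cluster means. What the generator does **not** emulate: nursery effects on
traits, linkage between markers, genotyping error, non-Gaussian trait
shapes, and missingness that depends on the missing value itself (MNAR).
Passing tests on these simulations demonstrate correct behaviour under the
stated design, not performance on any particular real germplasm bank.

Problem sizes used in the simulation-based tests — 20 replicates for
imputation recovery and cluster-count selection, 50 for the rare-cluster
guarantee, 200 random instances for the maximin oracle and 500 random
collections for the distance invariants — were chosen to keep the full
suite in the tens of seconds while leaving the binomial pass/fail margins
of each check wide.

## Numerical details and degenerate inputs

- Seeds: every stochastic routine takes an explicit seed; the pipeline
  derives per-stage seeds as `(global_seed XOR crc32(stage)) mod 2³¹`.
- k-means distance ties and maximin ties resolve to the lowest index /
  input order; allocation ties to the lowest cluster index.
- Distance matrices are symmetrised (0.5·(D + Dᵀ)) after vectorised
  computation to remove floating-point asymmetry; diagonals are set to 0.
- Degenerate cases: single accession (SD missing), all-missing trait (load
  warning, imputation error), k = 1 excluded from `select_k`, zero-variance
  groups in tests report p = 1 with a 0 statistic, H_T = 0 gives F_ST = 0.

## Known limitations

- The two-step strategy fixes the rare-cluster quota at one medoid per rare
  cluster; published practice may have taken more.
- The published VD% and VR% values are not reproducible from the printed
  formulas applied to the published summary table; both denominator
  conventions are therefore emitted and neither is asserted.
- Pipeline artifacts are CSV/TSV/JSON only; no plotting is included.
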