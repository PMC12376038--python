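# Methods

`enterolink` reimplements, as a tested library, the statistical chain used to
analyze repeated-measures livestock gut microbiota: enterotype discovery and
validation, co-occurrence network ecology with an automatic correlation
cutoff, null-model partitioning of community assembly processes, and
enterotype-to-phenotype statistics. Every stage runs end to end on a
synthetic cohort generator with planted ground truth, so the estimators can
be checked against known answers without any sequencing data.

## Community core

The central container couples an integer count table (samples × taxa) with
per-sample metadata (animal, timepoint, gut site). Standard steps:

- **Abundance/prevalence filter.** A taxon is kept when its mean relative
  abundance across all samples exceeds 0.01% (strict `>`) *and* it is
  detected in at least 50% of distinct animals. Detection is pooled across
  an animal's timepoints — the unit of prevalence is the animal, not the
  sample — and the 50% boundary is inclusive. The filter is idempotent.
- **Rarefaction** subsamples each sample without replacement (multivariate
  hypergeometric) to a fixed depth, dropping shallower samples with a
  warning. The depth default in the CLI is 15,307 reads, the smallest
  per-sample total of the kind of dataset this emulates.
- **Alpha diversity.** Shannon entropy uses the natural log (the common
  amplicon-toolkit default; the base is otherwise arbitrary). Good's
  coverage is 1 − singletons/reads.
- **Weighted UniFrac** is computed by explicit branch summation:
  Σ_b l_b·|A_b − B_b|, optionally normalized by Σ_b l_b·(A_b + B_b). The
  implementation is cross-checked in the tests against scikit-bio and a
  brute-force per-branch oracle.
- **PERMANOVA** uses Gower centering and sequential (type I) sums of squares
  via hat-matrix projections, with main effects in column order followed by
  the all-way interaction. P-values come from free permutation of sample
  labels; the repeated-measures structure is deliberately ignored (matching
  common practice for this analysis), which makes p-values for
  animal-constant factors anticonservative on strongly autocorrelated data —
  a known limitation. The one-factor case reduces exactly to the classical
  pseudo-F.

## Enterotyping

Per-animal profiles are arithmetic means of the per-sample relative
abundances across that animal's timepoints. Distances are Jensen–Shannon:
D(p,q) = √(H(m) − (H(p)+H(q))/2) in bits, a metric bounded by 1. Zeros are
handled by a 10⁻⁶ pseudocount followed by renormalization.

Clustering is PAM (BUILD + SWAP) on the JSD matrix, with equal-cost ties
broken by lowest index so results are deterministic. The number of clusters
is chosen by a distance-based Calinski–Harabasz pseudo-F in which sums of
squares are computed from pairwise squared distances (SS of a group =
Σ_{i<j} d²_ij / n_g); no centroid exists in JSD space, and a medoid-based
variant was rejected as unstable. Perfect separation returns +∞.

Validation has three parts:

- silhouette widths of the JSD/PAM assignment recomputed under quantitative
  Jaccard (2B/(1+B) with B the Bray–Curtis dissimilarity), Kulczynski
  (1 − ½(Σmin/Σx + Σmin/Σy)) and Bray–Curtis dissimilarities;
- bootstrap stability: animals are resampled with replacement 100 times
  (configurable), PAM is refit on each resample's unique animals, all
  animals are mapped to the nearest bootstrap medoid, and stability is the
  mean adjusted Rand index against the full-data assignment;
- between-class analysis: the taxon-weight vector is the principal axis of
  the size-weighted, grand-mean-centered class-mean profiles; each cluster's
  dominant taxon is the taxon with the largest weight oriented toward that
  cluster's mean, and it names the enterotype.

Independence of the enterotypes of two gut sites is tested with a Pearson
chi-square on the 2×2 cross-classification (Yates correction available as a
flag). On the printed cross-classification [[15,12],[18,29]] the uncorrected
statistic gives p ≈ 0.15; the source analysis reports p = 0.347 for the same
conclusion, so the exact variant it used evidently differs — the qualitative
conclusion (no association at α = 0.05) is what this operation reproduces.

## Network ecology

Correlations are Pearson (Spearman optional) on relative abundances; constant
taxa get r = 0 with a warning.

**RMT threshold.** Candidate cutoffs are scanned in ascending order; at each
cutoff the matrix is thresholded (|r| below the cutoff zeroed), edgeless
nodes dropped, and the eigenvalue spectrum unfolded by a low-order polynomial
fit to the empirical CDF after trimming 3-IQR outliers (the Perron modes of
dense modules, which would otherwise dominate the fit). The selected
threshold is the smallest cutoff at which the nearest-neighbor spacing
distribution stops decisively preferring the GOE Wigner surmise over the
Poisson (exponential) law, measured as the mean per-spacing log-likelihood
difference with a margin of 0.1. A likelihood comparison is used rather than
a plain goodness-of-fit test because a genuinely modular matrix with few
modules produces a superposition of a small number of component spectra —
intermediate between the pure laws — which a calibrated GOF test correctly
rejects even though the matrix is exactly the structure the threshold is
meant to find; noise-dominated spectra prefer the Wigner surmise by a wide,
cleanly separated margin (measured ≈ −0.21 vs ≥ −0.08 on planted two-block
fixtures). A chi-square GOF against Exp(1) on ≥ 10 equiprobable bins is
retained as a diagnostic.

**Topology and roles.** Edges carry the signed correlation; modules come from
greedy modularity maximization on |weight|; mean shortest-path distance is
reported over the largest connected component. Node roles use the
within-module degree z-score Zi and participation coefficient
Pi = 1 − Σ_t (k_it/k_i)², with the conventional generalist cutoffs
Zi > 2.5 or Pi > 0.62.

**Robustness** simulates extinction cascades: a fraction f of nodes is
removed at random; each remaining node's support is its abundance-weighted
sum of positive edge strengths, and nodes whose support falls to at most
`survival_threshold` (default 0.5) times the original are removed
iteratively. Robustness is the mean fraction of original nodes surviving.
With threshold 0 and a complete positive graph the cascade never fires and
robustness is exactly 1 − f.

**Cohesion.** Observed correlations are corrected by a taxa-shuffle null:
each taxon's abundances are permuted across samples independently, and each
shuffled community is renormalized to sum 1 before the null correlations are
computed, so the null carries the same compositional-closure bias
(mean r ≈ −1/(k−1)) as the observed relative abundances and the correction
removes it. A taxon's positive (negative) connectedness is the mean of its
positive (negative) corrected correlations; a sample's positive (negative)
cohesion is the abundance-weighted sum of the corresponding connectedness
values, so positive cohesion ≥ 0 ≥ negative cohesion by construction.

## Assembly partitioning

Taxa are grouped into phylogenetic bins greedily: the most abundant
unassigned taxon seeds a bin; unassigned taxa within patristic distance 0.2
join nearest-first until the bin holds 24 taxa; the next bin starts from the
remaining taxa. Bins finishing below a minimum size (default 12) are merged
into the bin with the nearest centroid; the quoted binning rule leaves
remainder taxa unspecified, so the merge policy is this package's choice and
can be switched off.

For every sample pair and bin, the abundance-weighted βMNTD is standardized
against a within-bin taxa-shuffle null (tip identities permuted jointly;
one permutation per null replicate shared across all pairs, which keeps cost
linear in the replicate count). βNTI > +1.96 → heterogeneous selection;
< −1.96 → homogeneous selection. Otherwise a Raup–Crick test on Bray–Curtis
runs: the null assembles each community from the bin's pool preserving its
richness and total abundance (taxa drawn by occurrence frequency, filled by
regional relative abundance); RC > +0.95 → dispersal limitation, < −0.95 →
homogenizing dispersal, else drift-and-others. The 1.96/0.95 cutoffs are the
published defaults of the bin-based framework and are exposed as arguments.
Degenerate nulls (sd = 0, typical when a pair shares nearly all taxa) route
the pair to the Raup–Crick step.

Community-level fractions weight each (pair, bin) label by the bin's mean
relative abundance in the pair, normalized per pair, so the five fractions
sum to 1 exactly. Bin weighting is per-pair (whether the source framework
weighted by regional pool or per pair is unstated). Group differences are
tested by a permutational Welch t-test.

## Host links

**Individualized vs common taxa.** Per taxon, (arcsine-square-root
transformed) relative abundance is fit with a linear mixed model —
enterotype, timepoint and their interaction as fixed effects, animal as a
random intercept (statsmodels `MixedLM`, REML). Wald chi-square statistics
are computed per term from the coefficient blocks under sum-to-zero coding;
on the balanced designs this pipeline produces these coincide with
marginality-respecting (type II) tests. P-values are Benjamini–Hochberg
adjusted across taxa per term, and a taxon is individualized when its
adjusted enterotype p ≤ 0.05. The reported effect size is the coefficient of
the exposure-enterotype contrast on the transform scale; the transform is
configurable (`arcsine` default, `identity` optional) because the source
scale is unstated. If the mixed-model fit fails numerically the taxon falls
back to an OLS fit flagged `degenerate` but is still classified by its
p-value; constant taxa are common by definition.

**Mediation.** Linear: M ~ X gives path a, Y ~ X + M gives paths b (mediator)
and ADE (direct); ACME = a·b, and total = ACME + ADE holds exactly.
Inference is a nonparametric row bootstrap (percentile intervals, two-sided
sign-crossing p-values) rather than the quasi-Bayesian approximation —
equivalent at these scales and simpler to verify. The reverse direction
swaps mediator and outcome.

## Synthetic cohorts

The generator emulates a herd of 74 animals sampled at three lactation
timepoints (days in milk −21, 21, 50), 80 genus-level taxa, sequencing
depths uniform on [15,307, 60,000]. Counts are Dirichlet–multinomial:
a skewed (log-normal) baseline weight vector is scaled by a total
concentration of 50, each animal's enterotype multiplies its dominant
genus's weight by `dominant_boost` (default 8), and a per-animal log-normal
perturbation (sd 0.3) shared across timepoints induces repeated-measures
correlation. Dominant taxa are the highest-baseline-weight taxa, so planted
enterotypes are dominated by abundant genera, as real enterotypes are.
Two gut sites are generated by two independent calls, so site-level
enterotype independence holds by construction. Phenotypes follow the linear
chain X → M → Y with configurable path coefficients (defaults a = b = 0.5,
direct = 0.2) and Gaussian noise.

Three dedicated assembly scenarios plant the ecological regimes:

- *neutral pool*: every sample is a multinomial draw from one skewed
  regional pool at moderate depth (500 reads), so presence varies and the
  nulls are non-degenerate; selection calls should stay near the nominal
  rate;
- *filtering*: two pectinate 48-taxon clades (eight tight subclades along a
  gradient); habitat A selects the first subclade of each clade, habitat B
  the last, each sample occupying three random members. Analyzed with the
  binning cap at the clade size (48), within-habitat pairs give homogeneous
  and across-habitat pairs heterogeneous selection; 24-taxon bins were too
  small for the null z-scores to resolve selection at this scale, which is
  why the scenario pins bins to clades;
- *dispersal-limited*: each sample is monopolized (~90% of each clade) by a
  founder taxon distinct across samples and random with respect to the tree,
  over an even low-count background that keeps richness high; observed
  turnover then exceeds the richness/abundance-preserving null while
  phylogenetic turnover stays null-like.

What the generator does *not* emulate: real taxon co-occurrence structure,
overdispersion beyond Dirichlet–multinomial, read-quality artifacts, paired
rumen–hindgut coupling, or timepoint mean shifts (available but off by
default — real lactation-stage effects exist but their magnitudes are not
specified anywhere usable). Passing tests therefore demonstrate estimator
correctness and calibration under a plausible compositional model, not
performance on real amplicon data.

## Problem sizes and numerical choices

Test and acceptance runs use the cohort defaults (74 animals × 3 timepoints)
for enterotyping and host links; 15–16-sample scenarios with 200 null draws
for assembly; 500 replicate null simulations at 99 permutations for PERMANOVA
calibration; and 20 planted replicates for the RMT detector — sizes chosen so
the full chain demonstrates calibration in minutes on one core. Seeds are
threaded explicitly through every stochastic step; identical seeds give
identical results throughout. Permutation p-values use the add-one estimator
(1 + exceedances)/(1 + permutations), so the smallest attainable p is
1/(n_perm + 1). Ties in PAM swaps and binning order are broken
deterministically by index.
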