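# Methods

This note records the models implemented in `adnapop`, their
assumptions, the numerical choices that were genuinely open, and what
the synthetic-data tests do and do not demonstrate.

## Genotype representation

Analyses run on pseudo-haploid calls: one sequenced allele per SNP per
individual, coded 0/2 in EIGENSTRAT convention with `9` (internally −1)
for missing. Population allele frequencies are the mean alternate-allele
dosage over covered individuals divided by two; individuals missing at a
SNP simply drop out of that SNP's frequency. Genetic positions are
Morgans internally and centimorgans at user-facing interfaces, so the
e^(−2tl) terms in segment dating never mix units. Sex chromosomes are
parsed but excluded from all autosomal statistics. Coverage filtering is
strict (`n_snps_covered > min_snps`, default gate 20,000), with the
at-least variant available by passing `min_snps − 1`.

## f4-statistics and the block jackknife

f4(A, B; C, D) is the average over usable SNPs of
(p̂_A − p̂_B)(p̂_C − p̂_D). In *allsnps* mode (the default) each statistic
uses every autosomal SNP covered in all of its own populations; in
intersection mode all statistics share the SNPs covered across every
population of the model. Uncertainty comes from a delete-one-block
jackknife over contiguous blocks that respect chromosome boundaries.
The default scheme targets ~0.05 Morgans per block capped at 700 blocks
(whichever is coarser), split into equal SNP counts per chromosome. For
a single f4 the weighted delete-m jackknife of Busing, Meijer & van der
Leeden (1999) is used, with block weights equal to their SNP counts; the
joint covariance of the stacked f4 vector inside the model fit uses the
unweighted delete-one-block outer-product estimator (the two coincide
for the default equal-count blocks).

## Admixture model fitting

With rights R_1..R_m (R_1 the anchor) the m − 1 statistics
y_j = f4(T, R_1; R_j, R_1) form a complete basis for the span of all
f4(T, ·; ·, ·) over the right set, so the mixture model reduces to
y = Xw with X_{ji} = f4(S_i, R_1; R_j, R_1) and Σw = 1. Weights minimize
the residual in the metric Ω(w), the jackknife covariance of the
residual vector, obtained by linear contraction of the joint covariance
of (y, X); the fit iterates metric and weights a few times from a
uniform start (four iterations; the solution is stable after two). The
residual norm at the optimum is referred to χ²(m − L), a conventional
degrees-of-freedom choice documented here because different
implementations differ; weights are unconstrained in sign, with negative
weights marking the model infeasible rather than being clipped. Weight
standard errors are delete-one-block refits at the converged metric,
combined with the standard jackknife variance formula. When the residual
covariance is ill-conditioned (condition number above 1e12) a ridge of
1e−10 × trace is added with a warning; this arises only in degenerate
constructions (e.g., a target identical to a left population).

Simulation calibration (see the acceptance tests): at 50,000 SNPs with
per-edge drift F ≈ 0.02–0.06, 15 individuals per population and 10%
missingness, two- and three-way mixtures are recovered with mean
absolute error ≈ 0.03 and 2-SE interval coverage ≈ 93–95%. A small
residual attenuation-type bias from sampling noise in the source
frequencies (errors-in-variables) remains at extreme mixture weights;
it shrinks with source sample size and is not corrected, matching
standard practice for this class of estimator.

## Model space, parsimony, and representative models

Three schemes are enumerated per target: broad (all 255 non-empty
subsets of the eight proxy sources; core 14 rights), western (Levantine
proxy moved to the rights; 127 subsets of the remaining seven) and
eastern (the three eastern proxies as candidate lefts, the five western
proxies moved to the rights; 7 subsets). A valid model M is discarded as
non-parsimonious when removing one source leaves a valid model M′ whose
fit is not significantly worse: the statistic max(0, χ²_M′ − χ²_M) is
referred to χ²(1), and p ≥ 0.05 triggers discard. No multiple-testing
correction is applied across the 134 western+eastern models — the
reported models are those *not* rejected, so the convention is
conservative in the same direction as the analysis it reproduces.

The representative model maximizes the main grouped ancestry component
(Sicilian-Aegean = Greece BA + Sicily EMBA for western models, Levantine
for eastern; Sardinia LBA + Iberia EBA group as western-Mediterranean).
When both schemes validate, the larger main contribution wins, compared
on grouped weights; ties prefer fewer sources, then higher p-value —
choices the underlying procedure leaves open, fixed here in the spirit
of parsimony. `min_ancestry` reports the smallest weight of a source
across an individual's valid models (0 when some valid model omits it),
the conservative lower bound used for presence/absence statements.

## PCA projection, shrinkage, and the cline estimator

The reference PCA centers each SNP by its reference mean dosage and
scales by √(p̂(1−p̂)) with p̂ a pseudocount-shrunk frequency; monomorphic
SNPs are dropped (counted in a warning) and missing reference calls are
mean-imputed. Ancient individuals are projected by least squares of
their normalized calls on the loadings restricted to covered SNPs
(default gate 20,000 overlapping SNPs). Because projected samples did
not shape the axes they are pulled toward the origin in high dimensions;
per-component shrinkage factors are estimated by leave-one-out
projection of up to 30 reference individuals
(factor_k = mean|LOO coordinate| / mean|full coordinate|, clipped to
(0, 1]) and divided out. This is a standard, testable surrogate for the
shrinkage modes of established PCA tools; it assumes the projected
sample is *not* part of the reference panel, and it is meaningful only
for components carrying structure — on a panel whose K-th component is
pure noise the correction legitimately inflates that axis.

The cline estimator projects a sample's (PC1, PC2) position onto the
segment between two cluster centroids and clamps to [0, 1]; with
centroids from the two source clusters the fraction is linear in the
true mixture weight in expectation. Site diversity is the mean pairwise
Euclidean distance in (PC1, PC2) over all unordered pairs, gated at ten
projectable individuals per site; a variant excluding individuals above
10% of a named ancestry (per `min_ancestry`) supports factoring one
component out of diversity comparisons.

## Pedigree simulation and relatedness analytics

Founders carry two uniquely labeled haplotypes per chromosome; each
meiosis places crossovers as a Poisson process at rate 1 per Morgan
(no interference, uniform map) and transmits an alternating mosaic. IBD
between two individuals is the union of maximal intervals where any
haplotype pairing shares a founder label; ROH is the same relation
within one individual. The default genome is 22 chromosomes with
human-like relative lengths summing to 35 Morgans. Consequences used as
exact oracles: parent–offspring IBD covers the whole map; siblings share
≥1 haplotype over 3/4 of the map in expectation; the offspring of
parents with kinship F carries F × map length of autozygosity in
expectation (221.25 cM for first cousins on the 3,540 cM reporting map;
the simulator's own 3,500 cM map differs by ~1%).

Relationship classes are assigned from segments >12 cM: no segment
>16 cM ⇒ unrelated; total above a first-degree threshold ⇒
identical/1st; above a second threshold ⇒ 2nd–4th; otherwise multiple
long segments ⇒ 5th–7th, a single one ⇒ unrelated-detectable. The two
thresholds (2,175.5 and 263.0 cM) are not magic numbers in code but a
data file regenerated by `scripts/calibrate_relatedness.py` (fixed seed
2024, 150 replicates per relationship) as geometric midpoints between
the empirical distributions of adjacent bands; the 2nd–4th / 5th–7th
distributions genuinely overlap, so only the first-degree band is
near-perfectly separable (the acceptance test requires ≥95% there).

Pairwise mismatch rates x are fractions of jointly covered autosomal
SNPs with differing pseudo-haploid calls, with 95% CIs x ± 1.96 × SE
from the weighted block jackknife; kinship is r = 1 − 2(x − b/2)/b with
b the mean mismatch of presumed-unrelated pairs (≥3 pairs required).
Estimates outside [−1, 1] are reported unclamped with a warning, since
raw values with CIs are more informative at low coverage.

Segment dating combines the geometric coalescent prior
(1/2N_e)(1 − 1/2N_e)^(t−1) with a long-segment density proportional to
(2t)² e^(−2tl) (l in Morgans) on a discrete grid t = 1..t_max, t_max
chosen so the truncated tail is below 1e−6. Quantiles treat the mass at
integer t as spread over (t − ½, t + ½], which reproduces the continuous
Gamma(3, 2l + λ) limit (λ = −ln(1 − 1/2N_e)) to within 2%; for a 16 cM
segment at N_e = 1000 the posterior median is 8.3 and the 95th
percentile 19.6 generations. Published applications of this style of
calculation quote 8.0 and 19.3; the residual few-percent gap is
consistent with differences in discretization and end-condition
conventions of the underlying density, which are not fully specified by
the formulation adopted here.

## Haplogroup diversity

ISOGG labels are truncated to k leading characters before counting;
k = 4 is the default (the finer figure-style convention) with k = 3
available (the coarser text-style convention) — both appear in practice
and the choice is left explicit rather than silently resolved. The
Inverse Simpson index is reported with two estimators: plug-in 1/Σp_i²
and the without-replacement form 1/[Σ n_i(n_i−1)/(n(n−1))], the default,
matching the definition via two males sampled without replacement; the
two differ noticeably at n ≈ 5–10, which is why the estimator is always
recorded in the output. Sites need ≥5 males (each above a 100,000-SNP
coverage gate when coverage is known); an all-singleton site has
infinite unbiased index and is reported as such.

## Synthetic cohort generator

Population structure is a rooted tree with Balding–Nichols drift per
edge: child frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F) around the parent
frequency p, giving exact moments (E = p, Var = F·p(1−p)) for oracle
tests; ancestral frequencies are Uniform(0.05, 0.95). The bundled
default tree pairs each grouped ancestry component with at least one
"sister" right population so that the rights are informative, while the
two members within the Sicilian-Aegean and western-Mediterranean pairs
share their terminal node and stay nearly indistinguishable — mimicking
the resolution structure of real panels. Edge F values (0.01–0.12) are
of the order of within-Eurasian ancient differentiation. Admixed targets
draw two alleles Binomial(2, Σ α_k p_k) and pseudo-haploidize;
admixture is instantaneous (no local-ancestry tracts), which suffices
for frequency-based statistics but not for tract-length methods — out of
scope here.

What the generator does *not* emulate: post-mortem damage and
contamination, linkage disequilibrium within populations (SNPs are
independent given the tree), reference bias, and non-uniform
recombination maps. Passing tests therefore validate the estimators
under their own model assumptions; on real data, LD makes the effective
number of independent loci smaller than the SNP count (the block
jackknife exists precisely to absorb this) and damage/contamination add
error modes the tests do not probe.

## Pipeline and problem sizes

The bundled pipeline (simulate → qpadm → models → pca → relatedness →
diversity → report) runs every stage on a synthetic cohort of 4,000
SNPs, 12 individuals per population and 12 admixed targets at two
sites — sizes chosen so a complete run takes well under a minute on one
CPU while still exercising all 134 models per individual. All
randomness flows from a single root seed expanded per stage; rerunning
with the same config and seed reproduces every output byte for byte.
The acceptance tests use larger, documented sizes per analysis (50,000
SNPs for weight recovery; 200 pedigree replicates; 500 pairs for CI
coverage), which are the package's reference operating points for the
claims above.
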