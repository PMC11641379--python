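# Methods

## Morphometric similarity and the regional statistic

Each subject is summarised by a 34 x 13 table: the 34 left-hemisphere
Desikan–Killiany cortical regions by 13 features (area, fold index,
curvature index, Gaussian curvature, mean curvature, thickness, volume;
mean/radial diffusivity, fractional anisotropy and the three diffusion
tensor eigenvalues). Features arrive in incommensurate units, so each
feature is z-scored across the 34 regions (sample SD, ddof = 1; the
statistic is invariant to the ddof choice applied uniformly). The subject's
morphometric similarity network is the 34 x 34 matrix of Pearson
correlations between region rows across the 13 features; the diagonal is
fixed at 1 and excluded everywhere. The regional morphometric similarity
(MS) statistic is the mean absolute off-diagonal correlation per region,
which lies in [0, 1].

Consequences of the z-scoring step worth keeping in mind:

* the pipeline is invariant to any affine rescaling of a raw feature
  column (units never matter), and
* any feature component that is *constant across regions* within a subject
  is removed exactly. Group differences in feature means therefore cannot
  move regional MS; only differences in the between-region correlation
  structure can. This is deliberate — the statistic measures patterning,
  not level — and it drives the design of the synthetic generator (below).

## Group contrast

Per region, ordinary least squares of regional MS on an intercept, the
group indicator (biomarker-positive = 1, so positive t means higher MS in
the positive group) and four covariates: age (years), gender (coded M = 1,
F = 0 so coefficients are reproducible), education (years) and MMSE
(points, 0–30). Two-sided p-values on n − 6 degrees of freedom;
Benjamini–Hochberg step-up adjustment across the 34 regions (the step-up
variant is the standard FDR choice in this literature). The fit goes
through statsmodels OLS; a response with zero variation across subjects is
reported as beta = 0, t = 0, p = 1 rather than a 0/0 artefact. Mixed
biomarker profiles (one marker positive, the other negative) are excluded
from the contrast with a logged count; the group cut-points are CSF
amyloid-beta >= 980 pg/mL *and* tau <= 24 pg/mL for the negative group
(inclusive on both), with the strict complement of both defining the
positive group, so the three classes partition the plane.

## PLS association

The response y is the length-34 contrast t-map; the predictors X are the
34 x G expression matrix. With one latent component and a univariate
response, the PLS solution is closed-form: standardise the columns of X
(mean 0, SD 1 across regions, ddof = 1), centre y, and take
`w = X_s' y_c / ||X_s' y_c||`, scores `t = X_s w`. A sign convention
negates w and t if corr(t, y) < 0, so reported r is non-negative (for the
self-fit this holds automatically since `t'y = ||X_s' y_c||^2 >= 0`; the
convention matters for resampled refits). The closed form is verified in
the tests against scikit-learn's PLSRegression first component.

**Permutation significance.** The response entries are shuffled uniformly
(default 10^4 times, vectorised in chunks) and the score–response
correlation recomputed; `p = (1 + #{perm >= observed}) / (n_perm + 1)`.
Permutations tying the observed statistic in real arithmetic (e.g. a full
reversal of a symmetric response) must count as ties, so the comparison
uses a relative floating tolerance of 1e-12. An exhaustive enumerator is
provided for up to 8 regions and is used as the exactness oracle in tests.
Spatial-autocorrelation-preserving nulls are out of scope; the permutation
is the naive exchangeable one.

**Bootstrap gene scores.** Each of the default 1000 replicates resamples
the 34 regions with replacement, refits the component (re-standardising
the resampled columns, since the estimand is defined on standardised
predictors) and aligns the replicate weight vector's sign to the original
fit by dot product — components are sign-indeterminate and unaligned
replicates would inflate the SE. Replicates with fewer than 3 distinct
regions or any zero-variance resampled column are redrawn (bounded
retries). The per-gene SE is the sample SD of replicate weights;
`z = w_g / SE`. Genes with SE = 0 get undefined z and are excluded from
selection with a log message. Per-gene `p = 2(1 − Φ(|z|))`, BH-FDR over all
genes with defined z, and the signed lists are `PLS+ = {z > 3, q < 0.05}`,
`PLS− = {z < −3, q < 0.05}` (strict inequalities), sorted by |z|
descending. The permutation and bootstrap streams are spawned independently
from one integer seed, so identical seeds give bit-identical outputs.

## Expression preparation

Donor-level tables (donor, sample, coordinates in mm, probe, intensity,
above-background flag) become the 34 x G matrix through:

1. **Intensity filter** — a probe is retained iff it is above background in
   at least 50% of samples, pooled over donors (inclusive boundary; the
   0.5 fraction mirrors the convention of the standard toolboxes; pooling
   rather than per-donor filtering is our choice and is documented here).
2. **Sample assignment** — each sample to the nearest region centroid
   within 2 mm (Euclidean; parcels are abstracted to centroids, voxel-level
   assignment is out of scope). Regions left empty for a donor receive that
   donor's single globally nearest sample as a fallback, so every donor
   covers every region; per donor/region/probe values are means over
   assigned samples.
3. **Differential stability** — per probe, the mean over donor pairs of the
   Spearman correlation between regional profiles on commonly covered
   regions (>= 3 required per pair; constant profiles skip the pair with a
   log; a probe whose pairs are all skipped has undefined stability). Per
   gene, the probe with maximal stability wins; ties break to the
   lexicographically smallest probe id.
4. **Scaled robust sigmoid** — per donor and gene,
   `s_i = 1 / (1 + exp(−(x_i − median) / (IQR / 1.35)))`, then min-max
   rescale to [0, 1] over regions. IQR/1.35 approximates a normal SD, making
   the transform outlier-resistant yet comparable to a z-score sigmoid; it
   is invariant to affine transforms of the input and strictly monotone.
   Zero-IQR (degenerate) gene profiles are dropped for that donor with a
   log.
5. **Donor averaging** — unweighted mean over donors with coverage; a
   region x gene cell with no coverage at all is an error.

## Enrichment

One-sided (greater) Fisher exact test: `p = P(X >= a)` for
`X ~ Hypergeom(N = |background|, K = |target|, n = |query|)`, computed via
the scipy hypergeometric survival function and checked in tests against a
direct pmf tail summation. Only enrichment (not depletion) is tested, which
matches how overlap tests are used in this setting. The odds ratio is the
sample estimate `ad / bc` (not the conditional MLE some packages print;
noted so numbers are comparable across tools), with OR = 0 for empty
overlap and OR = inf flagged when bc = 0 with ad > 0. Query genes outside
the background are dropped with a log; BH adjustment is applied within each
query x collection family, never pooled across collections. Cell-type
collections are compiled by merging study lists per label, deduplicating,
dropping requested labels, and restricting to the background; disease sets
are the background-restricted union of their source lists.

## Synthetic-data generator

The generator emulates the study conditions so every stage is testable
offline. Defaults: 172 biomarker-negative and 126 biomarker-positive
subjects; covariate means/SDs and male fractions per group matching the
cohort's published demographics (age 71.05 (7.10) vs 77.18 (7.92) years,
education 16.70 (2.38) vs 16.01 (2.54) years, MMSE 28.85 (1.47) vs
26.06 (4.62), 71/101 vs 60/66 males/females); CSF values drawn inside the
corresponding classification regions; 2000 genes with 50 positive and 50
negative pattern-tracking signal genes at SNR 1; six expression donors.

**Feature model.** For subject s and region i the 13-feature vector is

    f_si = sqrt(alpha_i) * lambda_si * g_s + sqrt(1 − alpha_i) * eps_si

with `g_s` a subject-level standard-normal vector, `eps_si` independent
noise, and `lambda_si` a random ±1 per-region loading. The loading is
essential: a shared component constant across regions would be removed
exactly by the per-feature z-scoring (see above) and leave the similarity
structure untouched, whereas the sign-flipping component survives it and
yields `|corr| ≈ sqrt(alpha_i * alpha_j)` between regions — exactly what
the mean-|r| statistic measures. Regional MS is therefore monotone in
alpha and approaches 1 as alpha → 1 (tested at alpha = 0.999; at smaller
feature counts the z-scoring amplifies noise on weakly expressed shared
features, so the approach to 1 is gradual). The group effect adds
`effect_delta` (default 0.15) to alpha in the target regions (defaults:
caudal anterior cingulate and lateral occipital, the two regions reported
with increased similarity) for positive-group subjects only — the effect
lives in the similarity structure, not in feature means, so it is visible
to regional MS and invisible to naive mean comparison, a useful negative
control. Baseline `base_alpha = 0.3` puts mean regional MS near 0.29,
within the range typical of empirical similarity networks.

**Expression.** Signal columns are
`sign * standardize(pattern) * snr + N(0, 1)` noise, unit-rescaled; null
columns pure rescaled noise. The end-to-end pipeline plants the signal
against the *observed* contrast t-map, so the transcriptomic signal tracks
the group effect exactly as measured — the configuration the recovery
checks assume. Donor-level emulation distorts the ground truth per donor
with a random affine gain/offset (harmless to the rank-based and
robust-sigmoid steps), emits two probes per gene (one low-noise, SD 0.1,
one noisy, SD 0.5, on a [0, 1] intensity scale — a realistic spread for
microarray replicate probes), flags the good probe above background at rate
0.9 versus 0.36 for the bad one, and covers each region with probability
0.9 per donor with two samples per covered region jittered < 1 mm around
centroids placed >= 10 mm apart.

**Gene sets.** Per sign, one enriched set draws 60% of its 50 members from
the same-signed signal genes and the rest uniformly from the background;
five null sets are uniform draws.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: cortical geometry and spatial
autocorrelation of both MRI features and expression (the permutation null
is exchangeable, which real spatial maps violate); scanner/site effects and
longitudinal drift; heavy-tailed or skewed feature noise (everything is
Gaussian); probe reannotation against real annotation releases; donor
batch effects beyond affine distortion; and the many-to-one structure of
real parcel geometry (centroids stand in for parcels).

## Numerical conventions

* Sample (ddof = 1) SDs throughout z-scoring, standardisation and
  bootstrap SEs.
* Correlation matrices are clipped to [−1, 1] and symmetrised against
  floating excursions; diagonals set to exactly 1.
* BH step-up is the 5-line sorted running-minimum implementation, checked
  against statsmodels `multipletests`.
* Permutation tie counting uses a 1e-12 relative tolerance (see above).
* All writers use fixed float formatting and sorted orderings, so repeated
  runs with one seed are byte-identical.
* Oracle tolerances in the test suite: 1e-12 for correlation/tail-sum
  identities, 1e-10 for regression and weight-vector equivalences.

## Known limitations

* One latent component only; no component-selection heuristics.
* Exchangeable permutation null (no spatial "spin" surrogates).
* Per-gene p-values assume normality of the bootstrap z; heavy-tailed
  weight distributions would make the FDR nominal rather than exact.
* The cohort generator draws covariates independently of the planted
  similarity effect, so covariate adjustment is exercised but confounding
  scenarios are not.
* Live annotation services (GO/KEGG lookups, protein-interaction
  retrieval) are out of scope by design; enrichment is generic
  GMT-driven overrepresentation.
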