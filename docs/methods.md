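# Methods

`ssrimet` implements a pharmacometabolomics analysis pipeline for
longitudinal SSRI treatment studies: a targeted plasma metabolite panel
measured at baseline, week 4 and week 8 of citalopram/escitalopram
treatment, with 17-item Hamilton Depression Rating Scale (HRSD-17) scores at
each visit. The pipeline has five stages — synthetic cohort generation,
preprocessing, per-metabolite longitudinal scans, regularized
partial-correlation networks, and ratio-trait genetics — each usable on its
own. This note records the models, the parameters that matter, and the
design decisions taken where more than one reasonable choice existed.

## Synthetic cohort generator

The generator exists so that every downstream stage can be tested against a
known truth. It emulates the statistical structure of a ~290-subject
depression cohort, not the chemistry of any instrument.

**Latent metabolite model.** A ground truth holds a p x p positive-definite
precision matrix Θ; baseline latent vectors are drawn from N(0, Θ⁻¹).
`make_precision_matrix` plants community-block structure: metabolites are
split into near-equal blocks and each block receives
`round(within_density * n_pairs)` off-diagonal entries of `-edge_strength`
(negative entries, hence positive partial correlations). When the edge
budget covers a cycle through the block, a random cycle is laid down first
so planted communities are connected — community recovery is otherwise
ill-posed. The diagonal is `diagonal_margin` plus the absolute row sum
(strict diagonal dominance, hence positive definiteness); planted partial
correlations are therefore roughly
`edge_strength / (diagonal_margin + degree * edge_strength)`, i.e. the
block density and edge strength jointly set both topology and effect size.

**Longitudinal structure.** Visits evolve by a stationary AR(1) carry-over:
x_t = ρ x_{t-1} + sqrt(1-ρ²) ε_t with innovations from the same group
covariance, ρ = 0.6 by default. On top of this, each subject carries a
stable per-metabolite level offset (sd 0.3 on the log2 scale, visit
constant), giving the within-subject correlation that the mixed models
downstream are meant to absorb. The offset is deliberately per-metabolite
rather than shared across the panel: a shared offset would induce a
rank-one correlation background across all metabolite pairs and hence
partial-correlation structure that was never planted. Note that even the
per-metabolite offset inflates marginal variances, so the observed-data
precision matrix differs slightly from the planted Θ; planted-structure
recovery studies therefore run with `subject_intercept_sd=0`.

**Exposure and outcome.** Drug-exposure effects are per-visit mean shifts in
standardized units added at week 4 and week 8. Responder labels are
Bernoulli(0.693), the observed 8-week response rate in the cohort this
emulates. HRSD-17 trajectories are drawn per group and visit from rounded
normals floored at 0, with baseline resampled until >= 14 (the study
inclusion rule); the group means/sds default to the observed values
(responders 21.86±5.17 → 10.10±5.77 → 5.79±3.27; nonresponders 22.03±4.28 →
15.03±6.58 → 14.90±4.15). HRSD values are drawn independently of the
metabolites by default; an optional coupling term adds
`coef * zscore(HRSD_t)` to a chosen metabolite's latent at every visit for
testing the symptom-association scan. No causal direction between
metabolites and symptoms is asserted.

**Differential edges.** Outcome-dependent network structure is planted as a
pair of precision matrices that differ only at declared edges
(θ_ij = -w sqrt(θ_ii θ_jj) per group); the low-outcome group (responders,
who end treatment with low HRSD) and high-outcome group use their respective
matrices at every visit. This two-population construction matches the
median-split design of the differential network test; no continuous
moderation is simulated.

**Raw abundances.** Latents map to positive raw abundances via
2^(10 + 1·(latent + subject offset)), so the log2 transform in
preprocessing is meaningful and multiplicative missingness/QC behave as
they would on instrument data. Instrument artifacts (batch effects,
pooled-QC drift, detection limits) are not simulated — a passing pipeline
here says nothing about robustness to those.

**Genotypes.** Biallelic dosages are Binomial(2, maf) with per-variant MAF
uniform in a range, optional MCAR missingness, and declared
(variant, trait, beta) effects applied additively by `genetic_trait`.
Linkage disequilibrium is not simulated.

## Preprocessing

Pipeline order is fixed: missingness QC → kNN imputation → log2 → unit
variance scaling.

- **QC**: metabolites with missing fraction strictly above 20% (default) are
  dropped, per visit; a metabolite must survive at every visit to stay in
  the panel.
- **Imputation** is k-nearest-neighbour (k=10 default) within each visit:
  distances are Euclidean over mutually observed entries of per-metabolite
  standardized columns, rescaled by the fraction observed; a missing cell
  becomes the mean of the metabolite among the k nearest subjects. Because
  standardization is affine and imputation is a neighbour mean, running the
  imputer on the standardized scale and mapping back is exactly
  neighbour-mean imputation on the raw scale. Imputation is per visit so no
  longitudinal signal leaks into the filled values.
- **Scaling**: log2, then center and divide by the n-1 standard deviation.
  For single matrices (`log2_scale`) the constants come from that matrix.
  For cohorts (`preprocess_cohort`) the default is *pooled* scaling: the
  centering/scaling constants are estimated once from the three visits
  stacked and applied to each visit. Per-visit centering would subtract each
  visit's own mean and thereby erase exactly the baseline-to-week mean
  shifts the exposure scan is built to estimate; pooled constants preserve
  them while still giving each metabolite unit pooled variance.
  `pool_scaling=False` restores strict per-visit standardization.
- **Outcome labels**: responder = at least 50% HRSD reduction from baseline
  to exit; remitter = exit score <= 7; complete non-responder = less than
  30% reduction. The three labels are computed independently of each other
  (a responder can also be a remitter; with the study's baseline >= 14
  inclusion rule a remitter is never a complete non-responder, since a drop
  to 7 from at least 14 is already a 50% reduction).

## Longitudinal scans

- **Exposure scan** (`exposure_scan`): per feature, a random-intercept
  linear mixed model (REML, statsmodels) of the standardized value at
  baseline and the target week on a week indicator, age, sex (F=1) and
  baseline HRSD; the indicator coefficient is the exposure effect in
  pooled-SD units. Weeks 4 and 8 are scanned separately. Inference is Wald
  z on the fixed effects — the standard large-sample choice for this model
  class; at small n it is mildly anti-conservative, which matters for the
  FDR-calibration discussion below.
- **Symptom scan** (`symptom_association_scan`): same model class across all
  three visits with the time-varying HRSD score (or its change from
  baseline, `regressor="change"`) plus age and sex; the HRSD coefficient is
  reported. A symptom score with no variance yields NA rows with a
  `degenerate` tag rather than an error.
- **Metabolite ratios** (serotonin turnover 5HIAA/5HT, I3AA/TRP, MHPG/TYR,
  PXAN/XAN, URIC/XAN, XAN/XANTH, 4HPAC/TYR by default) are differences of
  log2 abundances computed *before* unit-variance scaling, then
  standardized with pooled constants, and scanned alongside single
  metabolites.
- **FDR**: Benjamini-Hochberg step-up (statsmodels), cutoff 10% by
  convention in the scans.
- **Two-step time course** (`timecourse_two_step`): step 1 fits, per
  metabolite, least squares of the value on polynomial time (degree 2, the
  maximum identifiable with three visits), a group dummy, and group x time
  interactions; the global Wald F-test of all non-intercept terms is
  BH-adjusted and metabolites passing 5% FDR are flagged. Step 2 runs
  backward elimination at alpha = 0.05 and reports surviving
  group-difference terms. Because every subject contributes three rows,
  the F- and t-tests use subject-clustered covariance; with iid-by-subject
  OLS the repeated measures would make group-term inference
  anti-conservative and the null calibration would fail. Estimates remain
  plain least squares.

## Partial-correlation networks

- **Estimator**: graphical lasso (scikit-learn's coordinate-descent solver
  behind this package's `graphical_lasso` surface) maximizing
  log det Θ - tr(SΘ) - λ Σ_{i≠j} |Θ_ij| on the sample correlation matrix;
  λ=0 short-circuits to direct inversion, λ >= max off-diagonal |S| to the
  exact diagonal solution. Convergence is judged by the KKT stationarity
  residual of the penalized objective (accepted when <= 100x the solver
  tolerance), not by the solver's dual-gap warning alone: the dual gap can
  hover just outside tolerance at a numerically valid solution, and
  discarding those fits would silently drop penalties from the selection
  path. Edge weights are partial correlations
  w_ij = -θ_ij / sqrt(θ_ii θ_jj).
- **Penalty selection**: EBIC(λ) = -2 ℓ(Θ̂) + E log n + 4 γ E log p with
  ℓ the Gaussian log-likelihood at the penalized estimate, E the nonzero
  upper-diagonal count, γ = 0.5. The default grid is 100 log-spaced values
  from λ_max down to 0.01 λ_max; ties prefer the larger penalty. A known
  property of this criterion (shared with the reference R implementation)
  is that when true edges are strong, the minimum sits one to a few noise
  edges denser than the clean support: decreasing λ un-shrinks true edges,
  and the likelihood gain drags a few sampling-noise edges across the
  E log n + 4γE log p price. Support precision in simulations accordingly
  plateaus around 0.85-0.95 even where the path contains a cleaner model.
- **Bootstrap** (`bootstrap_network`): subjects resampled with replacement,
  penalty re-selected per resample by default (`refit_lambda=False` pins the
  full-data penalty); reported are elementwise median weights and edge
  inclusion frequencies. Resamples that lose all variance in a column are
  redrawn and counted.
- **Communities** (`walktrap_communities`): walktrap (python-igraph) on
  absolute edge weights, random-walk length 4, partition cut at maximum
  modularity. Negative-weight community handling is out of scope; an
  edgeless graph returns singletons with modularity 0.
- **Differential networks** (`compare_networks`): subjects are split at the
  outcome median (ties to the low group); both group networks are
  EBIC-selected; the structure statistic M = max |Δedge| and
  global-strength statistic S = |Σ|w₁| - Σ|w₂|| are referred to a
  permutation null that shuffles group labels and re-estimates both
  networks, with add-one p-values. Per-edge p-values come from the same
  permutations over the family of edges with nonzero observed weight in
  either group, Holm-adjusted. Setting `include_outcome_node=True` appends
  the standardized outcome as an extra node before estimation. Only
  independent-group permutation is implemented; comparing the same
  subjects at two time points is a paired problem this test does not
  support.
- **Interaction validation** (`validate_interaction`): ordinary least
  squares of one metabolite on the other, the outcome, and their product;
  the product-term t-test is the reported check.

## Genetics

- **HWE exact test**: conditional on allele counts, P(h heterozygotes) is
  computed in closed form with log-gamma arithmetic; the two-sided p sums
  probabilities no greater than the observed configuration's (with a 1e-12
  relative tie tolerance). Monomorphic variants return 1.
- **Variant QC** drops variants with call rate < 0.95, minor allele
  frequency < 0.05, or HWE p < 1e-5. The published description says
  "call rate <5%"; read literally that drops almost nothing, so it is
  interpreted as missing rate > 5%, the standard QC convention. Thresholds
  are parameters.
- **Population structure**: principal components of the column-standardized
  dosage matrix (missing dosages mean-imputed per variant), first five used
  as covariates by convention.
- **Ratio traits**: log2(numerator) - log2(denominator), standardized;
  subjects beyond 4 sd excluded, then re-standardized.
- **Association scan**: per variant, least squares of the trait on dosage
  plus covariates (age, sex, PCs, optionally the visit HRSD score);
  subjects missing that variant's dosage are dropped; constant dosages give
  NA rows. Additive coding throughout; sex coded F=1.

## Calibration notes and known limitations

- The differential network permutation test is exact under exchangeability
  regardless of how well the networks are estimated; its size was verified
  at the nominal 5% over 100 replicate null cohorts (permutation count 59,
  which makes the 5% level exactly attainable: p <= 0.05 iff the observed
  statistic ranks in the top 3 of 60).
- Under a global null, the probability that BH at level q makes at least
  one discovery *is* the FDR — about q under independence, less under
  positive dependence. Replicate-level "zero discoveries" rates around
  1 - q (not 1 - q/2) are therefore expected behavior of a correctly
  implemented scan, not evidence of miscalibration.
- EBIC support selection: see the precision plateau noted above. Where edge
  lists feed downstream biology, the bootstrap inclusion frequencies are
  the more robust evidence.
- The generator draws HRSD and metabolites independently unless coupling is
  requested, so symptom-scan discoveries on default synthetic cohorts are
  false positives by construction; tests exploit this.
- Problem sizes in the test-suite simulation studies (cohorts of 80-600
  subjects, panels of 8-31 metabolites, 50-200 permutations/replicates)
  were chosen to make each property measurable with comfortable margins on
  a single CPU; all are parameters, and nothing in the implementation
  depends on them.
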