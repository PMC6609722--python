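# ssrimet

Pharmacometabolomics of SSRI exposure and response: a tested, reusable
implementation of the analysis pipeline used to study how 8 weeks of
citalopram/escitalopram treatment reshapes a targeted panel of 31
neurotransmitter-related plasma metabolites in depressed outpatients, and
how those changes relate to symptom improvement and to genetics.

The package is aimed at statisticians and computational biologists who want
to run (or stress-test) this class of analysis without access to patient
data: every stage can be exercised end-to-end on synthetic cohorts with
known ground truth.

## What it implements

Given subjects measured at baseline, week 4 and week 8 with HRSD-17
depression scores at each visit:

- **Synthetic cohorts** (`ssrimet.synthetic`) — latent metabolite vectors
  drawn from N(0, Θ⁻¹) with a planted block-structured sparse precision
  matrix Θ, AR(1) visit-to-visit carry-over, drug-exposure mean shifts,
  a responder/nonresponder HRSD mixture (response rate 0.693 by default),
  outcome-dependent differential edges, MCAR missingness, and biallelic
  genotypes with planted ratio-trait effects.
- **Preprocessing** (`ssrimet.preprocess`) — missingness QC (>20% dropped),
  k-nearest-neighbour imputation, log2 transform, unit-variance scaling;
  outcome labels (responder ≥50% reduction, remitter exit ≤7, complete
  non-responder <30% reduction).
- **Longitudinal scans** (`ssrimet.longitudinal`) — per-metabolite
  random-intercept linear mixed models for drug exposure (baseline vs
  week 4/8, adjusting for age, sex, baseline HRSD) and for
  metabolite-symptom association (time-varying HRSD, adjusting for age and
  sex); Benjamini-Hochberg FDR; a two-step time-course screen (global
  polynomial fit + backward stepwise selection) separating responder and
  nonresponder profiles. Metabolite ratios (5HIAA/5HT, MHPG/TYR, ...) are
  scanned alongside single metabolites.
- **Partial-correlation networks** (`ssrimet.network`) — graphical lasso
  with EBIC penalty selection (γ = 0.5), partial-correlation edge weights
  w_ij = -θ_ij/√(θ_ii θ_jj), bootstrap edge stability (median weights,
  inclusion frequencies), walktrap community detection, and a permutation
  network-comparison test (structure statistic M = max |Δedge|, global
  strength S = |Σ|w₁| − Σ|w₂||) between groups split at the outcome median,
  with Holm-adjusted per-edge p-values and optional outcome node.
- **Genetics** (`ssrimet.genetics`) — exact Hardy-Weinberg test, variant QC
  (call rate ≥0.95, MAF ≥0.05, HWE p ≥1e-5), genotype principal components,
  standardized log-ratio traits of interacting metabolite pairs (e.g.
  HGA/GR, MET/TYR) with 4-sd outlier exclusion, and covariate-adjusted
  additive association scans.

See `docs/methods.md` for the models, defaults and design decisions.

## Worked example

```python
import ssrimet as sm
import numpy as np

# plant a 31-metabolite truth: 3 communities and a -1 sd week-8 serotonin drop
truth = sm.make_precision_matrix(31, n_communities=3, seed=0)
truth.exposure_effects["t8"] = np.zeros(31)
truth.exposure_effects["t8"][2] = -1.0          # 5HT

cohort = sm.simulate_cohort(290, truth, seed=1)
cohort = sm.inject_missing(cohort, rate=0.05, seed=2)

processed = sm.preprocess_cohort(cohort)         # QC -> kNN -> log2 -> scale
scan = sm.exposure_scan(processed, cohort.clinical, week=8)
print(scan.sort_values("q_value").head(3)[["feature_id", "effect", "q_value"]])

net = sm.ebic_select(processed["t0"])            # baseline network
part = sm.walktrap_communities(net)
print(f"{net.n_edges} edges at penalty {net.penalty:.3f}, "
      f"{len(set(part.labels.tolist()))} communities, modularity {part.modularity:.2f}")
```

Output:

```
   feature_id    effect       q_value
2         5HT -1.086442  1.193311e-97
10        HVA -0.178943  4.325967e-02
22        MET  0.129666  3.521779e-01
```

The planted serotonin decrease dominates the scan — the estimated effect is
−1.09 pooled-SD units against a planted −1.0 — and

```
88 edges at penalty 0.133, 4 communities, modularity 0.66
```

the EBIC-selected baseline network keeps 88 of the 465 possible edges and
walktrap recovers four communities over the three planted blocks.

A command-line interface mirrors the library:

```bash
ssrimet simulate --n-subjects 290 --n-metabolites 31 --seed 7 --out-dir cohort/
ssrimet preprocess --in-dir cohort/ --out-dir processed/
ssrimet scan exposure --in-dir cohort/ --week 8 --out exposure.tsv
ssrimet network compare --in-dir cohort/ --n-perm 1000 --out differential.tsv
```

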