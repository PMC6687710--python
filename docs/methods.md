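# Methods

This note documents the statistical model behind the synthetic cohort,
the algorithms of each pipeline stage, the main parameter defaults and
their rationale, and the numerical choices that matter for exactness.
Problem sizes and defaults are the package's own design choices for a
desk-scale testbed of a multi-plex TMT tumor study.

## 1. Synthetic cohort model

### Design

The default design multiplexes 108 tumors into 29 six-channel plexes.
Each plex carries 4 tumors and 2 aliquots of a common reference pool;
one pool aliquot is fixed in channel 0 of every plex (the *bridge
channel*), the second sits in a random channel. That yields 116 tumor
slots, so 8 randomly chosen tumors are measured twice (in different
plexes) — replicate measurements that the bridging stage must average.

### Signal model

True protein abundance is generated on the log2 scale:

```
t[p, s] = base[p] + program effect + dosage effect + N(0, sample_sd)
```

* `base[p] ~ N(0, protein_base_sd²)` with `protein_base_sd = 2.0`,
  matching the wide dynamic range of deep proteomes;
* three latent subtypes at proportions 0.40 / 0.47 / 0.13 (exact
  largest-remainder apportionment: 43 / 51 / 14 of 108), each with a
  disjoint program of 150 proteins shifted by `de_effect_log2 = 1.0`;
* copy-number regions: a *focal* region gained with probability 0.7 in
  the focal subtype versus 0.1 elsewhere, a subtype-*neutral* region
  (gain probability 0.3 everywhere), and several background regions with
  gains and losses; genes in the two dosage regions receive a cis
  effect of `dosage_effect_log2 = 1.2` per copy state;
* `sample_sd = 0.35` of per-sample biological deviation.

The reference pool profile is the row mean of the truth matrix —
operationally, a pool mixed from all cohort samples.

### Measurement model

Reporter intensities are emitted per spectrum on the log2 scale:

```
log2 I = 14 + profile[channel] + plex_shift + loading[channel]
         + spectrum_offset + N(0, noise_sd)
```

with `plex_shift ~ N(0, 0.5²)` per plex (run-level batch effect),
`loading ~ N(0, 0.2²)` per channel (mixing error), `spectrum_offset ~
N(0, 0.5²)` per spectrum (ionization efficiency), and `noise_sd = 0.25`
residual noise. Spectra per protein per plex are Poisson(3) (min 1);
distinct peptides per protein Poisson(4) (min 2) with a 2%
single-peptide fraction. Missingness (rate 0.05) is applied at the
protein × plex level — all channels of a plex go missing together, the
structure real TMT data shows. Decoy PSMs (10% of the target count) are
score-shifted null records: target scores ~ N(5, 1), decoy scores ~
N(0, 1), which exercises the target-decoy machinery without sequence
modeling.

### Matched omics

* **RNA**: per gene, `rna = base + r·z + sqrt(1−r²)·ε` with `z` the
  standardized true protein profile. The background coupling `r` is set
  to `2·sin(π·ρ/6)` so the *Spearman* correlation hits the target
  `ρ = 0.38`; dosage genes get a stronger Pearson coupling of 0.85.
* **Mutations**: per-gene Bernoulli indicators with subtype-specific
  odds (default: one gene at baseline odds 0.0175/(1−0.0175) with odds
  ratio 20 in the focal subtype; four unbiased genes).
* **CNV segments**: region-level segments (log2 = 0.45·state + N(0,
  0.05²), ~1 probe per 800 bp), plus two sub-threshold noise segments
  per tumor designed to fail the probe-count or length filter.
* **Screen**: RSA-style depletion scores and Bayes factors across 5
  cell lines; the first 5 focal-region dosage genes ("planted"
  candidates) and 2 focal program genes are essential (RSA ~ N(−5,
  0.5), BF ~ N(6, 1)), everything else null.
* **Survival**: exponential times with log hazard `0.5` per standard
  deviation of 3 prognostic proteins; uniform censoring on 1–10 years.

Everything is deterministic given `CohortConfig.seed`; the pipeline
derives per-stage seeds from one global seed by hashing the stage name
(sha256) so any stage can be re-run in isolation.

## 2. Two-step FDR assembly

PSM score thresholds are set by target-decoy competition with the
concatenated-search estimator `FDR(t) = 2·D(t)/(T(t)+D(t))` (the
separate-search `D/T` is available). Thresholds are score values, so
tied PSMs are admitted or excluded together. Step 1 filters at 0.1%
PSM FDR and keeps protein groups with ≥ 2 distinct peptides
(modification annotations stripped before counting); step 2 re-filters
all PSMs at 1% and keeps only spectra mapping to step-1 groups —
increasing spectral depth without admitting new groups. Protein-level
FDR is estimated as decoy groups surviving the step-1 gate divided by
target groups.

## 3. Pool-referenced bridging

Within each plex, every channel is scaled onto the bridge channel by a
rank-invariant procedure: iteratively keep features whose rank
difference between channel and pool is below a shrinking tolerance
(5% of the current set, halved per iteration, floor 1%, ≤ 10
iterations), then fit one multiplicative factor from the log-ratios
over the invariant set. **The factor is the median log-ratio** (the
geometric mean is available as an option). The median is chosen
deliberately: whenever a majority of the invariant set is exactly
proportional between channel and pool, the median factor is *exact* —
outlying features (e.g. subtype-program proteins caught in the set)
cannot bias it at all. This is what makes the zero-noise recovery
guarantee below hold to floating-point precision, where a geometric
mean would carry an O(10⁻³) contamination bias.

Spectral log2 channel/pool ratios are averaged per protein; the pool
channel itself is rolled up as the geometric mean of unlogged
intensities. Across plexes, each plex's pool protein vector is
rank-invariant-normalized onto a cohort reference pool (the pool whose
median log2 abundance is the median over pools), the per-protein
abundance scale is the geometric mean of normalized pools, and each
sample is reconstructed as `scale + log2 ratio`, with replicate tumor
measurements averaged on the log2 scale. No imputation anywhere.

**Exactness.** At zero noise (`sample_sd = noise_sd = 0`) every batch
term cancels: spectrum offsets cancel inside within-spectrum ratios,
plex shifts cancel against the pool channel, channel loading is removed
exactly by the median factor, and the remaining discrepancy is one
constant per protein — removed by per-protein centering. The acceptance
suite asserts recovery to 1e-9 at the full default design scale (the
observed error is ~5e-14). Rescaling all intensities of a plex moves
the bridged matrix by at most one global constant.

## 4. Subtype discovery

Top-1000 features by median absolute deviation are consensus-clustered:
250–1000 resamples of 80% of samples (all features), complete-linkage
hierarchical clustering on one-minus-Pearson distance over
pairwise-complete observations, consensus(i,j) = co-clusterings /
co-samplings. Because features are not subsampled by default, the full
sample-pair distance matrix is computed once and sliced per resample.
The number of clusters is the first k whose consensus-CDF area grows by
less than 10% relative to k−1; the CDF area is computed as the exact
integral of the empirical step function. Nearest-centroid
classification (Pearson, ≥ 10 shared genes) is provided for external
cohorts.

## 5. Association statistics

* Differential expression: two-sided Wilcoxon rank-sum per protein
  (exact null for combined n ≤ 25 without ties, tie-corrected normal
  approximation otherwise), significance = |fold change| ≥ 1.5 **and**
  Benjamini-Hochberg adjusted p ≤ 0.05.
* 2×2 associations: two-sided Fisher exact p with the
  **conditional-MLE odds ratio** (the value exact-test software
  reports; it maximizes the noncentral hypergeometric likelihood and is
  smaller in magnitude than the sample cross-product ratio).
* Ordered 2×K tables: the 1-df CMH nonzero-correlation statistic
  `M² = (N−1)·r²` with integer scores by default; invariant to affine
  score transforms.
* Storey q-values: `pi0(λ) = #{p>λ}/(m(1−λ))` on λ = 0.05…0.95,
  smoothed by a cubic polynomial, evaluated at λ = 0.95, clipped to
  (1/m, 1]; with < 20 p-values pi0 falls back to 1 (q = BH).
* Over-representation: one-sided hypergeometric tail with BH across
  sets.

## 6. Integration

Feature-paired Spearman correlations over shared samples require ≥ 10%
non-missing support per vector. Band partitions use strict
inequalities (ρ > 0.5 high; −0.2 < ρ < 0.2 low). Differential
correlation contrasts per-feature correlation to an anchor between two
sample groups (≥ 5 samples each, BH within group).

Copy-number segments are reduced to gene level after filtering: ≥ 50
probes **and** length strictly > 400 kb; coordinates are 0-based
half-open; a gene takes the log2 of the overlapping segment with
maximal |log2| (length-weighted mean optional). The vulnerability
cascade intersects H (CNV-protein and RNA-protein ρ > 0.5 with adjusted
p < 0.25 at both levels), E (significantly elevated in the focal
subtype), and D (RSA < −3 in ≥ 1 cell line); primary candidates are
H∩E∩D, secondary (E∩D)\H, with Bayes-factor > 3 confirmation flags.

## 7. Outcome and meta-analysis

The log-rank test comes from lifelines. Univariate Cox regression is a
hand-written Newton-Raphson on the partial likelihood (covariate
standardized internally, estimate rescaled back): Breslow tie handling
by default, Efron as a cross-check (they agree to 1e-8 without ties,
and the fit matches lifelines to 1e-6); the SE comes from the observed
information; monotone likelihoods (|β| diverging) are flagged rather
than reported.

Per-gene log hazard ratios from protein, RNA and copy number are pooled
by a random-effects model with an empirical-Bayes (Paule-Mandel-type)
heterogeneity estimator: τ² solves `Q(τ²) = Σ wᵢ(yᵢ−μ(τ²))² = k−1`
with `wᵢ = 1/(seᵢ²+τ²)` (Brent's method, tolerance 1e-8, τ² = 0 when
even zero over-disperses, DerSimonian-Laird fallback on bracketing
failure). Genes are selected at Storey q ≤ 0.3. Simulation shows mean
τ̂² ≈ 0.28 for true τ² = 0.25.

## 8. What the simulator does *not* model

Peptide sequences and fragmentation, ratio compression from co-isolation
interference, intensity-dependent missingness, isotope impurity
cross-talk between channels, subclonal copy number, batch-correlated
survival confounding. These are deliberate omissions: the generator's
purpose is to give every pipeline stage a ground truth with realistic
*statistical* structure (batch layers, pool referencing, target-decoy
score mixtures, block missingness), not to emulate a mass spectrometer.

## 9. Testing strategy

Wherever feasible, tests compare against independent oracles rather
than stored outputs: exhaustive enumeration for the Fisher test (every
2×2 table with N ≤ 12) and rank-sum test (every group assignment for
combined n ≤ 10), a brute-force threshold scan for FDR filtering, a
loop-based interval-overlap oracle for CNV reduction, numerical
integration for the CDF area, an O−E hand implementation for the
log-rank statistic, lifelines for Cox, and closed forms for two-study
meta-analysis. Generator calibration (missingness, decoy fraction,
Spearman target, mutation odds) is checked by Monte-Carlo against the
configured parameters.
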