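# Methods

## Model and rationale

Editing efficiency at one site in one sample is estimated as
`p̂ = n_I / n` from `n_I` edited and `n_A = n − n_I` unedited reads.
Modelling `n_I ~ Binomial(n, p)` gives the variance of the estimate

    Var(p̂) = p(1−p)/n = n_I n_A / n³,

which differs across samples because read depth differs. The two-group
comparison therefore uses weighted least squares of `p̂` on a dichotomous
0/1 group indicator with inverse-variance weights `w = n³/(n_I n_A)` — the
weighted generalisation of the unpaired two-tailed Student t-test. For a
0/1 predictor the WLS solution is closed form: the slope equals the
difference of the weighted group means, `SE² = s²(1/W₀ + 1/W₁)` with
`W_g = Σ_g w` and `s² = Σ w r² / (N−2)`, and the two-tailed p-value comes
from the t distribution with N−2 degrees of freedom. The implementation is
this closed form (vectorised across sites); the test suite checks it
against a generic WLS fit (statsmodels) to 1e−10 and against the classical
pooled-variance t-test in the equal-weight case.

Multiple testing is corrected per comparison with Benjamini–Hochberg;
sites at q ≤ 0.05 are reported with a direction: hyper (higher weighted
mean in the second group, positive slope) or hypo (negative slope).

### Edge rules

* **Zero counts.** At `n_I = 0` or `n_A = 0` the nominal weight is
  infinite. A Haldane-style continuity correction replaces the weight
  denominator by `(n_I + 0.5)(n_A + 0.5)` *for that sample only*; all other
  weights remain exact. The per-site count of corrected samples is reported
  in the results table (`n_zero_corrected`).
* **Zero residual variance.** If `s² = 0` the t statistic is undefined:
  p = 1 when the group means agree; otherwise p is set to the smallest
  positive float and the row is flagged `degenerate` so downstream FDR
  mechanics still work without silently dropping the site.
* **Equidistant LOOCV score.** A held-out efficiency exactly halfway
  between the group means scores 0 (a 1e−9 relative tolerance absorbs
  floating-point ties such as 6/15 vs 0.4).

## Read-level filters (quantification)

Reads overlapping a catalog site are filtered in order: duplicate removal,
mapping quality ≥ 10, a 2-bp end-exclusion window, base quality ≥ 20 at
the site. All thresholds are parameters; these defaults are deliberately
stringent. Choices the filter definitions leave open:

* "Highest base quality" among duplicates is read as highest **mean** base
  quality over the read, ties broken by file order (deterministic).
* The duplicate key is (mapping position, orientation, read sequence,
  **mate mapping position**): an aligned record does not carry its mate's
  sequence, and the mate position is an equivalent, locally available proxy
  for PCR-duplicate detection. Alignment-file duplicate *flags* are
  ignored; detection is purely sequence/position based.
* The end rule drops a read when the site falls on the first two or last
  two positions of the *aligned* portion of the read.
* Reads whose alignment has a deletion or reference skip across the site
  observe no base there and contribute nothing to `n`.
* Catalog coordinates are 1-based inclusive; conversion to 0-based
  half-open happens once, at the alignment-file boundary.
* Paired mates that both survive at one site are counted as two records;
  their incidence is not collapsed (not addressed by the filter
  definitions; logged choice).

## Site selection

Three pure per-site predicates (so the kept set is order-invariant):
coverage ≥ 10 in every sample; the mean-efficiency band (removed only when
**both** group means are < 0.05 or both > 0.95 — the conjunctive reading;
an either-group switch exists); and the SNP heuristic. All efficiency
intervals are closed at both ends. The group mean used throughout — band
filter, LOOCV group means, clustering selection — is the pooled
(coverage-weighted) ratio `Σn_I / Σn`; a simple-mean switch exists.

The SNP heuristic flags a site when more than 40% of samples fall in the
three genotype bands [0, 0.1] ∪ [0.4, 0.6] ∪ [0.9, 1] combined and at
least two bands individually exceed 5% — the tri-modal pattern of AA/AG/GG
genotypes. On synthetic data it achieves ≥ 95% sensitivity on genotype
mixtures (40 samples, coverage 50, every genotype ≥ 10%) with ≤ 5% false
flags on unimodal editing sites around 0.15–0.35.

## Expression correlation

Expression is the normalized coverage, exonic reads over total mapped
reads. Spearman's rank correlation (average ranks for ties) is computed
between per-sample efficiencies (samples with site coverage < 10 excluded)
and expression of the containing gene, or of designated target genes such
as the ADAR enzymes. The alternative hypothesis follows the sign of the
observed coefficient ("greater" for positive, "less" for negative) — note
this sign-directed convention halves p-values by construction, so the
two-sided p is also reported. A coefficient of exactly zero is reported
with the two-sided p and flagged. P-values are exact (full rank-permutation
enumeration) for n ≤ 9 and use the large-sample t approximation on rho
otherwise; the method used is recorded per result. BH adjustment runs over
all tested site–gene pairs of a run.

## LOOCV classification

Each fold drops one sample and reruns the *entire* comparison — selection
filters and the weighted test with its own BH family — on the remaining
samples, so the held-out sample leaks into nothing (an instrumentation
test perturbs the held-out counts and asserts bit-identical training
output). Significant training sites vote ±1 by which training-group
weighted mean the held-out efficiency is strictly closer to (0 below
coverage 10 or at a tie); the summed score signs the prediction and a zero
sum is "Not Determined". Accuracy counts Not Determined as incorrect;
the Fisher 2×2 table covers determined samples only (a 2×2 table cannot
hold a third outcome) — both conventions are reported.

## Clustering

Sites are selected without consulting group labels: coverage ≥ 10
everywhere, not SNP-flagged, all-sample pooled efficiency within the
closed band [0.02, 0.98]. Samples are clustered on 1 − Pearson correlation
with average linkage (scipy's deterministic UPGMA). Branch support is the
bootstrap proportion: sites resampled with replacement, the tree rebuilt,
and a branch credited when the replicate contains the same sample
bipartition (bipartitions are canonicalised so the two children of the
root count once). With several scale factors (default single scale 1.0;
the multiscale set 0.5…1.4 is available) an approximately unbiased (AU)
value is extrapolated by fitting `z(r) = v√r + c/√r` to the normal
quantiles of the per-scale proportions, AU = 1 − Φ(v − c). The AU values
are an approximation of the published multiscale-bootstrap procedure and
are labelled approximate; the plain BP at scale 1 is the primary support.
For heatmaps, each site row is centered by its all-sample mean.

## Synthetic data: what it emulates and what it does not

The generator draws per-site baseline efficiencies from Beta(α, β)
(default (2, 6): mean 0.25, long right tail, as in genome-wide catalogs);
coverage from a negative binomial with mean 50 and dispersion 0.3
(variance m + d·m², truncated at ≥ 1; dispersion 0 gives Poisson, and
`coverage_fixed` pins the depth exactly for calibration studies); edited
counts `n_I ~ Binomial(n, p)`; group effects as an absolute shift of
`effect_size` (default 0.2) at `n_differential` sites in the second group,
clamped to [0, 1]; SNP-like sites from a Beta mixture concentrated at
0.02 / 0.5 / 0.98 with configurable genotype frequencies (default
0.25/0.5/0.25); and optional extra-binomial per-sample jitter
(`editing_noise_sd`, default 0 — no generative model for inter-individual
editing variability beyond binomial sampling is assumed, so this knob is
exposed without further claims). Expression is log-normal per gene with
log-expression optionally coupled to the latent per-sample editing level
with slope `expression_coupling` plus Gaussian noise.

All draws flow from one seed through fixed per-function substreams
(`default_rng([seed, k])`, k = 0 catalog / 1 counts / 2 expression) in a
documented field order, so outputs are bit-reproducible.

Not emulated: splicing and alignment artefacts, batch effects between
cohorts, copy-number variation, allele-specific expression, linkage
between neighbouring sites, and library-preparation duplicate structure
beyond what the SAM fixtures construct explicitly. Passing tests therefore
demonstrate statistical correctness of the pipeline under its own sampling
assumptions, not robustness to those real-data complications.

## Problem sizes and numerical choices

The test and acceptance simulations use desk-scale conditions chosen to
make the checked quantities statistically stable: 2×10⁵ draws for the
variance law; 10⁴ sites (15 vs 15 samples, mean depth 50) for type-I
calibration plus 200 replicates of 500 sites — the per-comparison site
count of a typical genome-wide run — for BH behaviour; 500 sites with 100
true effects for power; 400 sites for the SNP heuristic's operating
characteristics; 24 samples × 200 sites for LOOCV; and 24 samples × 60
sites with 1000 bootstrap replicates for clustering.

Known limitation: with *exactly constant* coverage (Poisson or fixed at
50) and ~30 samples, the estimated inverse-variance weights carry pure
noise and the far tail of the weighted t statistic becomes mildly
anti-conservative (~1.2× at the 10⁻⁴ quantile), nudging the global-null
probability of any BH discovery slightly above the nominal 0.05. Under
over-dispersed coverage — where the weights encode real information and
which motivates the weighting in the first place — calibration is clean
(per-site type-I ≈ 0.055, family-wise null discovery ≈ 0.03–0.05). The
equal-weight limit reduces exactly to the classical pooled t-test.
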