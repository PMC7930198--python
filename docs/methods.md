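# Methods

## Statistical model of the pipeline

### Probe collapsing

Each gene on a DSP panel is measured by several barcoded probes (median 10
here). Probe counts within a gene are approximately lognormal with occasional
gross outliers (failed or cross-hybridizing probes), so collapsing uses the
geometric mean after outlier removal. The outlier rule is a two-sided Grubbs
test on log2 counts at α = 0.01, applied per gene per ROI and iterated: each
round removes the single most extreme probe of any group whose Grubbs
statistic `G = max|xᵢ − x̄| / s` exceeds the critical value

    G_crit = (n−1)/√n · √(t² / (n − 2 + t²)),  t = t-quantile(α/2n, n−2),

until no group flags. Groups below three probes are never tested, so at least
two probes always survive; negative-control probes are exempt (the LOQ
consumes them raw). Grubbs suffers from masking — two comparably extreme
probes can shield each other — which is inherent to the test, not a defect of
the implementation. Per-ROI (rather than per-probe-across-ROIs) application
was chosen because a probe can fail locally (tissue chemistry) without
failing globally.

**Zero counts.** Everywhere a log or geometric mean is taken on raw counts
the counts are floored at 1 (`max(x, 1)`). This keeps logs finite, leaves all
positive counts untouched (geomean{4,16} = 8 exactly), and gives the
degenerate all-zero case a geometric mean of 1 (so an all-zero IgG pair yields
a protein LOQ of 3).

### Detection limits

The RNA LOQ per ROI is the geometric mean of the negative probes times the
squared geometric SD — identically `exp(μ + 2σ)` with μ, σ the mean and
sample SD (ddof = 1) of the log counts. The two phrasings "geomean × GSD²"
and "geometric mean plus two standard deviations" coincide only under this
log-space reading, which is therefore canonical here. The protein LOQ is
3 × the IgG geometric mean. Detection is strict (`count > LOQ`): a count
exactly at the limit is not detected. Protein SNR detection is inclusive
(`SNR ≥ 3`), because the stated rule is that antibodies *below* an SNR of 3
are not detected.

### QC attrition

ROIs are excluded for annotation flags (missing/fat, pure stroma, sequencing
failure) or for ≤ 100 genes detected; each exclusion is attributed to exactly
one reason with precedence missing/fat > stroma_only > seq_fail > low_genes,
so the ledger's counts always sum to input − retained. Genes detected in no
retained ROI are then dropped.

### Normalizations

All normalizations are per-ROI scalar multiplications and therefore preserve
within-ROI rank order. Negative normalization reports
`log2(count / GeoMean(neg))`. Q3 normalization divides each ROI by the 75th
percentile of its *detected* counts (linear-interpolation percentile — the
definition is fixed for reproducibility) and rescales by the geometric mean
of all ROIs' Q3s, so an already-homogeneous cohort passes through unchanged.
Housekeeping normalization divides by the per-ROI geometric mean of the three
housekeeping antibodies and rescales by the cohort geometric mean of those
factors.

### Signature scores and phenotype classes

A signature is scored per sample by the combined z-score: each gene is
standardized across samples (sample SD), and the score is `Σᵢ zᵢ / √k` over
the k signature genes present. Zero-variance genes are dropped; if all genes
are degenerate the score is 0. Under independence the raw score has unit
variance, but planted (or biological) co-regulation inflates its spread by up
to √k. Classification thresholds are therefore applied to
**cohort-standardized** scores (raw score divided by its cohort SD), putting
the default cutoffs ±0.5 on a stable SD scale; `combined_zscore` still
returns the raw statistic.

Each axis is binned as negative (< −0.5), low (−0.5 ≤ s < +0.5) or positive
(≥ +0.5), boundary values upward. Of the nine (AR, NE) level pairs only six
classes are printed; the unprinted cells collapse to the nearest printed
class by a fixed table: AR+ with NE-low → AR+/NE− (full positivity on both
axes is required for the amphicrine call), low/low → ARlow/NE−, and ARlow
with NE+ → AR−/NE+ (the NE axis dominates). Tumor-level calls average the
tumor's ROI scores first, then classify.

The thresholds are deliberately configurable. Fixed symmetric cutoffs on
standardized scores are well calibrated when the class mix is roughly
balanced; under a heavily skewed mix the majority class sits near the cohort
mean and small calibration errors flip calls between adjacent bins. Recovery
validation therefore uses a balanced design (below). The score→class rule is
this package's operationalization; MDS is kept for visualization only.

### Classical MDS

Torgerson scaling: double-center −½·D² (Euclidean D), eigendecompose,
coordinates are eigenvectors scaled by √eigenvalue with negative eigenvalues
clipped to zero coordinates; each coordinate's sign is fixed so its
largest-magnitude entry is positive. Configurations of intrinsic dimension
≤ 2 are reproduced exactly (to 1e−8 in the tests).

### Concordance statistics

Phenotype homogeneity is the proportion of (nonmissing) ROI pairs in a
stratum sharing the same six-way call. The three strata are disjoint:
intratumor (same tumor), intrapatient (same patient, different tumors — the
exclusion keeps the intratumor > intrapatient > interpatient comparison
meaningful), interpatient (different patients). The exact estimate enumerates
all pairs and equals the hypergeometric identity `Σ_g C(n_g,2) / C(n,2)`
within a group; the sampled estimator draws pairs uniformly with replacement
and is unbiased for the exact value.

Uncertainty uses the bias-corrected accelerated (BCa) bootstrap with B = 1000
replicates. The resampling unit is the **patient** (cluster bootstrap): ROIs
within a patient are strongly dependent, and ROI-level resampling would
understate between-patient variance. Bootstrap copies of a patient are
treated as distinct patients when pairs are formed. Bias correction
`z₀ = Φ⁻¹(#{θ* < θ̂}/B)` (clipped to keep it finite), acceleration from the
jackknife skewness `a = Σd³ / 6(Σd²)^{3/2}`, endpoints read from the
bootstrap distribution at the adjusted levels with linear-interpolation
percentiles. Degenerate inputs (a single unit, or a constant bootstrap
distribution) return a zero-width interval with a warning. Empirical
coverage of the nominal 95% interval on simulated Bernoulli-agreement
cohorts is ~94% (500 replications; checked in the test suite).

### Group comparisons

Per-gene comparisons use the two-sided Wilcoxon rank-sum test — exact for
small tie-free groups (so complete separation at 6 vs 3 gives p = 2/C(9,3) ≈
0.024, the smallest attainable value at those sizes) and tie-corrected
asymptotic otherwise; constant genes report p = 1. The log2 fold change is
the difference of group means on the log2 scale. Multiplicity is controlled
by Benjamini–Hochberg (the choice of correction was open; BH is the field
default for volcano-style screens).

### AR-V7 junction quantification

A "spliced read" is an alignment with a gap — a CIGAR `N` skip, or a deletion
of ≥ 20 bp (long deletions in spliced aligners are junction-equivalent) —
whose first and last skipped reference positions both lie inside
chrX:67686127–67694672 (1-based inclusive). Reads are deduplicated by read
id so paired mates count once; malformed records are skipped and tallied.
SRPM divides the junction-read count by total aligned reads / 10⁶; whether
the original denominator was all aligned or all spliced reads is ambiguous,
and all aligned reads was adopted (the larger, more stable denominator).

## The synthetic cohort generator

The generator emulates a rapid-autopsy DSP study: default 26 patients × 2
metastases × 3 ROIs (156 ROIs), a 2093-gene panel with Poisson(10) probes
per gene (median 10) plus 220 negative probes, and a 57-antibody protein
panel (3 housekeepers) plus 3 IgG controls. Counts follow

    count = round( depth · 2^(base + effect·activity + bio) · probe · noise )

with per-ROI depth lognormal (GSD 2.0, giving counts spanning roughly
10²–10⁵), per-probe efficiency and per-observation noise both lognormal with
GSD `probe_dispersion` (default 1.6), and 1% of probe×ROI cells multiplied by
20 to exercise the Grubbs path. Non-signature genes carry hierarchical
biological effects (patient-level log2 SD 0.5, tumor-level 0.8), which is
what produces the intratumor > intrapatient > interpatient ordering of
profile correlations; signature genes carry the planted phenotype activity
instead (AR/NE effect of `effect_size` = 2 log2 units at full activity, half
at "low" activity). Negative probes and IgG antibodies are drawn from
phenotype-independent backgrounds (geomeans 20 and 25), which is exactly what
makes them valid detection controls. CD3+ counts are negative-binomial with
mean 13.9 and strong overdispersion (tumor-rich ROIs are mostly immune-cold
with occasional hot regions).

Default class weights are skewed toward AR+/NE− (72%), as in a
castration-resistant metastatic population, chosen so that chance
(interpatient) agreement is near one half. Discordance defaults —
tumor-level 0.08, ROI-level 0.02 — were derived a priori from the
headline concordance levels of such cohorts under the independent-flip model
((1−f)² ≈ 0.96 intratumor, (1−t)²(1−f)² ≈ 0.82 intrapatient).

Signature gene memberships are synthetic placeholders (the first panel genes,
10 AR + 10 NE + 8 each for CCP / FGFR-MEK / RB1-loss); real memberships live
in external references and are supplied as GMT files in practice. CCP,
FGFR-MEK and RB1-loss carry no planted signal — they exercise the scoring
code only.

**Validation cohorts.** Parameter-recovery and concordance validation use
`balanced_assignment`: the six classes cycled over patients (tumors inherit,
with optional seeded tumor flips). A random draw of patient classes over 26
patients can leave a class nearly or entirely absent, which both invalidates
recovery statistics for that class and shifts the score geometry of the
others; a balanced design is the standard choice for recovery validation.
With effect size 2 log2 units (≥ 2× the log-scale probe dispersion) the full
pipeline recovers ≥ 90% of planted phenotypes (typically ≥ 99%).

### What the generator does not emulate

No image or segmentation noise, no UMI/read-level sequencing simulation, no
batch or slide effects, no cell-type deconvolution structure, no
spatial autocorrelation between neighboring ROIs, and no correlation between
signature genes beyond the planted class activity. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated noise
model, not performance on any particular real dataset.

## Problem sizes used in tests and the acceptance script

Unit tests run on small panels (tens of genes); the acceptance script runs
the full 2093-gene × 156-ROI pipeline twice (study-mix and balanced
cohorts), B = 1000 bootstrap replicates per stratum, and 250 000 simulated
alignment records at an SRPM target of 1600 — sizes chosen so the whole
script completes in well under a minute while keeping Monte-Carlo error a
few percent. The BCa coverage check uses 500 replications of 30-patient
Bernoulli cohorts.

## Known limitations

* Grubbs masking: two comparable outliers in one probe group can escape
  flagging; generalized ESD would be more robust but departs from the
  platform convention implemented here.
* Threshold classification under heavily skewed class mixes is sensitive to
  calibration near the cutoffs (see above); thresholds are parameters, not
  constants.
* The sampled concordance estimator samples pairs, not patients; its seed
  and draw count are recorded in the result object for reproducibility.
* BCa intervals for proportions very close to 0 or 1 degenerate to
  zero-width; the implementation warns rather than widening artificially.
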