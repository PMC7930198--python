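# dsphet

Analysis of inter- and intra-tumor phenotype heterogeneity from digital
spatial profiling (DSP) data, with a ground-truthed synthetic-cohort
generator so the whole pipeline is testable without any data download.

DSP platforms (e.g. GeoMx) count barcoded probes in user-selected regions of
interest (ROIs) on a tissue section. A study of metastatic
castration-resistant prostate cancer typically profiles a patient / tumor /
ROI hierarchy — several patients, two metastases each, three ROIs per tumor —
and asks how consistently the tumor phenotype is classified across those
levels. `dsphet` implements the full path from raw probe counts to that
answer:

1. **Probe processing** — probe-level counts are collapsed to gene counts by
   the geometric mean of each gene's probes after iterative two-sided Grubbs
   outlier removal (α = 0.01 on log2 counts).
2. **Detection limits** — per ROI, the RNA limit of quantitation is
   `LOQ = GeoMean(neg) × GSD(neg)²` over the negative-control probes
   (identically `exp(μ + 2σ)` on the log scale); the protein LOQ is
   `3 × GeoMean(IgG)` over the IgG control antibodies. A target is detected
   when its count is strictly above the ROI's LOQ.
3. **QC and normalization** — ROI attrition (flags, ≤ 100 genes detected),
   log2 negative normalization `log2(count / GeoMean(neg))`, Q3 (75th
   percentile) normalization, protein SNR (`count / GeoMean(IgG)`, detected at
   SNR ≥ 3) and housekeeping normalization.
4. **Signatures and phenotype** — gene-set scores by the combined z-score
   `Σᵢ zᵢ / √k`; six-way AR/NE classification (AR+/NE−, ARlow/NE−, AR−/NE−,
   AR−/NElow, AR+/NE+, AR−/NE+) by thresholding the AR- and NE-axis scores;
   classical (Torgerson) MDS for visualization.
5. **Heterogeneity statistics** — pair-agreement concordance within tumors,
   within patients (across tumors), and across patients: exact enumeration
   (`Σ_g C(n_g,2) / C(n,2)`), Monte-Carlo sampling, and bias-corrected
   accelerated (BCa) bootstrap confidence intervals resampling patients;
   stratified Pearson profile correlations; per-gene exact two-sided
   Wilcoxon rank-sum comparisons with Benjamini–Hochberg correction.
6. **Splice-variant quantification** — AR-V7 as the number of distinct reads
   whose alignment gap (CIGAR `N` skip or long deletion) lies inside the
   exon3→cryptic-exon-3 junction `chrX:67686127-67694672`, normalized to
   spliced reads per million (SRPM).
7. **Synthetic data** — a lognormal hierarchical count simulator
   (`count = round(depth · 2^(base + effect·activity) · probe factor ·
   noise)`) with planted phenotypes, negative probes, outlier probes, IgG and
   housekeeping antibodies, and junction-read alignments, plus a truth table
   for parameter-recovery testing.

## Worked example

Simulate a balanced validation cohort (26 patients × 2 tumors × 3 ROIs, the
six classes cycled over patients, tumor- and ROI-level discordance planted at
the default rates), run the pipeline, and measure concordance:

```python
import dsphet as dh
from dsphet.simulate import CohortConfig, balanced_assignment, simulate_dataset

cfg = CohortConfig(seed=1)
cfg.phenotype_assignment = balanced_assignment(
    cfg, discordant_tumor_fraction=cfg.discordant_tumor_fraction)
data = simulate_dataset(cfg)

genes, mask = dh.probes.process_probes(data["probes"])  # Grubbs + collapse
loq = dh.compute_rna_loq(data["probes"])
det = dh.detection_matrix(genes, loq)
print("median genes above LOQ per ROI:", det.sum(axis=0).median())

rois, kept, ledger = dh.apply_qc_filters(det, data["annotations"])
nn = dh.negative_normalize(genes.loc[kept, rois], loq)
scores = dh.score_signatures(nn, data["signature_sets"])
calls = dh.classify_phenotype(scores)
truth = data["truth"].rois.set_index("roi_id")
print("recovery:", (calls["phenotype"] == truth.loc[calls.index, "phenotype"]).mean())
calls = calls.join(truth[["patient_id", "tumor_id"]])
for stratum in ("intratumor", "intrapatient", "interpatient"):
    print(stratum, round(dh.pair_agreement_exact(calls, stratum).estimate, 3))
```

prints (seed 1):

```
median genes above LOQ per ROI: 488.5
recovery: 0.9935897435897436
intratumor 0.987
intrapatient 0.872
interpatient 0.138
```

Of ~2100 panel genes, roughly 500 rise above the negative-probe detection
limit in a typical ROI. The classifier recovers 99% of the planted phenotype
labels. ROI pairs from the same tumor agree on the six-way call 99% of the
time, pairs from different tumors of the same patient 87% (the planted
tumor-level discordance), and pairs from different patients 14% (chance
agreement under six balanced classes) — the intratumor > intrapatient >
interpatient ordering that localizes the phenotypic heterogeneity.

A command-line interface mirrors the stages:

```sh
dsphet --out-dir run simulate --seed 1
dsphet --out-dir run process run/probes.tsv run/annotations.csv
dsphet --out-dir run score run/log2_nn.tsv --gene-sets run/signatures.gmt
dsphet --out-dir run classify run/scores.tsv
dsphet --out-dir run concordance run/phenotype_roi.tsv run/annotations.csv
dsphet --out-dir run arv7 reads.sam
```

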