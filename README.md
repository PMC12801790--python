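# fragclass

Multidimensional cell-free DNA (cfDNA) fragmentomics for liquid-biopsy
cancer detection: feature extraction from shallow whole-genome sequencing
fragments, a stacked ensemble classifier, and a synthetic cohort
simulator so the whole pipeline is testable without patient data.

## Who this is for

Computational biologists working on cfDNA-based early detection who need
a transparent, reproducible implementation of the three standard
fragmentomic readouts and the ensemble scoring scheme built on top of
them — either to analyze their own aligned cfDNA fragments (BAM or
fragment BED + reference FASTA) or to study the method's behavior under
controlled synthetic conditions.

## The method

Each plasma sample is reduced to **3,432 features** (under the bundled
hg19 autosome presets) in three families:

* **CNV — 2,475 features.** Fragments are counted in 1 Mb bins (midpoint
  assignment), GC-corrected by LOESS, divided by mappability, normalized
  against a panel of normals (per-bin median of healthy profiles), and
  expressed as median-centered log2 ratios
  `r_i = log2((c_i / Σc) / PoN_i)` with autosomes as the diploid
  baseline. A heterozygous gain diluted at tumor fraction *tf* appears at
  `log2(1 + tf/2)`.
* **FSD — 39 arms × 24 bins = 936 features.** Per chromosome arm
  (acrocentric short arms 13p/14p/15p/21p/22p excluded), fragment lengths
  are histogrammed in 5 bp bins from 110 bp upward, GC-corrected across
  arms, and z-scored `(x − µ)/σ` against training-cohort statistics.
* **FRAGMA — 21 features.** 5′ end motifs of fragments in Alu repeats:
  the frequencies of the four CGN and four NCG 3-mers, their CGN/NCG
  ratio, and ten cleavage-register ratios around CGCG sites
  (NCG×4 / CGC / GCG / CGN×4, a partition summing to 1) plus CGC/NCG and
  CGN/CGC. Elevated CGN cleavage is the readout of CpG methylation.

Each feature family is fed to six learner families — GLM, extremely
randomized trees (XRT), random forest (DRF), a small feed-forward net,
gradient boosting (GBM), and XGBoost — with stratified 5-fold
cross-validation. The stacked cancer score (0–1) is the mean of the base
scores over the best block subset by out-of-fold AUC (a second-layer
logistic meta-learner is available via config). The decision cutoff is
fixed on the training cohort at 95% specificity; evaluation reports
ROC/AUC (Mann–Whitney), sensitivity/specificity/PPV/NPV/accuracy with
exact Clopper–Pearson 95% CIs, and per-stratum sensitivity.

The simulator generates toy genomes and healthy/cancer fragment cohorts
with a tumor-fraction dial controlling all three signal axes: a fragment
size-mode shift (167 → 145 bp), planted copy-number segments, and CpG
end-motif cleavage bias. See `docs/methods.md` for the model details.

## Worked example

An end-to-end demo — simulate a 60-training / 30-validation cohort at 1×
depth, extract all features, train the ensemble, score validation:

```yaml
# demo.yaml
genome: {n_chroms: 4, chrom_length: 3000000}
depth: 1.0
seed: 1
cohort: {n_train_cancer: 30, n_train_healthy: 30,
         n_val_cancer: 15, n_val_healthy: 15, tf_low: 0.05, tf_high: 0.3}
```

```sh
fragclass run --config demo.yaml --out demo_out
# validation AUC 1.000, cutoff 0.311
```

`demo_out/summary.json` then contains:

```json
{
 "validation_auc": 1.0,
 "cutoff": 0.31054404149347525,
 "training_specificity_at_cutoff": 0.9666666666666667,
 "selected_blocks": ["cnv", "fragma", "fsd"],
 "confusion": {"tp": 15, "fp": 1, "tn": 14, "fn": 0},
 "sensitivity": 1.0,
 "specificity": 0.9333333333333333
}
```

Reading: with tumor fractions drawn from U(0.05, 0.3) all 15 validation
cancers score above the training-derived cutoff (sensitivity 1.0), one
healthy sample crosses it (specificity 14/15 ≈ 0.93), and ranking is
perfect (AUC 1.0). The cutoff 0.311 is the smallest score threshold
putting ≥ 95% of training healthy samples below it.

Other subcommands: `fragclass simulate` (write a cohort to disk),
`extract` (per-sample features from BED/BAM), `pon` (panel of normals),
`train` / `predict` (fit on a cohort directory, score new BEDs),
`evaluate` (metrics from a score table).

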