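# glioclass

Survival-aware multi-omics feature screening, autoencoder integration and
deep subtype classification for paired tumour expression/methylation
cohorts — the analysis pattern used for glioma subtyping (astrocytoma /
oligoastrocytoma / oligodendroglioma in lower-grade glioma; classical /
proneural / mesenchymal in glioblastoma), built as a reusable, fully tested
pipeline that runs end to end on synthetic cohorts with planted ground
truth.

It is intended for computational biologists who want the complete chain —
differential screening, survival filtering, promoter CpG–gene pairing,
concatenated-autoencoder embedding, ANN/CNN classification and a
standardized metric report — as library functions and CLI subcommands,
with every stage testable without access to controlled patient data.

## The method

Given an expression matrix (log2(RSEM+1), genes × samples), a methylation
matrix (beta values, CpGs × samples), a clinical table and a probe
annotation:

1. **Differential screening.** Per feature and subtype *s*,

   ```
   z = (x̄_s − μ) / σ
   ```

   with x̄_s the subtype mean, μ and σ the cohort mean and population SD.
   Features with z > 1 or z < −1 in any subtype are the DEGs/DMRs.

2. **Survival screening.** A univariate Cox proportional-hazards model per
   feature, h(t) = h₀(t)·exp(b·x), fitted by Newton–Raphson on the Efron
   partial likelihood; features with Wald p < 0.05 are survival-linked.

3. **Promoter pairing.** A (CpG, gene) pair is kept when both passed both
   screens and the CpG lies in the gene's promoter (TSS1500, TSS200, first
   exon, 5′UTR) — promoter hypermethylation represses its gene, so the two
   blocks carry coupled, clinically relevant signal.

4. **Integration.** The gene block and CpG block feed a concatenated-input
   autoencoder (encoder: concat → hidden → linear bottleneck; mirrored
   decoder; MSE loss). The bottleneck activations are the latent features.

5. **Classification.** A one-hidden-layer ANN and an eight-layer 1-D CNN
   (single filter, kernel 3, dropout 0.2) over the latents, evaluated by
   stratified 10-fold cross-validation and summarized with eight metrics —
   accuracy, sensitivity, specificity, precision, F1, FPR, G-mean (K-th
   root of the product of per-class sensitivities) and MCC — each with a
   t-based 95% CI over folds.

A synthetic-data module generates cohorts with planted subtype signatures,
anti-correlated promoter CpGs, a shared prognostic program tied to an
exponential-survival Cox hazard, and annotated decoys, so the whole chain
can be validated against known ground truth. See `docs/methods.md` for the
model details and design choices.

## Worked example

```bash
glioclass simulate --outdir sim
glioclass run-all --indir sim --seed 1 --outdir run
```

which prints

```
wrote simulated cohort (500 genes x 150 samples) to sim
ann: mean accuracy 1.0000, mean MCC 1.0000
cnn: mean accuracy 0.9900, mean MCC 0.9864
manifest -> run/manifest.json
```

The simulated cohort plants 60 promoter CpG–gene pairs among 500 genes and
1500 CpGs over three 50-sample subtypes. The screening chain keeps 48
differential, survival-linked promoter pairs (the run manifest records the
counts and checksums per stage); the autoencoder compresses the 96
concatenated features into 47 latent ones; both classifiers then recover
the planted subtypes essentially perfectly in 10-fold cross-validation —
the expected outcome when the screening chain has isolated the truly
informative features. The
`metrics_report.tsv` in the output directory holds all eight metrics as
`mean [lo–hi]` cells, one row per classifier.

The same pipeline exposes ablation modes (`--mode random_pairs`,
`preprocessed_full`, `mono_expression`, `mono_methylation`) and a `compare`
subcommand that repeats runs per mode and reports pairwise Mann-Whitney
tests on the accuracy distributions.

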