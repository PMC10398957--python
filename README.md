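# astrotraj

Astrocyte reactivity trajectory analysis for single-nucleus RNA-seq.

In Alzheimer's disease, gray-matter (protoplasmic) astrocytes shift from a
homeostatic to a reactive transcriptomic state. `astrotraj` implements the
full analysis that quantifies this shift as a continuous trajectory and
screens the transcriptome along it:

1. **QC / normalization** — drop genes detected in < 30 nuclei and nuclei
   expressing ≥ 2500 genes, depth-normalize, ln(1+x) transform, and denoise
   with a PCA-kNN smoother.
2. **Clustering & annotation** — Leiden modularity clustering over a
   resolution sweep on a symmetrized kNN graph; cluster-vs-rest Wilcoxon
   rank-sum markers with Benjamini–Hochberg correction; marker-panel scoring
   that labels protoplasmic/fibrous astrocytes and flags astrocyte–neuron and
   astrocyte–oligodendrocyte doublet clusters; Sankey-ready cluster-flow
   tables.
3. **Diffusion pseudotime** — adaptive-bandwidth Gaussian kernel on the kNN
   graph; the root nucleus is the minimum of the first diffusion component,
   sign-anchored so the homeostatic-expression-high end is the trajectory
   start; pseudotime *t* ∈ [0, 1] is the distance in scaled diffusion space
   ψᵢ·λᵢ/(1−λᵢ) from the root, then refined by principal-curve-style passes.
4. **Trajectory regression screen** — the core statistic. Pseudotime is
   rank-uniformized, `tᵢ ↦ (rankᵢ − 1)/(n − 1)`, and every gene's
   normalized-log expression is regressed on it by OLS. A gene is
   dysregulated when |β| > 0.1, R² > 0.1 and the Bonferroni-corrected slope
   p < 0.05, with a composition-drift correction, inference on the
   un-smoothed values, and a split-half reproducibility gate guarding against
   trajectories fit to noise. MA-style tables (mean expression vs β) exclude
   MALAT1.
5. **Mixed model** — per-nucleus pseudotime ~ amyloid + tau + TREM2 + APOE +
   age with a random intercept per donor (REML), E3/E3 and WT as reference
   levels.
6. **Enrichment statistics** — shared 2×2 primitives (two-sided Fisher,
   Pearson chi-squared) behind mouse-model signature overlap with homolog
   mapping, transcription-factor enrichment, GWAS-list intersection and
   GMT-based over-representation; immunofluorescence count comparisons on
   pooled proportions.

Because the study's sequencing data are not bundled, the package ships a
negative-binomial cohort simulator (`astrotraj.datagen`) with the study's
structure — 15 donors varying in amyloid/tau pathology and APOE/TREM2
genotype, four nucleus populations, a latent reactivity axis whose mean is
0.118 higher in amyloid-positive donors, and 52 upregulated / 144
downregulated planted genes — plus the ground-truth channel that the
recovery tests score against.

## Worked example

```bash
python examples/03_pseudotime_screen.py
```

```
pseudotime vs latent reactivity: Spearman r = 0.902
trajectory reproducibility (split-half): 0.732
called: 47 up / 137 down (planted 52 / 144)
sensitivity: up 0.87, down 0.95; false-discovery proportion 0.011

  gene     beta     R2    Bonferroni p   status
  VIM      +0.192  0.302  9.70e-12   up
  CHI3L1   +0.153  0.261  3.29e-13   up
  NRXN1    -0.254  0.519  1.68e-25   down
  ERBB4    -0.171  0.268  4.47e-08   down
  MALAT1   +0.094  0.248  6.09e-03   ns

MALAT1 in MA table: False
```

On a simulated 2000-nucleus protoplasmic cohort the inferred pseudotime
orders nuclei by their latent reactivity (Spearman r = 0.90), the screen
recovers the planted program with a down-dominated signature (137 down vs 47
up called), reactivity markers (VIM, CHI3L1) carry positive slopes while
homeostatic genes (NRXN1, ERBB4) carry negative ones, and the
high-abundance nuclear transcript MALAT1 is excluded from MA-style tables.
The other `examples/` scripts walk the remaining stages (simulation,
clustering/annotation, the mixed model, enrichment, IF counts), one
capability each.

A thin CLI wraps the same pipeline for shell use:

```bash
astrotraj simulate --seed 1 --outdir runs/sim
astrotraj run --config run.yaml --seed 1 --outdir runs/out
```

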