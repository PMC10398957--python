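# Methods

This note records the models, conventions and design choices behind
`astrotraj`, in the order data flows through the pipeline.

## Synthetic cohorts

The generator (`astrotraj.datagen`) emulates a 15-donor frontal-cortex
snRNA-seq study of astrocytes. It is first-class, tested code: every
recovery claim in the test suite is scored against its ground-truth channel.

**Donors.** `n_samples` donors (default 15), of which `amyloid_positive`
(default 10) carry amyloid pathology and `tau_positive` (default 5, a subset
of the amyloid-positive donors, mirroring amyloid-then-tau staging) carry
tau pathology. APOE genotypes are drawn at frequencies 0.6 / 0.3 / 0.1 for
E3/E3, E3/E4, E4/E4 and TREM2 at 0.85 / 0.15 for WT / R47H; age at death is
uniform on 65–95.

**Latent reactivity.** Each protoplasmic nucleus carries
`r = clip(Beta(2,2) + u_d + 0.118·(A_d − ½), 0, 1)` where `u_d ~ N(0,
0.05)` is a donor intercept and `A_d` the donor's amyloid status. Beta(2,2)
puts smooth interior mass so a trajectory exists; the ±0.059 centering keeps
the amyloid-positive/negative difference at the planted 0.118 while
limiting clipping, which still attenuates the realized difference slightly
(≈ 0.10–0.11 in practice). `r` is defined only for protoplasmic nuclei;
fibrous astrocytes are homogeneous.

**Genes.** The desk-scale transcriptome has `n_genes` = 2000 genes:
four 8-gene marker panels (protoplasmic, fibrous, neuron,
oligodendrocyte) boosted by 3.0 nats in their population; MALAT1 as a flat,
very-high-abundance nuclear transcript; 52 genes rising with `r` at slope
+0.3 and 144 falling at −0.5 (log scale per unit reactivity); the remainder
null. Null baselines are log-normal `ln-mean ~ N(−1.5, 1)`. Planted
baselines are `N(1.0, 0.5)`: published dysregulated-gene lists are by
construction survivors of an R² threshold applied to denoised data, i.e.
moderately-to-well expressed genes, and the recovery tests are meant to
exercise the pipeline machinery rather than the detection floor. The first
planted genes carry literature labels (VIM, CHI3L1 up; NRXN1, NRG3, GPC5,
ERBB4, NFIA down) so marker-panel and root-rule configs read naturally —
the symbols are labels only.

**Counts.** Negative binomial via Gamma–Poisson with per-gene dispersion
`θ_g ~ LogNormal(ln 10, 0.5)` (BCV² ≈ 0.1, a standard UMI-scale
overdispersion) and expected depth 5000 counts/nucleus with log-normal
(σ = 0.3) per-nucleus depth factors. Depth and dispersion are conventions,
not estimates of the original data.

**Doublets.** Astrocyte–neuron and astrocyte–oligodendrocyte doublets are
sums of two hidden parent profiles (an astrocyte draw plus a neuron or
oligodendrocyte draw), binomially thinned back to singlet depth because a
droplet carries one library's depth. Parent identities are recorded in the
truth channel. Default population sizes (1430 / 837 / 432 / 406) keep the
reference proportions 7153 : 4184 : 2161 : 2031 at one-fifth scale.

**What the simulator does not model:** ambient RNA, batch/chemistry
effects, UMI collisions, gene–gene correlation beyond the single reactivity
program, branching trajectories, and cell-cycle or spatial structure.
Passing recovery tests therefore demonstrate that the pipeline's inferences
are correct when its generative assumptions hold, not that real tissue
meets those assumptions.

## QC and normalization

Genes detected in fewer than 30 nuclei are dropped; nuclei expressing 2500
or more genes are dropped (strictly fewer-than retained). The published
description of this nucleus filter is internally inconsistent (a
"fewer than" wording attached to a doublet-removal rationale); we keep
the doublet-removal direction and expose both the bound and the direction
(`keep`, `inclusive`). Counts are scaled per nucleus to a common target sum
(default: the median library size, keeping the transform scale-free) and
ln(1+x)-transformed; zeros stay exactly zero.

Denoising is a deterministic PCA-kNN smoother standing where an iterative
deep-learning cluster-and-denoise model would sit in a GPU pipeline: each
nucleus is replaced by the mean of itself and its k nearest neighbors in
top-50 PC space. Two strengths are used — k = 30 for marker detection and
the screened expression, and k = 60 for the embedding/pseudotime geometry —
because ordering nuclei tolerates (and benefits from) heavier averaging
than effect-size estimation does. `denoise: none` disables both.

## Clustering and annotation

The neighbor graph takes Euclidean distances in PC space (randomized SVD
with a fixed seed above 500 nuclei, exact below) and symmetrizes directed
kNN edges by union. Leiden modularity (RBConfiguration, seeded, 2
iterations) is run at each requested resolution; the analysis resolution is
the sweep member whose cluster count is closest to a target (default 4).

Markers are cluster-vs-rest two-sided Wilcoxon rank-sum tests on the
denoised log expression: exact enumeration of rank splits (midranks) when
the smaller group has ≤ 6 nuclei, otherwise the tie-corrected normal
approximation; BH adjustment is applied within each cluster's gene list.
The log-fold-change is the difference of mean log expression.

A cluster's panel score is the mean log-fold-change of the panel's genes
among its significant markers (q < 0.05). The cluster takes the
best-scoring panel's label, with the neuron/oligodendrocyte (doublet)
panels taking precedence when they exceed the best astrocyte panel, and
stays `unassigned` when no panel reaches a minimal score (0.25 ln-FC) — the
guard that keeps noise-level fold changes in a homogeneous dataset from
inventing identities. When no cluster matches an astrocyte panel at all,
the pipeline treats all nuclei as a single analysis population; this is the
supported path for feeding a pre-subset second cell type (the microglia
control) through the identical pipeline. The panel-score rule is an
algorithmic proxy for what is in practice annotation by differential
expression plus literature.

## Diffusion pseudotime

The kernel is Gaussian with per-node adaptive bandwidths (distance to the
⌈k/2⌉-th neighbor), symmetrized, with unit diagonal. Eigenpairs of the
symmetric conjugate `D^{-1/2} K D^{-1/2}` are computed with a deterministic
start vector; the trivial unit eigenpair is dropped and eigenvector signs
are canonicalized. A second unit eigenvalue (disconnected graph) raises an
error instructing a subset to the largest connected component, which the
pipeline applies automatically.

The root is the nucleus minimizing the first nontrivial diffusion
component, sign-fixed so that the end with the highest homeostatic-panel
expression (default panel: NRXN1, NRG3, GPC5, ERBB4) is negative; ties
break by homeostatic score, then lowest identifier. This replaces a
force-directed-layout axis with a deterministic equivalent. Root candidates
are restricted to protoplasmic-labeled nuclei. Pseudotime is the Euclidean
distance between scaled diffusion representations `ψ_i · λ_i/(1−λ_i)` of a
nucleus and the root, divided by its maximum so t ∈ [0, 1].

Pseudotime is computed on the protoplasmic + fibrous subset jointly. At the
default (strong) population separation, the fibrous cluster is
graph-disconnected from the protoplasmic manifold after denoising, so the
production run orders the protoplasmic component only; the joint-ordering
behavior (a trajectory-less population collapsing to a narrow pseudotime
band, variance ratio < 0.25) is exercised in tests at reduced separation.

**Refinement.** Two principal-curve-style passes follow: regress every gene
on the ranked ordering, project the denoised expression onto the vector of
Bonferroni-significant slopes, and re-rank nuclei along the projection
(orientation kept). Pooling hundreds of trajectory genes orders nuclei with
less noise than a diffusion distance; on default synthetic cohorts this
raises Spearman agreement with the latent reactivity from ≈ 0.85 to ≈ 0.91.
`refine_iterations: 0` disables it.

## Trajectory regression screen

Pseudotime is rank-uniformized (`(rank−1)/(n−1)`, midranks for ties;
configurable to raw ranks, which rescales β by n−1) so dense pockets of
nuclei do not dominate the regression design. Each gene's denoised,
normalized, log expression is regressed on the ranked pseudotime by OLS. A
gene is called up (down) when β > 0.1 (β < −0.1), R² > 0.1, and the
Bonferroni-corrected slope p < 0.05, with m = the number of genes actually
tested. The effect-size floor is two-sided because the reference analysis
reports both up- and downregulated genes under a "beta > 0.1" wording.

Three inference safeguards, each added after a failure mode surfaced on
synthetic data:

- **Raw-data p-values.** Neighbor-smoothed expression violates OLS
  independence; p-values computed on it are strongly anticonservative.
  Slope inference therefore runs on the un-smoothed expression (t
  distribution, n − 2 df), while β, R² and the mean come from the denoised
  values. If no raw matrix is supplied, smoothed input falls back to an
  effective sample size of n/(k+1).
- **Composition-drift correction.** Depth normalization is compositional:
  when a large program falls along the trajectory, every other gene
  acquires a spurious positive slope proportional to its sensitivity
  x/(1+x) at its mean expression (and symmetrically for rising programs).
  The drift line is fit by median (LAD) regression of the gene slopes on
  that sensitivity — the flat majority pins the line — and subtracted;
  classification uses the centered slope `beta_centered`, while the raw OLS
  `beta` is reported unchanged. With near-constant sensitivities the fit is
  unidentifiable and a scalar median is subtracted instead.
- **Split-half reproducibility gate.** In data with no real trajectory the
  diffusion axis is built from the same noise being tested, and no
  per-gene correction can repair that circularity. The pipeline therefore
  splits nuclei at random into halves, infers pseudotime independently in
  each, regresses each half's raw expression on its own ordering, and
  correlates the two slope vectors. Genuine trajectories reproduce
  (|r| ≈ 0.7–0.9 on default cohorts); noise axes do not (|r| < 0.05). Below
  the threshold (default 0.2) the screen calls nothing. The gate activates
  above 200 nuclei.

MA-style tables keep genes with Bonferroni-significant slopes and drop
configured exclusions (MALAT1 by default, whose extreme nuclear abundance
dominates the expression axis).

## Mixed model

Per-nucleus pseudotime is the response in `t ~ amyloid + tau + TREM2 +
APOE + age`, with a random intercept per donor, fit by REML (statsmodels
MixedLM; this stage is deliberately off-the-shelf statistics — the module
owns the design coding and output schema). Amyloid and tau are binary 0/1;
E3/E3 and WT are the reference levels; sex is omitted because the emulated
cohort is single-sex. Raw (not rank-transformed) pseudotime is the default
response. All covariates are donor-level, so the donor-level design matrix
must have full column rank; a cohort in which genotype perfectly predicts
pathology raises a singular-design error naming the collinear columns, and
a fit whose fixed effects leave the vicinity of the donor-means
least-squares solution (a rare optimizer divergence on near-singular
designs) is rejected the same way. Recovery tests that average over random
cohorts skip such unidentifiable draws.

## Enrichment statistics

All comparisons reduce to 2×2 tables. Fisher's exact test is two-sided by
the minimum-likelihood convention (sum of margin-fixed table probabilities
no larger than the observed one); odds ratios are sample cross-product
ratios ad/bc (infinite when bc = 0), which is why published odds ratios
(e.g. 14.97, 1.930) are reproduced only approximately (14.80, 1.90) — they
were computed with different software conventions. Chi-squared is the
Pearson statistic on 1 df, continuity correction available but off by
default. Homolog mapping keeps genes whose human symbol lies in the
analysis universe and reports dropped counts by direction; the background
universe of every comparison is an explicit argument because the
appropriate background is genuinely ambiguous for cross-species contrasts.
Over-representation against a GMT collection uses one-sided Fisher tests
with BH across sets — a generic substitute for interactive GO services, with
no term-redundancy clustering. Immunofluorescence comparisons pool counts
over donors and images per group and Fisher-test the pooled proportions; a
per-donor stratified model is deliberately out of scope.

## Problem sizes and determinism

Recovery checks run at desk scale, chosen to keep the full suite fast while
leaving clear statistical margins: screens at 3000 protoplasmic nuclei ×
2000 genes (populations in reference proportions), pseudotime recovery at
2000 nuclei over five fixed seeds, null calibration at 20 cohorts of 1500
nuclei × 1000 genes, and mixed-model recovery over 20–50 simulated
15-donor cohorts. Every stochastic step (simulation, PCA, Leiden, split
halves) is seeded; eigensolvers use deterministic start vectors, so a given
config + seed reproduces outputs byte-identically, and each run's manifest
records the config hash, seed and package version.

## Known limitations

- The annotation rule is a proxy; real analyses also lean on literature.
- The reproducibility gate binarizes the screen near its threshold.
- The composition correction assumes a single dominant drift line.
- Doublet simulation ignores ambient RNA and chemistry effects, so doublet
  detection here is easier than in real droplet data.
- The LMM treats pseudotime as measured without error.
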