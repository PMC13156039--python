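# Methods

## Scope and model overview

`drgcomm` analyzes a time-course single-cell RNA-seq experiment of the
dorsal root ganglion after an inflammatory trigger. The pipeline takes a
sparse gene×cell count matrix with per-cell metadata (cell type,
compartment ∈ {neuronal, non_neuronal, immune}, timepoint in days,
condition), a ligand–receptor reference with associated target-gene
programs, and gene-module definitions. It emits per-cell QC and label
assignments, per-cell-type differential expression versus the t₀ control,
a scored sender→receiver ligand–receptor interactome, [0, 1]-scaled module
scores with permutation tests, and cell-composition fold changes.

## Normalization

"Normalized counts" means library-size scaling to 10,000 counts per cell
followed by natural log1p: `ln(1 + c·10⁴/total)`. All thresholds phrased on
normalized expression (the *Rbfox3* < 0.5 and *Apoe* > 2 neuron-purification
rules) are interpreted on this layer. Cells with zero total counts get an
all-zero normalized row and a warning. The layer is invariant to per-cell
scalar rescaling of counts and monotone within a cell.

## QC and label transfer

A gene is "detected" when its count is > 0. Primary QC keeps cells with
mitochondrial fraction ≤ 0.20 (strictly more than 20% is discarded) and
more than 2,000 detected genes; secondary QC relaxes the gene cutoff to at
least 1,000. The neuron-purification rule removes a cell when *either*
marker criterion holds (normalized Rbfox3 < 0.5 OR Apoe > 2); the
conjunctive reading is available via `PipelineParams.neuron_filter_mode`
because the published phrasing is ambiguous.

Label transfer uses `PrototypeClassifier`, a scikit-learn estimator:
per-label centroids over the 500 most variable genes in normalized space,
scored by the Gaussian posterior under an isotropic within-class model —
softmax over −d²/(2σ̂²), with σ̂² the pooled within-class per-feature
variance of the reference. This calibration is the design choice that
makes the 0.55 score threshold meaningful across datasets: a query on the
centroid of a well-separated reference scores near 1, a query exactly
between two centroids scores 0.5, and duplicated cells across labels stay
at 0.5 for any scale. A plain softmax over raw Euclidean distances is not
calibratable across gene counts and label counts (it left most perfectly
separable cells below threshold in our tests). Cells scoring below 0.55
are labeled `unassigned`.

## Differential expression

Two-sided Wilcoxon rank-sum on normalized expression with midranks for
ties. For n+m ≤ 12 the rank-sum null distribution is enumerated exactly
over all C(n+m, n) assignments and p = min(1, 2·min(P(W≤w), P(W≥w)));
otherwise a normal approximation with tie-corrected variance and a 0.5
continuity correction is used. Fold change is the ratio of group means on
the expm1-of-normalized scale with a 10⁻⁹ pseudocount (the published
analysis never defines its fold change; this mirrors the convention of its
toolchain). Adjustment is Benjamini–Hochberg by default; Bonferroni is
available (`p_adjust_method`) since the source analysis does not state
which its "adjusted P" is. Selection regimes: pseudobulk DE at adjusted
P < 10⁻²⁰ (strict); ligand candidates at fold > 3, detection > 10%, raw
P < 0.05 (all strict inequalities; the raw p is used because the candidate
criteria are stated separately from the adjusted pseudobulk cutoff).

## Ligand–receptor activity score

Candidate pairs: the ligand must be upregulated (candidate criteria above)
in the sender type and the receptor detected in more than 10% of receiver
cells at the scored timepoint — the 10% reuses the only published
expression threshold; self-pairs are allowed. The candidate pool is the
global union of upregulated genes across cell types (per-type pooling is a
config option).

Background: all genes outside the candidate pool, ranked by mean
normalized expression in the receiver cells at the scored timepoint
(global ranking is a config option), split into 20 equal-rank intervals
(quantile bins, not equal-width expression bins), 100 genes drawn
uniformly without replacement per interval. If the smallest interval holds
fewer than 100 genes the per-interval draw is clamped (with a warning),
never below 1 — at desk scale (2,000-gene universes) this clamp is always
active, because 20×100 background genes cannot fit; the partition and
sampling logic is unchanged.

Raw score: mean over receiver cells of [mean normalized expression of the
pair's associated target genes − mean over the background matrix]; by
linearity this equals the difference of the gene-set means of per-gene
average expression, which is how it is computed. "Comparing the average
expression to the randomized background" is deliberately made precise as
this difference of means. Each replicate's raw score is clipped at 0
(negative = nonactivity) and the activity is the mean of 5 independent
background replicates, which reduces background-sampling variance by ~5×.

Calibration note: under a null simulation (no planted programs) about half
— not all — of scored pairs are exactly 0. The replicates of a pair share
its target set, so clipping zeroes a pair only when the target-set mean
falls below the stratified-background mean, and for random target sets
that is close to a fair coin (measured 52% on the log-normalized scale,
65% on the linear scale). The clipping guarantees non-negativity and
removes the negative half of the null, but it does not by itself force the
bulk of null activities to zero; planted programs are nevertheless
separated perfectly from decoys at desk scale (AUROC 1 at the default
seed, ≥ 0.95 over 20 seeds).

## Module scores and permutation test

Per-cell raw module score = mean normalized expression of the module genes
− mean of one binned-control background draw (same stratified machinery as
the activity score, for internal consistency; bin count shared). Scaled
score = (raw − min)/(max − min) across all scored cells, per module; if
all raw scores are equal the scaled scores collapse to 0 ("nonactivity";
configurable to another constant). Scaling is exactly invariant to affine
transforms of the raw scores. Modules are first intersected with the DE
gene set and dropped below ten surviving genes.

Group comparisons use a permutation test on |difference of group means|
with uniform label shuffles and the add-one estimator
p = (1 + #{permuted ≥ observed})/(B + 1), which is valid and never zero;
B = 1,000 by default. The test is two-sided via the absolute statistic.

## Composition

Fractions are computed within a compartment (immune by default; "all"
supported), matching how immune percentages are reported. Fold change is
the ratio of fractions at two timepoints with a 95% CI from the normal
approximation on the log ratio of independent binomial proportions. No
compositional transform (CLR etc.) is applied — raw fraction ratios are
the reported quantity.

## Synthetic data generator

The generator emulates the modeled experiment's structure: 15 cell types
across the three compartments, timepoints (0, 0.25, 0.5, 1, 2, 12, 33, 63
days), counts drawn gene-wise from a negative binomial whose mean is a
gene-specific log-normal prior times a per-cell library factor, with
planted effects acting multiplicatively on the NB mean (matching the
fold-change selection rule downstream):

| parameter | default | rationale |
| --- | --- | --- |
| gene-mean prior | LogNormal(−0.5, 1.5) | realistic scRNA-seq skew: most genes near zero, few dominant |
| NB dispersion θ | 2 | overdispersion typical of droplet counts |
| library factor | log-uniform [0.5, 2] | per-cell depth spread |
| cells/type/timepoint | 40 | desk scale (overridable) |
| genes | 2,000 | desk scale |
| monocyte fraction | 0.035 → 0.65 at 6–12 h | the reported ~20-fold influx |
| planted target fold | 5 at 12 h | clearly above the fold > 3 selection rule |
| ISG-like module | 15 genes, fold 4, 6 h–1 d | transient induction in 5 cell types |
| mito genes / damaged cells | 5% / 5%, ×30 mito boost | QC testability |
| markers/type | 10 genes, fold 20 | disjoint identity programs for label transfer |

All free parameters were fixed a priori; effects are multinomial/NB draws,
so binomial sampling error is part of the stated world. Each cell type
carries a disjoint marker program; receptors of planted pairs get a floor
on their NB mean in the receiver type so that candidate-pair construction
is exercised. A single master seed drives everything through per-stage
child streams (hash of stage name), so adding a stage never perturbs
another stage's draws, and identical seeds give byte-identical outputs.

What the generator does **not** emulate: doublets, batch/well effects,
UMI-level noise, per-timepoint replicate structure (each timepoint is one
pooled sample), gene–gene correlation beyond the planted programs, and
realistic transcriptome size (2,000 genes vs ~20,000). A green recovery
test therefore establishes that the statistics recover multiplicative
planted structure at desk scale under NB noise — not robustness to batch
effects or to correlated background programs. QC gene-count cutoffs
(2,000/1,000 detected genes) are from the full-transcriptome world and are
exercised on constructed fixtures, not on the 2,000-gene simulations.

## Reproducibility and numerical choices

All tabular outputs are written with fixed column order and 9-significant-
digit floats; the run manifest records a config snapshot and SHA-256
digests of every output. Ties in activity tables break lexicographically
by (sender, receiver, ligand, receptor). Degenerate cases: zero-variance
rank-sum → p = 1; empty module after universe intersection → error; zero
reference fraction → fold change undefined (error); empty compartment at a
timepoint → error naming the timepoint.

## Known limitations

* The activity score has no null distribution or p-value (by design — the
  published analysis ranks clipped scores); use the permutation machinery
  on module-style activity vectors when inference is needed.
* The prototype classifier is a stand-in with the same contract as a
  mixture-discriminant label-transfer model (label, calibrated score,
  threshold), not a reimplementation of one; cells whose state shifts
  strongly (e.g. module-induced) lose score even when identity is intact.
* Pseudoreplication is not modeled: DE treats cells as independent.
* Background-interval clamping at small gene universes makes background
  draws nearly deterministic, so replicate averaging matters mainly at
  realistic transcriptome sizes.
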