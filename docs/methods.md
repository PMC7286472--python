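# Methods

This note documents the models, defaults and numerical choices behind
`lncwgcna`, and what the synthetic benchmarks do and do not establish.

## The analysis model

The pipeline targets a small ordinal-trait microarray design: samples from
four sequential lesion stages (normal duct, adenoma, noninvasive carcinoma,
invasive lesion), a few thousand lncRNA expression profiles recovered by
probe reannotation, and the question *which coexpression module — and which
genes within it — track progression?*

**Trait coding.** Stages are coded 1, 2, 3, 4 in progression order and
z-scored. The coding direction is a convention: reversing it flips the sign
of every correlation but changes no absolute statistic, module choice, hub
set or ANOVA result (asserted by a test).

**Network.** Unsigned adjacency `a_ij = |cor(x_i, x_j)|^β` (Pearson).
Unsigned, because positively and negatively stage-correlated genes are
expected to share modules in this design. The soft-threshold β is chosen as
the smallest value whose signed scale-free fit index reaches 0.80 on the
grid 1…20; if none does, the best-fitting β is used with a warning. The fit
index regresses log10 bin frequency on log10 mean connectivity over 10
equal-width connectivity bins and is sign-flipped so a decaying degree
distribution scores positively.

**Topological overlap.** `TOM_ij = (l_ij + a_ij) / (min(k_i,k_j) + 1 −
a_ij)` with `l_ij = Σ_{u≠i,j} a_iu a_uj`, `TOM_ii = 1`; denominators below
1e−10 yield 0. The implementation is vectorized
(`l = A₀² ` with zeroed diagonal) and is property-tested against a
triple-loop oracle at 1e−12.

**Module detection.** Average-linkage (UPGMA) clustering of `1 − TOM`, cut
statically at `cut_quantile × max(max merge height, 1)` (default 0.99);
clusters of ≥ 30 genes become modules, everything else is grey. The floor
at 1 — the ceiling of the TOM-dissimilarity scale — exists because the cut
is meant to separate genuine clusters from the near-1 "grey sea"; without
it, a dataset that is one tight cluster (all merges far below 1) would be
shattered by a cut placed just under its root. A static cut was chosen over
dynamic tree cutting for determinism and testability; it is configurable.

**Power selection caveat.** The R² ≥ 0.80 criterion is calibrated for
genome-scale arrays. On the ~300-gene synthetic design it crosses only at
β ≈ 14–15, where the static cut then discards weakly attached module genes.
The recovery benchmarks and the acceptance script therefore pin the
published power of 9; the automatic rule remains the default and is tested
on its own contract.

**Module–trait statistics.** Gene significance GS = |cor(gene, trait)|;
module significance MS = mean GS over members; module eigengene = first
right singular vector of the gene-standardized module submatrix, unit
variance, sign-aligned to the module mean profile. The stage-relevant
module maximizes MS; the eigengene–trait criterion is computed as a
cross-check and a disagreement warns. Ties break toward the larger module
(lower label) for determinism.

**cor.Weighted.** The screening output mirrors a network-weighted gene
screening: `cor.Weighted` is the trait correlation of the blend
`(1 − w)·z(gene) + w·z(module eigengene)` with w = 0.5 by default; w = 0
reproduces the plain correlation, and grey genes are never blended. This
definition is this package's own (the source analysis chain never prints
one); note that blending *raises* the trait correlation of ordinary module
members (whose own |r| is below the blend's) but can *lower* it for genes
whose trait coupling exceeds their module's — so it denoises rank-and-file
members rather than uniformly inflating hubs.

**Hubs.** Members of the selected module with |cor.Standard| > 0.8 AND
|cor.Weighted| > 0.8, both strict, sorted by |cor.Weighted|. kME (module
membership against every eigengene) is computed and exported but not part
of the default rule.

**ANOVA.** One-way fixed effects per gene across the stage groups,
(k−1, N−k) df. Zero between-group variance reports F = 0, p = 1; zero
within-group variance with distinct means reports F = ∞ with p floored at
2.2e−16 (all p-values are floored there).

**Sample QC.** Intersample adjacency `(1 + cor)/2` with zero diagonal;
K = row sum; C = `Σ_{j≠k} A_ij A_jk A_ki / (K_i² − Σ_j A_ij²)`; Z.K and Z.C
standardized with mean/sd (ddof = 1); outlier iff Z.K < −2 or Z.C > 2.
Note that with ~22 samples the extreme order statistic of 22 standardized
values crosses ±2 in most draws, so on this design the rule flags ≈ 1
sample in roughly 80 % of clean datasets — an inherent property of
thresholding standardized scores in small cohorts, not a defect; both cuts
are configurable.

**Enrichment and survival.** Upper-tail hypergeometric p per gene set
(sets intersected with the universe first), Benjamini–Hochberg adjustment
across all tested sets, significance at FDR < 0.05. Survival: median split
(ties to "low"), Kaplan–Meier product-limit curves (via lifelines), and a
hand-rolled two-group log-rank test exposing per-group expected events,
verified against lifelines to full precision. The chi-square reference for
the log-rank statistic is asymptotic; its null p-values are detectably
non-uniform below ~50 events per arm.

## The synthetic world

`SimulationConfig` defaults encode the emulated training design: stage
sizes 7/6/6/3 (22 samples), three modules of 60/50/40 genes with
within-module correlation ρ = 0.7, one stage-linked module (β = −0.75),
150 background noise genes, Gaussian noise (the conventional surrogate for
log2 RMA intensities), values centered at a log2-intensity-like baseline
of 8. Genes follow `x_i = √ρ·f_m + √(1−ρ)·ε_i` with
`f_m = β_m·z(stage) + √(1−β_m²)·η_m`, so ρ and β are the population
within-module and factor–trait correlations (verified by Monte-Carlo and
large-n tests).

**Hub genes** (3 by default) are planted in the stage module with
*sample-exact* trait correlation ±0.9: their non-trait component mixes the
module factor noise and private noise equally (`hub_module_mix = 0.5`) and
is orthogonalized against the realized stage score. Exact-by-construction,
because the dual > 0.8 screening rule is only meaningful for genes whose
realized correlation clears it — a population-level 0.85 loading at n = 22
lands on the threshold as a coin flip — and 0.9 matches the magnitude such
screens report for their hits. The factor-noise share makes hubs genuine
module members; without it ~10 % fail to cluster into their module.

**Probe universe.** Per gene, one probe set of 11 × 25-mers (the GPL570
convention; configurable). Clean lncRNA sets carry 8 exact unique windows
of their transcript plus 3 random probes. Decoys: protein-coding transcripts
with perfect matches (biotype filter), sets whose probes all carry one
central mismatch (exact-match filter), gene pairs sharing a verbatim region
so every probe maps twice (specificity filter), and sets with only 3
matching probes (≥ 4 rule). Default universe: 202+ transcripts, 66 probe
sets. Probe-level expression adds a per-probe affinity offset (sd 0.5) and
measurement noise (sd 0.25) to the gene profile. Random 25-mers collide
with a ~4²⁵ keyspace, so accidental cross-matches are vanishingly unlikely
rather than impossible.

**Survival.** Exponential event times, base hazard 0.1 scaled by the
hazard ratio in the "high" arm; independent exponential censoring with the
rate set so the requested fraction is censored at HR = 1. Pipeline default:
90 per arm, HR = 2, 30 % censoring — a plausible TCGA-cohort-sized
prognostic contrast.

**What green tests establish.** Recovery of planted structure under
Gaussian factor data with exact probe matches. Real arrays add
heavy-tailed noise, probe-affinity biases, cross-hybridization, batch
effects and annotation drift, none of which are simulated; RMA background
correction and summarization, spliced alignment, and microRNA-target
inference are out of scope.

## Determinism

Every generator takes a seed; the pipeline fans one seed out to per-stage
seeds via `numpy.random.SeedSequence`. Two runs at the same seed are
byte-identical across all outputs (asserted by a test). Reports contain no
timestamps for that reason.
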