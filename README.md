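# lncwgcna

Weighted coexpression-network analysis of long noncoding RNAs (lncRNAs)
along an ordinal tumor-stage trait, as used to study the stepwise
tumorigenesis of intraductal papillary mucinous neoplasms (IPMN) of the
pancreas: four ordered lesion stages (normal main duct → adenoma →
noninvasive carcinoma → invasive lesion) profiled on legacy expression
arrays, with lncRNA expression recovered by probe reannotation.

The package is a tested, reusable reimplementation of that analysis chain
for bioinformaticians who want to run it on their own matrices — or audit
it, since every stage can be exercised on synthetic data with planted
ground truth.

## What it computes

1. **Probe reannotation** — 25-mer array probes are matched exactly (both
   strands) against a transcript FASTA with biotype metadata. A gene is
   accepted as a measurable lncRNA iff ≥ 4 distinct probes match it
   perfectly and specifically and its biotype is on the lncRNA whitelist
   (lincRNA, antisense, processed_transcript, …). Expression of an accepted
   gene is the mean of its supporting probes.
2. **Sample QC** — intersample adjacency `A_ij = (1 + cor(i, j)) / 2`;
   samples are flagged when standardized connectivity Z.K < −2 or
   standardized clustering coefficient Z.C > 2. Quantile normalization and
   log2 transform are provided for pre-summarized inputs.
3. **Network + modules** — unsigned weighted adjacency
   `a_ij = |cor(x_i, x_j)|^β` with β chosen by the scale-free topology fit
   (signed R² ≥ 0.80 over β = 1…20), transformed to the topological overlap
   matrix

   `TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)`,

   then average-linkage clustering of `1 − TOM` with a static cut and a
   minimum module size of 30.
4. **Module–trait and hub statistics** — module eigengenes (first PC),
   module significance MS = mean |gene–trait correlation|, eigengene–trait
   correlation, and the dual hub rule |cor.Standard| > 0.8 AND
   |cor.Weighted| > 0.8, plus a per-gene one-way ANOVA across the four
   stages.
5. **Downstream statistics** — hypergeometric gene-set over-representation
   with Benjamini–Hochberg FDR (< 0.05), and Kaplan–Meier / log-rank
   comparison of median-dichotomized expression groups.
6. **Synthetic data** — a Gaussian factor model
   (`x_i = √ρ·f_m + √(1−ρ)·ε_i`, `f_m = β_m·z(stage) + √(1−β_m²)·η_m`)
   planting modules, stage effects and hub genes; a probe/transcript
   universe with mismatch, multi-mapping, sparse and wrong-biotype decoys;
   and two-group exponential survival tables. See `docs/methods.md`.

## Worked example

```sh
printf 'seed: 1\npower: 9\n' > config.yaml
lncwgcna full-pipeline --config config.yaml --outdir demo
```

The command simulates the default world (22 samples staged 7/6/6/3, three
planted modules of 60/50/40 genes at ρ = 0.7, one module carrying a stage
effect β = −0.75 with three planted hubs, 150 background genes, and a
3 619-probe universe with decoys), then runs the whole chain and prints the
truth comparison:

```json
{
  "hub_sensitivity": 1.0,
  "hub_specificity": 1.0,
  "module_ari": 1.0,
  "reannotation_precision": 1.0,
  "reannotation_recall": 1.0,
  "selected_module_matches_planted": true
}
```

`demo/report.json` holds the run summary. For this seed: 303 lncRNAs
retained (all planted genes, no decoys), 3 modules of sizes 65/51/40, the
stage module selected with MS = 0.580 and eigengene–trait correlation
r = −0.70 (p = 4.5e−4), and all three planted hubs recovered
(e.g. `LNCHUB02`: cor.Standard = −0.906, cor.Weighted = −0.849). The
negative signs mean expression falls as lesions progress, matching the
planted β = −0.75. Every intermediate table (`modules.tsv`,
`screening_stats.tsv`, `hubs.tsv`, `stage_anova.tsv`, `enrichment.tsv`,
`km_curves.tsv`, …) is written to `demo/`.

Each stage is also available as its own subcommand (`simulate`,
`reannotate`, `qc`, `network`, `hubs`, `anova`, `enrich`, `survival`) for
user-supplied TSV/FASTA/GMT inputs, and as plain library functions.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full synthetic pipeline from scratch at the given seed — the
generators, reannotation, QC, network construction at the published power
of 9, module and hub screening, and the downstream statistics — and writes
the results JSON to `--out`.
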