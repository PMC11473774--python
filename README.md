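# irislib

Cell-type-specific ligand–receptor interaction inference and
immunotherapy-response scoring from deconvolved bulk, single-cell and spatial
transcriptomics.

The package covers an end-to-end workflow on tumor cohorts treated with
immune checkpoint blockade (ICB):

1. **Activation calling** (`irislib.activation`) — binarize each
   database interaction per sample: active iff both the ligand-side and the
   receptor-side deconvolved expression (in the stated cell types, complexes
   averaged over subunits) are strictly above their medians across the
   cohort's timepoint group.
2. **Two-step training** (`irislib.iris`) —
   *Step 1*: Fisher exact screening of interactions differentially activated
   between pre-treatment samples and post-treatment non-responders
   (Benjamini–Hochberg FDR < 0.2 within each cell-type pair), classifying
   candidates as resistance-downregulated (RDI) or -upregulated (RUI).
   *Step 2*: 500 iterations of stratified 3-fold greedy forward selection;
   each iteration's selected set earns +1 / 0 / −1 by held-out AUC
   (≥ 0.6 / in between / < 0.4); per-feature reward sums are compared with a
   1000-permutation null (independent shuffling of each iteration's score
   vector) and features with empirical p < 0.05 and a positive score form an
   interaction set.  Rotating mutually exclusive step-1/step-2 cohorts yields
   an ensemble.
3. **Scoring and evaluation** (`irislib.scoring`) — per-sample response
   scores (mean over ensemble sets of the fraction of each set activated,
   then standardized), Youden cut-point / odds-ratio classification,
   rank-based AUC, exact one-sided paired Wilcoxon, one-sided Fisher
   enrichment, coefficient of variation of AUCs.
4. **Single-cell inference** (`irislib.social`) — mean-expression-product
   interaction scores with a 100-iteration cell-type-label permutation null,
   median-filtered activation across samples, and the 40 % down-sampling
   pseudo-sample construction (200 iterations per group).
5. **Spatial inference** (`irislib.special`) — slide segmentation into
   ~250 μm regions (overlapping sliding window over spots, or seeded K-means
   with the area-ratio region count: 144 regions for a 3000 μm puck),
   per-region permutation inference, and region-level concordance between
   activated-interaction counts and binarized CD8+ T-cell infiltration.
6. **Synthetic data** (`irislib.synthetic`) — cohorts, single-cell and
   spatial datasets with planted, exactly recoverable signal (activation
   states are planted first and expression synthesized to match the median
   rule), for testing every stage without downloads.
7. **Orchestration** (`irislib.app`) — the `iris` CLI and a
   leave-one-cohort-out evaluation harness.

## CLI

```bash
# synthetic four-cohort benchmark with 20 planted RDIs
iris simulate cohorts --seed 1 --out scratch/sim --n-cohorts 4

# binarize one cohort, train an ensemble, score and evaluate
iris binarize --cohort-dir scratch/sim/cohort_00 --db scratch/sim/database.tsv --out scratch/prof
iris train --cohorts-dir scratch/sim --db scratch/sim/database.tsv --direction rdi --seed 1 --out scratch/model.json
iris score --model scratch/model.json --cohort-dir scratch/sim/cohort_00 --db scratch/sim/database.tsv --out scratch/scores.tsv
iris evaluate --scores scratch/scores.tsv --cohort-dir scratch/sim/cohort_00 --out scratch/eval.json

# leave-one-cohort-out evaluation
iris loco --cohorts-dir scratch/sim --db scratch/sim/database.tsv --seed 1 --out scratch/loco.json

# single-cell and spatial inference on synthetic data
iris simulate sc --seed 1 --out scratch/sc
iris social --sc-dir scratch/sc --db scratch/sc/database.tsv --seed 1 --out scratch/social.tsv
iris simulate spatial --seed 1 --out scratch/sp
iris special --spatial-dir scratch/sp --db scratch/sp/database.tsv --mode kmeans --n-regions 16 --seed 1 --out scratch/special

# enrichment of a trained set against the database background
iris enrich --model scratch/model.json --db scratch/sim/database.tsv --grouping ligand_ct --out scratch/enrich.tsv
```

Exit codes: 0 success, 2 validation error, 3 precondition error.

## Data formats

All inputs and outputs are plain text:

- interaction database: TSV with columns `ligand_genes`, `receptor_genes`,
  `ligand_cell_type`, `receptor_cell_type`, `annotation`; complexes are
  `_`-joined gene symbols.
- cohort directory: `samples.tsv` (`sample_id`, `timepoint` pre|post,
  `response` R|NR|unknown) plus one genes × samples `<cell_type>.tsv` per
  cell type (NA allowed).
- activity profile: interactions × samples TSV (NA = non-measurable) with a
  JSON sidecar of sample metadata.
- single-cell / spatial directories: `expression.tsv` (cells × genes) plus
  `cells.tsv` (`cell_id`, `cell_type`[, `group`][, `x`, `y`, `spot_id`]).
- trained ensembles: JSON (sets, direction, provenance, config).
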