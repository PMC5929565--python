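# perturbnet

Individual-specific miRNA–lncRNA network perturbation analysis and
edge-biomarker discovery.

## The problem

Long non-coding RNAs act as competing endogenous RNAs that sequester miRNAs,
and the dysregulation of these miRNA–lncRNA interactions — rather than of any
single RNA — is implicated in cancer. Classical differential-expression
screens see only node-level (single-RNA) changes and miss interactions whose
endpoints keep normal expression levels while their *co-expression
relationship* breaks down. `perturbnet` is for computational biologists who
have paired miRNA and lncRNA expression matrices over a tumor / non-tumor
cohort, plus a catalog of candidate miRNA–lncRNA interactions, and want to
find the interactions (edges) that characterise the disease — per patient and
per cancer type.

## The method

Given *n* non-tumor (reference) samples, the expression profiles
m_i = (m_i1, …, m_in) and l_j = (l_j1, …, l_jn) define a **reference
network**: one Pearson correlation r_ij per cataloged edge (i, j). Appending
a single case sample s_{n+1} and recomputing the correlation over n + 1
samples gives the **perturbed network**, and

  ΔPCC_ij(s) = r_ij(n+1 samples) − r_ij(n samples)

measures how strongly sample *s* disturbs edge (i, j). Edges with a
statistically significant ΔPCC (default: a pooled-normal z-test; per-edge
asymptotic z available) form the sample's **individual-specific
miRNA-lncRNA network (ISMLN)**. Aggregating over all N tumor samples, each
edge gets a **significance score**

  score(i, j) = N₁ / N,  N₁ = #{samples whose ISMLN contains (i, j)},

and the high-scoring edges form the cancer's **basic miRNA-lncRNA network
(BMLN)**; edges with score > 0.8 (configurable) are candidate edge
biomarkers. Candidates are ranked by random-forest feature importance on
their per-sample ΔPCC values and evaluated by stratified 10-fold
cross-validated ROC/AUC. Each miRNA additionally receives an **activity
score**

  activity(i) = (Σ_j score(i, j) over its candidate pairs) × C₁ / C₂,

with C₁ / C₂ its candidate-pair vs full-catalog pair frequency. A synthetic
cohort generator with planted correlation perturbations makes every stage
testable end to end.

## Worked example

```bash
perturbnet simulate --out work/ --seed 17 --n-ref 84 --n-tumor 100 \
    --n-edges 500 --n-planted 25
perturbnet delta --mirna work/mirna.tsv --lncrna work/lncrna.tsv \
    --phenotype work/phenotype.tsv --catalog work/catalog.tsv \
    --group tumor --out work/delta_tumor.tsv
perturbnet delta --mirna work/mirna.tsv --lncrna work/lncrna.tsv \
    --phenotype work/phenotype.tsv --catalog work/catalog.tsv \
    --group non_tumor --out work/delta_control.tsv
perturbnet cutoff --delta work/delta_tumor.tsv --alpha 0.05 --out work/cutoff.json
perturbnet bmln --delta work/delta_tumor.tsv --cutoff work/cutoff.json \
    --threshold 0.1 --out work/scores.tsv --candidates work/candidates.tsv
perturbnet evaluate --delta-tumor work/delta_tumor.tsv \
    --delta-control work/delta_control.tsv --candidates work/candidates.tsv \
    --top 5 --folds 10 --out work/roc.tsv
```

which prints:

```
wrote cohort (84 control + 100 tumor samples, 500 edges, 25 planted) to work/
ΔPCC matrix: 500 edges x 100 tumor samples (50000 defined entries); wrote work/delta_tumor.tsv
ΔPCC matrix: 500 edges x 84 non_tumor samples (42000 defined entries); wrote work/delta_control.tsv
pooled-normal cutoff |ΔPCC - -0.000417787| >= 0.0117519 at alpha=0.05; wrote work/cutoff.json
34 of 500 edges have significance score > 0.1; wrote work/scores.tsv
10-fold CV on top-5 edges: AUC = 0.9634; wrote work/roc.tsv
```

Reading the output: appending one sample to an 84-sample reference moves a
null edge's correlation by about ±0.006 (1σ), so the fitted pooled-normal
cutoff calls a perturbation significant at |ΔPCC| ≥ 0.0118 (1.96σ); 34 edges
are perturbed in more than 10% of tumor samples, and 24 of the 25 planted
edges occupy the top 25 rows of `work/scores.tsv` (top score 0.36 — a single
sample perturbs an edge only subtly, so scores far below 1 are expected at
this cohort size); the five most important edges then separate tumor from
non-tumor samples with cross-validated AUC ≈ 0.96 even though no RNA in this
cohort is differentially expressed.

The same pipeline is available as a library — see `perturbnet.build_reference`,
`delta_matrix`, `fit_cutoff`, `scores_from_delta`, `select_candidates`,
`rank_by_importance`, `cv_auc`, `activity_scores`, `de_baseline`.

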