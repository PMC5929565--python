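# Methods

## Model and procedure

`perturbnet` treats each cataloged miRNA–lncRNA pair as an edge whose state
in a cohort is summarised by the Pearson correlation of the two expression
profiles over the *n* non-tumor (reference) samples. The working assumption
is the competing-endogenous-RNA picture: a regulatory interaction between a
miRNA and a lncRNA expresses itself as co-variation of their abundances
across samples, and disease perturbs the interaction — hence the
correlation — before or without perturbing either marginal expression level.

For one case sample the pipeline is:

1. **Reference network.** r_ij over the n controls, one value per catalog
   edge. Edges with a zero-variance endpoint are flagged undefined and carry
   the flag through every later stage; they are never imputed and never
   enter cutoff fitting or network membership.
2. **Perturbation.** The case sample is appended and the correlation is
   recomputed over n + 1 samples; ΔPCC = r(n+1) − r(n). The update is done
   incrementally from cached sufficient statistics (per-edge endpoint means,
   centered sums of squares, cross-deviation sums), which is algebraically
   identical to recomputation: with deviations dx, dy of the appended point
   from the reference means, S_xy ← S_xy + dx·dy·n/(n+1) and likewise for
   S_xx, S_yy. Cost is O(edges) per sample; the equality with brute-force
   recomputation is tested to 1e-10 on random instances.
3. **Significance.** Under the default `pooled_normal` rule a single normal
   N(μ̂, σ̂²) is fitted by moments to every defined entry of the tumor-group
   ΔPCC matrix and an entry is significant when |ΔPCC − μ̂| ≥ z_{1−α/2}·σ̂
   (ties significant; α = 0.05 default). The cutoff is the exact two-sided
   α-quantile of the fitted normal — the unique value whose tail mass equals
   α, which operationalises "p-value below and as close as possible to α".
   The alternative `ssn_z` rule uses the per-edge asymptotic statistic
   z = ΔPCC·(n−1)/(1−r²) against the standard normal, giving an
   edge-specific threshold vector; it is sharper for |r| near 1 but relies
   on the asymptotic null, whereas the pooled fit is empirical.
4. **ISMLN / BMLN.** A sample's individual-specific network is its set of
   significant edges. Over N tumor samples each edge's significance score is
   N₁/N (the fraction of ISMLNs containing it); edges with score strictly
   above a threshold (default 0.8) are candidate edge biomarkers. Ranking
   ties break by descending |mean tumor ΔPCC|, then catalog order, making
   every ordering deterministic.
5. **Edge biomarkers.** Candidate edges become classification features: each
   tumor and non-tumor sample contributes its ΔPCC per candidate edge
   (flagged-missing entries imputed as 0 — "no detectable perturbation" —
   with a logged count). A random forest (500 trees, impurity importance,
   fixed seed) ranks the candidates; stratified k-fold cross-validation
   (default 10) with pooled out-of-fold probabilities yields a single ROC
   curve and its trapezoidal AUC. Pooling rather than per-fold averaging is
   used because it gives one well-defined curve for any fold size.
6. **Activity scores.** Per miRNA: the sum of its candidate edges'
   significance scores times C₁/C₂ (candidate-pair count over full-catalog
   pair count). Since C₁/C₂ is constant within a miRNA it factors out of the
   sum; the score is bounded by C₁.
7. **Node baseline.** Differential expression per RNA: log2 fold change of
   group means with pseudocount 1, two-sided Wilcoxon rank-sum p,
   Benjamini–Hochberg adjustment, and a call at |lfc| > 1, adjusted
   p < 0.05 (both configurable).

### Control-sample ΔPCC columns

Control samples already sit inside the reference, so re-appending one
duplicates it and shrinks its apparent perturbation. The default therefore
computes control columns leave-one-out: sample s is removed (the n−1
remaining controls form the reference) and appended back, giving control
columns the same (n+1 vs n) structure as tumor columns. Removal also uses
closed-form downdates (S_xx ← S_xx − dx²·n/(n−1), etc.), and appending the
sample back restores the full n-sample statistics exactly, so the perturbed
correlation of a LOO column is the full-reference correlation. The naive
construction is kept as `control_mode="reappend"`.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `alpha` | 0.05 | two-sided significance level of the ΔPCC test |
| cutoff `method` | `pooled_normal` | empirical pooled fit; matches a single symmetric cutoff on the pooled ΔPCC histogram. `ssn_z` per-edge alternative |
| cutoff population | tumor ΔPCC matrix | the matrix that is subsequently thresholded; both-group pooling possible by passing a merged matrix |
| score `threshold` | 0.8 (strict >) | candidate edge biomarkers; at desk-scale cohort sizes single-sample perturbations yield scores ≈ 0.2–0.4, so synthetic studies lower it explicitly |
| `n_trees` | 500 | random-forest size; importance stabilises well before this |
| `folds` | 10 | stratified CV |
| `k` (cross-cancer) | 200 | top-K edges compared across cohorts |
| DE thresholds | lfc 1, adj-p 0.05 | volcano-style call |

## Synthetic cohorts

The generator emulates what the method consumes: pair-level correlation
structure with tumor-specific perturbation. Each edge's endpoints are latent
bivariate normals with correlation `rho_ref` in controls; a planted subset
switches to `rho_tumor` in tumor samples. Latents map to expression scale by
an affine transform (mean 10, sd 1 by default) plus a per-feature shift to
non-negativity — affine maps preserve all correlations exactly, which is why
the simple normal model is preferred over count distributions here.
`shared_mirna` mode routes several edges through one miRNA latent factor
(l = ρ·z_m + √(1−ρ²)·ε gives the target correlation per edge), exercising
the C₁/C₂ bookkeeping that only multi-edge miRNAs trigger. An optional
`mean_shift` adds node-level (marginal) tumor signal for
differential-expression tests; without it marginals are identical between
groups, isolating relational dysregulation.

Default study conditions — 84 controls, 100 tumors, 500 edges, 25 planted
with ρ 0.8 → 0 — mirror a breast-carcinoma-shaped cohort thinned to sizes
the full pipeline (including 20-seed repetition) processes in minutes; the
full 84/508 shape is the `brca-shape` preset. What the simulations do *not*
model: count noise, library-size and batch effects, shared lncRNA hubs,
correlated miRNA families, and catalog mis-specification. Passing tests
therefore show the statistics behave as designed under the model's own
assumptions, not that real cohorts satisfy those assumptions.

## Numerical choices

- Sufficient statistics and correlations in float64 with compensated
  summation in the scalar `pearson`; correlations clipped to [−1, 1] against
  round-off.
- Leave-one-out downdated sums clamped at 0; a downdated sum of exactly 0
  flags the edge undefined for that column.
- Cutoff comparisons use ≥ (ties significant).
- Undefined (zero-variance or missing-endpoint) edges: NaN value plus an
  explicit boolean mask; excluded from fitting, network membership and score
  denominators are unaffected (score counts simply cannot include them).
- All randomness (generator, forest, fold assignment) flows from explicit
  integer seeds; fixed seed ⇒ byte-identical outputs.

## Design choices where the design was open

- **Pooled vs per-edge z-test.** The significance rule behind a single
  symmetric ΔPCC cutoff is not uniquely determined; both a pooled empirical
  normal (default, matching one global cutoff pair) and the per-edge
  asymptotic `ssn_z` statistic are implemented and selectable.
- **Node-baseline evaluation protocol.** The edge pipeline ranks features by
  full-data forest importance and then cross-validates a chosen subset —
  the method's own published protocol, kept as specified. For the *node*
  baseline on cohorts without marginal signal, ranking thousands of null
  expression features on the full data and cross-validating the winners
  measures only the selection's winner's curse (picking the 5 most extreme
  of ~1000 null features inflates AUC to ≈ 0.69). `nested_de_cv_auc`
  therefore re-selects the top DE features inside each training fold, the
  standard correction for feature-selection bias, so the node AUC reflects
  the information node features actually carry (≈ 0.5 on null cohorts).
- **Cross-cancer degree table.** "Top-K lncRNAs" is read as "lncRNAs
  appearing in the top-K edges"; the degree of a lncRNA is the number of
  cohorts whose top-K edges contain it.
- **Eq-style activity summation.** The sum runs over the candidate pairs
  containing the miRNA; C₁/C₂ factors out either way.

## Known limitations

- The pooled-normal null treats all edges as exchangeable; edges with very
  high |r| have intrinsically smaller ΔPCC variance and are under-called
  relative to `ssn_z`.
- Significance scores at small cohort sizes are far below the 0.8 candidate
  threshold appropriate to consortium-scale data; users must scale the
  threshold to their cohort (the CLI exposes it).
- The LOO control construction uses an (n−1)-sample reference, so control
  and tumor ΔPCC null variances differ by O(1/n); at n ≳ 50 this is
  negligible, and the random forest is insensitive to it in practice.
- Feature importance from random forests is known to favour correlated
  feature groups; ranks among near-tied candidates should not be
  over-interpreted.
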