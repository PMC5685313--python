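# Methods

This note documents the models and procedures implemented in
`remission_rank`, the defaults and why they were chosen, what the
synthetic generator does and does not emulate, and the numerical
conventions a user re-deriving results will need.

## The statistical problem

A cohort of a few hundred extremely obese diabetic patients undergoes
gastric bypass; remission is defined as discontinuing all antidiabetic
medication within 30 days. The goal is to rank pre-surgery clinical
covariates and array SNPs by their joint, possibly nonlinear,
contribution to predicting remission. The obstacles are (i) no SNP
reaches genome-wide significance at this sample size, (ii) exhaustive
multivariate search over ~10⁵ SNPs is infeasible and would incur a
crushing multiple-testing burden, and (iii) cross-validated performance
estimates are biased upward when near-duplicate patients straddle the
train/test split. The pipeline answers each in turn: biology-guided
candidate enrichment, greedy forward selection inside nested
cross-validation, and similarity-based cohort reduction.

## Pipeline stages

### Quality control and association scan

Patients with missing-genotype rate > 10% are removed first; SNP
statistics are then computed on the survivors, and SNPs fail on
MAF < 5%, exact Hardy–Weinberg p < 1e−4, or missingness > 10% (in that
precedence; the report lists every exclusion). The Hardy–Weinberg test
is the exact conditional test: enumerate all heterozygote counts
compatible with the observed allele counts and sum the probabilities of
configurations no more probable than the observed one, without the
mid-p adjustment — the convention of the standard association toolkits.

Each surviving SNP is fit by maximum likelihood:
`logit P(remission) = β₀ + β₁·dosage + β₂·age + β₃·sex`, with rows
missing dosage or a covariate dropped per fit. β₁'s Wald p-value is the
association score; the odds ratio and 95% CI are `exp(β₁ ± 1.96 se)`.
Non-convergent or separated fits are flagged `unstable_fit` and carry
no values — never a fabricated p. The genomic inflation factor is the
median observed χ²₁ statistic divided by the null median (≈0.4549);
λ ≈ 1 on a null panel certifies calibration.

### Network expansion

The k lowest-p SNPs (default k = 200; ties broken by SNP id) seed a
gene set; intergenic SNPs annotated `"A|B"` contribute both flanking
genes. The candidate pool is every panel SNP annotated to a seed gene
or a first-degree interaction partner of one, tagged with provenance
(`seed` vs `network-expanded`). Seed genes absent from the network keep
their own SNPs. Candidates with p > 0.2 are dropped first; the
survivors are then greedily LD-pruned in ascending-p order — each
visited SNP removes every not-yet-kept SNP whose squared dosage
correlation (pairwise-complete samples, composite LD since phase is
unavailable) exceeds 0.8. Filtering before pruning guarantees a
low-p SNP is never sacrificed in favour of an ineligible one; pruning
is pairwise over the whole candidate set because the set is small
(~10³ at most).

### Redundancy reduction

Patient similarity is the Gower coefficient over the clinical vector —
continuous variables contribute `1 − |Δ|/range` (ranges computed once
on raw values over the full cohort, ignoring missing entries),
dichotomous ones the symmetric match indicator, and variables missing
in either patient carry zero weight. The remission label is excluded:
using the outcome inside a redundancy filter would leak label
structure. Tobacco use is excluded by default, mirroring the modelling
covariate set (its missingness is too high to compare patients on).
Pairs with similarity strictly above 0.925 form a graph; nodes are
removed greedily by highest current degree until the graph is edgeless,
ties broken first toward more missing values (leaving a more complete
final data set), then by sample id. Survivors are a maximal independent
set of the similarity graph, verified in the tests against exhaustive
enumeration on small graphs. The tie-break order is configurable
(`hobohm_tiebreak`): degree-first preserves the greedy character of the
classic algorithm, missingness resolves ties.

### Network training and encoding

The classifier is a feed-forward network with one hidden layer of three
logistic units and a logistic output — deliberately small, regularized
by a quadratic weight-decay penalty of 1 on **all** parameters
(including biases, the reference-implementation convention). Training
minimizes summed cross-entropy plus the penalty with L-BFGS-B and an
analytic gradient, starting from seeded uniform(−0.5, 0.5) weights,
capped at 1000 iterations: the batch quasi-Newton equivalent of
classic back-propagation, and deterministic given (data, seed). A
numba-compiled objective is used when available, with a pure-numpy
reference implementation kept alongside and asserted equal in tests.

Encoding: dichotomous → {0.05, 0.95} (soft targets ease sigmoid
saturation); continuous → log then standardized with the **training
split's** mean and s.d., applied unchanged to test rows; SNPs →
additive minor-allele counts {0, 1, 2}. Only complete cases for the
listed features are used; a continuous feature with nonpositive values
raises an error instructing the user to configure an offset rather than
silently shifting.

### Forward selection and finalization

Splits: stratified 5 outer folds; within each outer training set,
5 stratified inner folds repeated 5 times → 125 selection runs, each a
full sequential forward selection on its inner train/test split.
Per-run RNG substreams derive from (master seed, outer, repeat, inner),
so runs are reproducible and order-independent. Within a step every
remaining candidate is trained with the same seeded initialization (so
candidates differ only by the added feature); the best is accepted if
it improves the inner-test AUC (rank/Mann–Whitney form, tie-corrected)
by ≥ 0.01, exact ties resolved by a uniform draw from the run's
substream. The clinical phase runs first from an empty base (starting
AUC 0.5); the finalized clinical set is then the fixed base for the SNP
phase (starting AUC = base-model AUC). A `snp_phase_mode="single"`
switch restricts each SNP-phase run to at most one acceptance, for
users who read "evaluating individual SNP importance" strictly; the
default allows full forward selection, consistent with selection-count
reporting.

Finalization: a feature is included when selected at least once in
every outer fold (a guard against fold-specific circularity) and at
least X times over all runs — X = 45 for clinical features and 5 for
SNPs at the default 125-run geometry. Note X_snp = 5 equals the number
of outer folds: for SNPs the all-folds rule is the entire constraint.

### Evaluation

Out-of-fold scores from one model per outer fold (trained on the outer
training set with the final features) give the cross-validated AUC and
the confusion metrics at the 0.5 cutoff (score ≥ cutoff → predicted
remitter; boundary inclusive by documented convention). Model
improvement from SNPs is quantified by:

* **categorical NRI** with the classification cutoff 0.5 as the single
  category boundary (configurable list),
  `NRI = [P(up|event) − P(down|event)] + [P(down|nonevent) − P(up|nonevent)]`,
  `se = √(Σ_groups (p_up + p_down − (p_up − p_down)²)/n_group)`;
* **continuous NRI**, same form counting any score increase/decrease;
* **IDI** = difference of discrimination slopes (event mean minus
  nonevent mean of the score), `se = √(var(Δ|events)/n_e +
  var(Δ|nonevents)/n_ne)`; each reported with the asymptotic z and
  two-sided p.

The 8-group patient breakdown cross-classifies true class ×
clinical-model correctness × full-model correctness, isolating e.g. the
patients the genomic markers "rescue" from a wrong clinical prediction.
Negative controls: (i) random SNP sets of the final set's size drawn
from the candidate pool excluding the final SNPs, re-evaluated with the
clinical base — their mean AUC should match the clinical-only model;
(ii) label permutation — the full pipeline must score chance AUC.
Importance is the signed connection-weights product Σ_h w(f→h)·w(h→out)
per feature, scaled to max |·| = 1 per model and averaged over the
outer-fold models; the sign is interpretable (positive: high values /
minor alleles push toward remission).

## The synthetic generator

`synthetic_cohort` produces inputs with the statistical structure the
analysis assumes, since the real cohort is controlled-access.

* **Genotypes** — biallelic SNPs in LD blocks (default 4 SNPs/block,
  one block per synthetic gene). Haplotypes use a copy-flip
  construction: a per-block base allele at the block's frequency is
  copied by each SNP with probability √r, giving expected pairwise
  allelic correlation exactly `within_block_r` (default 0.9) within
  blocks and independence across blocks; two haplotypes per individual
  give Hardy–Weinberg dosages. MAFs are uniform on [0.05, 0.5) per
  block.
* **Network** — preferential attachment over the annotation's genes
  with m = mean_degree/2 new edges per node (default mean degree 4),
  giving the heavy-tailed degree structure of curated interactomes.
* **Covariates** — the full 16-variable baseline set: continuous
  variables are log-normal matched to the published cohort's medians
  and interquartile ranges; medication/lifestyle flags are Bernoulli at
  the published prevalences; missingness is injected per column,
  completely at random, at the published observation gaps (tobacco
  worst at 28%). MCAR is a simplification — no missingness mechanism
  is documented for the real data.
* **Labels** — Bernoulli(logistic(η)) with η = intercept + Σ clinical
  effects (per log-s.d. for continuous, per unit for flags) + Σ
  per-allele SNP effects on **centered** dosage (so planted SNPs move
  individual risk without shifting cohort prevalence). The default
  intercept 1.9 reproduces the published prevalence (317/457 ≈ 0.69).
* **Planted effects (the default study conditions)** — insulin therapy
  −2.0, HbA1c −1.0, serum insulin +0.8; one strong SNP (conditional
  per-allele log-odds 1.4 ≈ marginal OR 2.2, the scale of the
  strongest reported single-SNP association) and one **network-latent**
  SNP on a first-degree interaction partner of the strong SNP's gene.
  The latent SNP is a suppressor: it raises standardized log-HbA1c by
  0.85 per centered allele while its direct effect (+1.4) favours
  remission, so its marginal scan signal is ~0.4 log-odds (often
  outside a small seed set, occasionally strong enough to seed) while
  its covariate-adjusted signal stays at the planted value — exactly
  the class of marker the interaction-network expansion exists to
  recover, and invisible to a univariate screen at these sample sizes.
  Planted SNPs are restricted to MAF ≥ 0.2, matching the reported top
  markers (0.23–0.47). These are positive-control magnitudes: large
  enough that a correct implementation recovers them reliably; the
  generator is a correctness control, not a power analysis.

What passing the synthetic tests does **not** show about real data:
there is no population structure or relatedness (none was detected in
the study cohort, so none is simulated), missingness is MCAR, LD is
block-diagonal with a single correlation level, covariates are mutually
independent given the planted links, and the label model is exactly
logistic — real effect sizes, interactions and confounding will be
messier, and the pipeline's statistical power on real cohorts cannot be
inferred from the positive controls.

## Calibration and positive-control studies

`calibration` fixes two standing experiments (used by the tests and
`scripts/acceptance.py`):

* **Null calibration** — 2000 independent null SNPs at n = 500
  (independent so each test is a fresh draw; 2000 because a genomic-λ
  median estimated from a few hundred p-values has sampling error of
  the same order as the λ ∈ [0.9, 1.1] band being asserted). Expected:
  λ ≈ 1, ~5% of p < 0.05, permuted-label pipeline AUC ≈ 0.5.
* **Parameter recovery** — 20 replicates of the full pipeline at
  n = 1000 on a 200-SNP/50-gene panel with seed_k = 5 (proportionally
  more generous than the full-scale 200 of 86,444), a 5 × 3 × 2 nested
  schedule (30 runs) with inclusion thresholds scaled from the 125-run
  protocol (clinical ⌈45·30/125⌉ = 11; SNPs keep the once-per-outer-
  fold rule). Success means: all three planted clinical effects
  finalized, both planted SNP **loci** finalized, and at most one false
  positive. Recovery is scored at the locus level — a planted SNP or
  any same-LD-block mate counts, and planted-block mates are not
  counted as false positives — because the LD-prune step intentionally
  collapses correlated markers and a block mate of a causal SNP carries
  its signal. Residual false positives are cohort-level spurious
  associations whose in-sample AUC increment reaches the 0.01
  acceptance threshold; they are intrinsic to the protocol at this
  sample size, which is precisely why the finalization rules exist.
* **Random-SNP control** — 200 random draws replacing the final SNPs,
  on a cohort with a wider seed set (k = 20) so the candidate pool is
  large enough to draw from; mean AUC of the draws should sit within
  0.03 of the clinical-only model.

## Numerical conventions and degenerate inputs

* Chi-square tests on 2×2 tables use the continuity correction clamped
  at |O − E|, so a perfectly balanced table scores exactly 0; this
  convention reproduces the published univariate p-values to the
  printed precision. Zero margins are an error.
* Kruskal–Wallis drops missing values pairwise; an all-constant column
  returns statistic 0, p = 1 (not an error). Quartiles use linear
  interpolation; printed percentages round half-up to one decimal.
* Minor alleles are determined per SNP from observed frequency at read
  time when the file does not declare them; frequency-0.5 ties break
  lexicographically by allele symbol. Missing genotypes are NaN —
  never 0, which is a valid dosage. Coordinates are 1-based.
* Seeds: one master seed; every substream derives from it through
  `numpy.random.SeedSequence` with a purpose-specific key, so stages
  are reproducible independently and in any order. Reruns with the
  same config and seed produce byte-identical output tables.

## Known limitations

* The per-feature complete-case rule (inherited from the reference
  workflow) means candidate features with different missingness are
  compared on slightly different inner-test subsets during forward
  selection; with MCAR missingness this is unbiased but adds noise.
* Greedy forward selection with a fixed ΔAUC ≥ 0.01 rule admits
  spurious features whose in-cohort increment reaches the threshold;
  the all-outer-folds and X-count finalization rules mitigate but
  cannot eliminate this at small n.
* The Hobohm-style reduction is greedy, not an exact maximum
  independent set — by design, matching the reference algorithm.
* VCF input is restricted to biallelic records; binary PLINK files and
  imputation are out of scope.
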