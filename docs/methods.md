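# Methods

`prsnet` models the polygenic risk of a case-control trait (the motivating
application is late-onset Alzheimer's disease) from genotype dosages, and
interprets the fitted models against quantitative endophenotypes.  This
note records the models, the numerical choices behind them, and what the
synthetic studies used for validation do and do not establish.

## The modelling problem

Each individual carries dosages `d_i ∈ [0, 2]` (expected effect-allele
counts) at a panel of variants.  Disease status (AD vs NC, with MCI as an
optional intermediate class) is modelled from those dosages together with
age, sex and the top five genetic principal components.  Four score
families are provided:

1. **Weighted PRS** — `score_s = Σ_i w_i d_si`, with `w_i` the per-variant
   log-odds ratios from a GWAS or meta-analysis.  No normalization is
   applied; the score is a linear functional of dosage, so it cannot
   express epistasis.
2. **L1-logistic (lasso) score** — penalized logistic regression over the
   variant panel, covariates unpenalized (or regressed out first; see
   below), solved by penalized IRLS with cyclic coordinate descent over a
   descending grid of 100 log-spaced penalties from `λ_max` (the smallest
   penalty that zeroes every variant coefficient) down to `10⁻³ λ_max`.
   Variant columns are standardized internally; coefficients are reported
   on the dosage scale.  The working penalty is chosen as the grid value,
   among those evaluated by 5-fold cross-validation, that retains the most
   nonzero variant coefficients — i.e. the smallest grid value; the full
   CV path (penalty, mean CV squared error, support size) is recorded so
   any other rule can be applied.
3. **Layered sigmoid network** — two reference architectures.  The
   locus-structured form: dropout on the input, dense(3·L), dropout,
   dense(L), dense(22), dense(5), dense(1), where L is the number of loci,
   3·L reflects an assumed maximum of three disease haplotypes per locus,
   22 the autosome count, and 5 a small number of putative parallel
   pathways.  The compact form: dense(50), dropout, dense(30), dropout,
   dense(10), dense(5), dense(1).  All dense activations are logistic
   sigmoids; the output unit is the risk score; the dense(5) layer feeding
   it is the *module* layer used for interpretation.
4. **LD-graph convolutional classifier** — each individual is a graph
   whose nodes are the panel variants; node features are the dosage plus
   six functional-annotation counts, normalized dimension-wise; an edge
   joins two variants when their dosage r² exceeds 0.6.  Three
   symmetric-normalized graph-convolution layers (rectifier, width 128)
   feed global max pooling, one dense rectifier layer of width 64, and a
   sigmoid output.

## Association, meta-analysis and variant selection

Per-variant association uses logistic regression of status on dosage plus
covariates, fitted by Newton/IRLS with Wald two-sided p-values (the
conventional GWAS test).  The IRLS core is written in-package so that
calibration studies sweeping tens of thousands of single-variant fits run
in seconds; it is validated against `statsmodels.Logit` to ~1e-6.
Non-converged or separated fits are flagged with missing p-values rather
than dropped silently.

Fixed-effects meta-analysis uses inverse-variance weights
`w_s = 1/se_s²`, with Cochran's Q and `I² = max(0, (Q−(k−1))/Q)·100`
floored at zero; for a single study I² is defined as 0.  LD is squared
Pearson correlation of dosage columns (constant columns get r² = 0
off-diagonal).  Clumping is greedy by ascending p with a deterministic
(p, chromosome, position, id) tie-break; defaults r² > 0.1 within
1000 kb.  Threshold selection uses strict `p < threshold`.  A composed
`select_replicated` recipe retains variants significant in either of two
cohorts that are then either meta-significant or sign-concordant.

## Training the networks

The dense network minimizes mean binary cross-entropy by mini-batch SGD
under a staircase exponential-decay schedule
(`lr = lr0 · 0.96^⌊step/100000⌋`, `lr0 = 0.5`).  Presets mirror three
evaluation scenarios: fit-on-all-data (2000 epochs, batch 256),
cross-validation (1500 epochs, batch 1024), and independent-cohort
evaluation (early stopping on a held-out split, best weights restored).
Dropout (inverted; 0.2 locus-structured, 0.3 compact by default) is
active only in training passes.  Weight initialisation is seeded
symmetric-uniform with fan-based scaling.  Gradients are exact
(finite-difference-checked to 1e-5 in the tests); training is bit
reproducible given the seed.

Two numerical points matter in practice.  First, deep sigmoid stacks
frequently fail to leave their initial plateau when fed raw dosages, so
`train_nn` standardizes input features by default (the scaler is stored on
the model and applied at inference; it can be disabled).  Second, the
cross-entropy of a sigmoid stack on an interaction-driven trait sits on a
long plateau (often > 1000 epochs) before the nonlinear structure is
found, while on additive traits late training overfits.  An early-stopping
patience rule fires during that plateau, so the evaluation preset instead
trains the full 2000-epoch budget with a held-out fifth of the training
data monitored and the best-validation-epoch weights restored at the end
(`TrainConfig.restore_best`).  The same preset is used for every
synthetic evaluation scenario — it is not tuned per architecture of the
truth.

The graph model trains with adaptive-moment (Adam) optimisation
(lr 1e-3), early stop patience 20, in float32.  "Two fully connected
layers as the final classifier" is resolved as dense(64) → dense(1); max
pooling routes gradients to the argmax node per channel.

## Risk stratification

Risk scores are fitted with a univariate K = 3 Gaussian mixture by plain
EM (k-means initialisation; up to 200 iterations; relative log-likelihood
tolerance 1e-8; collapse triggers a reseeded restart, at most 5).  ECM
and plain EM have the same fixed points for a univariate mixture, so the
simpler iteration is used.  Components are sorted by mean: low, medium,
high.  Membership probabilities default to posterior responsibilities,
which sum to one exactly and therefore satisfy the identity
`p_med = 1 − p_low − p_high`; a "literal" mode instead evaluates the outer
components' mode-normalized density heights and derives the medium
probability as the complement, clipped into [0, 1] with a warning — it
exists for sensitivity analysis because the density-plug-in reading of
that identity is ambiguous.  Group-phenotype association is logistic
(AD-vs-NC, MCI-vs-NC) with the low group as reference.

## Interpretation pipeline

Endophenotype association uses M-estimation: a Huber pass for a stable
start, then Tukey bisquare with tuning constant 4.685 (95% Gaussian
efficiency) and MAD scale, through `statsmodels` RLM.  Cognitive scores
are rank-inverse-normal transformed with the Blom offset 3/8 (average
ranks for ties).  Raw p-values are reported by default; BH adjustment is
a flag.  Imaging endophenotypes can add intracranial volume as an extra
covariate.

Module-level association fits one robust model with all five module
columns as joint predictors and returns their t-statistics.  Clustering
of |t| profiles uses best-of-25 k-means per candidate k; the elbow is
operationalized as the k with the largest second difference of the WSS
curve (ties toward the smallest k) because the cited heuristic is a
visual rule and automation needs an algorithmic one.  Per-variant
attribution uses partial Spearman correlation computed from the inverse
of the joint rank-correlation matrix, p-values from the t-approximation
with `df = n − (m−1) − 2`.  Cell-type specificity calls a gene specific
to a cell type when its FPKM is ≥ 5 there and ≥ 1.5× every other type (a
single-tier simplification of the cited tool's three-tier scheme);
enrichment is the hypergeometric upper tail with BH adjustment across
cell types within a cluster.  Group comparisons are one-way ANOVA with
Bonferroni-multiplied pairwise t-tests.

## The synthetic cohort generator

Restricted-access cohorts cannot ship with the package, so every test
runs on synthetic cohorts with the statistical structure the analyses
assume:

* **Genotypes.** Two latent haplotypes per sample drawn from block-wise
  equi-correlated Gaussians and thresholded at the MAF quantile; dosage is
  their sum.  The latent correlation is calibrated numerically (bivariate
  normal orthant mass inverted by Brent's method) so the *dosage*
  correlation matches the requested within-block target; one MAF is drawn
  per block so the calibration is exact.  Across blocks r ≈ 0.  This is a
  Gaussian-copula approximation — it produces no recombination gradients,
  no allele-age structure, and no population stratification.
* **Phenotypes.** Liability `L = Σ β_i g_i + Σ γ_jk (g_j−ḡ_j)(g_k−ḡ_k)
  + β_age·age + β_sex·sex + ε`; status is Bernoulli(logistic(L − mean L)),
  then case-control subsampled to the requested fraction (default 0.5,
  held within ±2 points).  Epistatic terms use centered dosage products so
  marginal per-variant effects are exactly zero — this is what makes the
  "nonlinear model beats weighted PRS under epistasis" comparison fair.
  A tenth of retained controls are relabelled MCI to exercise the
  three-level status logic.  Age is uniform [55, 90], sex Bernoulli(1/2);
  matching real cohort demographics is a non-goal.
* **Endophenotypes.** Pathway burdens `B_k = Σ_{i∈pathway k} β_i g_i`
  (default five pathways, round-robin variant assignment) mix into
  biomarkers through a loadings matrix plus Gaussian noise.
* **Seeding.** One global seed drives genotype, phenotype, endophenotype
  and annotation streams through `SeedSequence` splitting, so each stage
  is reproducible independently of call order.

## Validation studies and their scope

The end-to-end studies (in `prsnet.benchmarks`, re-run by
`scripts/acceptance.py`) use these problem sizes, chosen to exercise each
claim at desk scale:

* oracle equivalence on 200 random fixtures (n ≤ 50) and closed-form
  meta-analysis cases;
* GWAS type-I error pooled over 200 null cohorts of n = 5000 × 100
  variants; bootstrap CI coverage over 100 null replicates (B = 1000);
  robust-fit and ANOVA null uniformity over 200 replicates;
* recovery: 3-component mixture at means (−2, 0, 2) with n = 3000; lasso
  support with 20 causal variants (|β| = 0.25) among 100 at n = 8000 over
  5 seeds; single-variant log-OR of ln 3 at n = 8000 with no residual
  liability noise (the check is estimator consistency under a correctly
  specified logistic model; residual Gaussian liability noise would
  attenuate the marginal slope by a known factor and test that constant
  instead);
* model-family ordering on n = 6000 cohorts of 50 variants: five
  zero-marginal interaction pairs (γ = 6) for the epistatic arm, fifty
  additive effects (|β| = 0.25) for the additive arm, 5 seeds each,
  70/30 train/test;
* stratification on n = 2000 additive cohorts scored with true-beta
  weighted PRS, 5 seeds;
* module interpretability on n = 4000 cohorts with five disjoint strong
  additive pathways (every variant effect 0.5, variant j in pathway
  j mod 5), 5 seeds.

Passing these studies shows the implementation is correct and calibrated
under its own generative assumptions.  It does not show that the models
transfer to real genotype data, where LD has haplotype structure, effects
are smaller and confounded with ancestry, and diagnosis is noisy.

## Known limitations

* The penultimate modules of a network trained on a near-additive trait
  are strongly inter-correlated (measured |r| 0.93-1.00): a scalar logit
  needs only a rank-one representation, so module identity is arbitrary
  and per-module attribution is barely identifiable.  Each pathway burden
  is reliably tracked by *some* module, but asking *which* module carries
  a given pathway gives chance-level answers; the corresponding
  attribution test is expected to fail and is kept as an honest record of
  this limitation.  Designs with within-pathway interaction terms were
  tried and made pathway-burden coverage worse without making attribution
  identifiable.  Treat per-module claims on real data as exploratory.
* The lasso's two covariate treatments (unpenalized vs regress-out) give
  similar but not identical scores; neither is asserted as canonical.
* The graph classifier's global max pooling is insensitive to additive
  per-node signals by construction; it is the right inductive bias for
  "any high-risk configuration" signals, not for sums.
* No support for BGEN/PGEN, phasing, imputation, liftover, or mixed-model
  association.
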