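# prsnet

Polygenic risk modelling for case-control traits with classical and
neural scores, written for desk-scale methodological work on Alzheimer's
disease genetics.  The package covers the whole workflow: reading and
harmonizing genotype dosages and GWAS summary statistics, per-variant
logistic association with fixed-effects meta-analysis and LD clumping,
four polygenic-score model families, threshold-free evaluation with
bootstrap uncertainty, Gaussian-mixture risk stratification, and
interpretation of a network's hidden "modules" against endophenotypes —
plus a synthetic-cohort generator so everything runs without
restricted-access data.

## The models

Given dosages `d_si ∈ [0, 2]` (sample *s*, variant *i*):

* **Weighted PRS** — `PRS_s = Σ_i ŵ_i d_si`, with `ŵ_i` per-variant
  log-odds ratios from a GWAS or inverse-variance fixed-effects
  meta-analysis (`β̂ = Σ w_s β_s / Σ w_s`, `w_s = 1/se_s²`, heterogeneity
  `I² = max(0, (Q−(k−1))/Q)`).
* **Lasso score** — L1-penalized logistic regression over the variant
  panel (covariates unpenalized), glmnet-style coordinate descent over a
  100-value penalty path with 5-fold cross-validation; the retained
  penalty is the grid value keeping the most variants.
* **Neural score** — a layered sigmoid network (e.g. widths
  50/30/10/5/1 with interleaved dropout) trained with mini-batch SGD
  under a staircase schedule `lr = 0.5 · 0.96^⌊step/10⁵⌋` on binary
  cross-entropy.  The dense layer of width 5 feeding the output is the
  *module* layer; its activations summarize genetic input into latent
  risk components used for interpretation.
* **LD-graph classifier** — per-sample variant graphs (edges where
  dosage r² > 0.6; node features: dosage + annotation counts) through a
  3-layer graph convolutional network with global max pooling.

Risk scores are stratified into low/medium/high groups with a
3-component Gaussian mixture fitted by EM; group membership uses the
posterior responsibilities.  Endophenotype association uses bisquare
M-estimation (c = 4.685, MAD scale) with age, sex and five principal
components as covariates; cognitive scores get a rank-based
inverse-normal transform (Blom offset 3/8).

## Worked example

```python
import numpy as np
from prsnet import SimSpec, simulate_cohort
from prsnet.assoc import logistic_assoc, compute_ld, ld_clump
from prsnet.models import WeightedPRSModel
from prsnet.metrics import evaluate
from prsnet.stratify import fit_gmm, assign_risk_groups

spec = SimSpec(
    n_samples=3000, n_variants=40, seed=7,
    ld_blocks=[(4, 0.8)] * 5 + [(1, 0.0)] * 20,
    additive_effects={0: 0.5, 8: -0.4, 20: 0.35},
    large_effect=(24, 1.1),          # an APOE-like major locus
    liability_noise_sd=0.5,
)
cohort = simulate_cohort(spec)

stats = logistic_assoc(cohort.genotypes, cohort.phenotypes)
print(stats.table.nsmallest(3, "p")[["id", "beta", "se", "p"]])

kept = ld_clump(stats, compute_ld(cohort.genotypes), r2_threshold=0.1)
print(len(kept), "variants retained after clumping")

scores = WeightedPRSModel.from_summary_stats(stats).score(cohort.genotypes)
y = cohort.phenotypes.binary_status()          # AD=1, NC=0, MCI excluded
keep = np.isfinite(y)
print(evaluate(scores[keep], y[keep].astype(int), B=1000, seed=0).summary())

gmm = fit_gmm(scores, seed=0)
groups = assign_risk_groups(gmm, scores)
is_ad = (cohort.phenotypes.status == "AD").to_numpy()
for g in ("low", "medium", "high"):
    sel = groups.labels == g
    print(g, sel.sum(), round(is_ad[sel].mean(), 3))
```

This prints:

```
      id     beta       se            p
rs000025 1.028023 0.072622 1.719636e-45
rs000001 0.500590 0.055353 1.516618e-19
rs000002 0.421411 0.055441 2.938103e-14
25 variants retained after clumping
auROC 0.6761 [0.6561, 0.6959]  auPRC 0.6871  (n_pos=1473, n_neg=1326)
low 971 0.333
medium 1510 0.533
high 465 0.742
```

The major locus simulated with β = 1.1 is recovered as the top hit
(β̂ ≈ 1.03), clumping collapses the five 4-variant LD blocks to their
index variants, the weighted PRS separates cases from controls with
auROC ≈ 0.68, and the mixture-defined risk groups show the expected
monotone rise in case fraction (33% → 53% → 74%).

Training the neural models and the interpretation pipeline follow the
same pattern; see `prsnet.models` (`build_nn`, `train_nn`,
`penultimate_outputs`, `build_graphs`, `train_gnn`) and
`prsnet.interpret`.

A thin CLI mirrors the data-level steps:

```sh
prsnet simulate --spec cohort.yaml --out cohort
prsnet assoc --geno cohort.dosage.tsv --pheno cohort.pheno.tsv --out gwas.tsv
prsnet score --geno cohort.dosage.tsv --stats gwas.tsv --out scores.tsv
prsnet evaluate --scores scores.tsv --pheno cohort.pheno.tsv
prsnet stratify --scores scores.tsv --pheno cohort.pheno.tsv --out groups.tsv
```

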