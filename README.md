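# clustsig

Model-based clustering of gene expression for survival-stratifying
signatures.

Chronic lymphocytic leukemia (CLL) and other heterogeneous cancers hide
small patient subgroups — a few percent of a cohort — whose expression of
a handful of genes is shifted and whose survival is sharply worse.
`clustsig` implements the full discovery-and-transfer pipeline for such
signatures, for computational biologists working with bulk expression
matrices and right-censored follow-up:

1. **Per-gene screen.** Each gene's expression across samples is split
   into the two most likely clusters with a univariate two-component
   Gaussian mixture (equal-variance *E* and unequal-variance *V* models
   compared by BIC), the binary cluster label is tested against overall
   survival with Cox regression, and genes are selected at a
   Benjamini–Hochberg q-value < 0.05.
2. **Multivariate signature.** A K=2 Gaussian mixture over the selected
   genes, with the covariance of component *k* parameterized
   geometrically as Σ_k = λ_k·A_k (volume λ_k > 0, diagonal shape A_k
   with det A_k = 1; families EII, VII, EEI, VEI, EVI, VVI), fitted by EM
   and chosen by BIC = 2·ℓ − m·log n (maximized).  The component whose
   members show the higher observed death hazard is the *adverse*
   cluster.
3. **Transfer.** A validation cohort measured on a different platform is
   placed into the training model's space with parametric empirical-Bayes
   batch adjustment (the ComBat location/scale model), and cluster
   membership is predicted from the *frozen* training mixture — no
   refitting — then tested against validation survival.
4. **Independence.** A multivariate Cox model checks that the cluster
   effect survives adjustment for the usual prognostic covariates (age,
   Binet stage, IGHV status, TP53/del17p, ATM/del11q, NOTCH1, SF3B1,
   BIRC3 or any user-supplied set).

All survival machinery (Cox partial likelihood with Efron/Breslow ties,
Kaplan–Meier, BH adjustment) and the constrained-mixture EM are
implemented in the package and cross-checked in the test suite against
independent oracles (exhaustive-partition enumeration, grid search,
lifelines, statsmodels, scikit-learn).

A synthetic-cohort generator with a planted minority cluster, known
hazard ratio, independent censoring and gene-wise batch effects provides
ground truth for every stage.

## Worked example

Discover a signature on a 450-sample synthetic cohort (3 signature genes
planted among 2000, minority ≈ 4.5%, true hazard ratio 5) and transfer
it to a batch-shifted 107-sample cohort:

```python
import numpy as np
import pandas as pd
from clustsig import (SyntheticConfig, generate_paired_cohorts, screen_genes,
                      fit_signature, apply_signature, combat_adjust, fit_cox)

train_cfg = SyntheticConfig(n_samples=450, shift=2.5, true_log_hr=np.log(5.0), seed=1)
valid_cfg = SyntheticConfig(n_samples=107, shift=2.5, true_log_hr=np.log(5.0), seed=2)
train, valid = generate_paired_cohorts(train_cfg, valid_cfg)

res = screen_genes(train.expression, train.survival)
genes = list(res.index[res["selected"]])
sig = fit_signature(train.expression.subset_genes(genes), train.survival, random_state=0)

joint = pd.concat([train.expression.values, valid.expression.values], axis=1)
adjusted, _ = combat_adjust(joint, ["train"] * 450 + ["validation"] * 107)
table = apply_signature(sig, adjusted.loc[sig.genes_, valid.expression.sample_ids])
cox = fit_cox(valid.survival, table["adverse"].to_numpy(float)[:, None])
```

This prints (via the obvious `print` calls):

```
selected genes: ['G00022', 'G00807', 'G00899', 'G01195']
covariance family: EII
training adverse fraction: 4.44%
training HR: 3.60 (p=6.33e-08)
validation adverse calls: 7/107 (6.54%)
validation HR: 8.25 (95% CI 3.27-20.82, p=7.99e-06)
```

The screen recovered the three planted genes (plus one false positive,
the price of FDR-5% selection); the multivariate clusterization isolates
4.4% of training samples as the adverse cluster, and the frozen model
transfers: 6.5% of validation samples are called adverse with an
eight-fold death hazard.  `table["borderline"]` flags samples whose
adverse posterior falls in [0.4, 0.6].

The same workflow is available from the shell:

```sh
clustsig simulate --paired --seed 1 --out cohort/
clustsig screen  --expression cohort/train/expression.tsv --survival cohort/train/survival.tsv --out screen/
clustsig fit     --expression cohort/train/expression.tsv --survival cohort/train/survival.tsv \
                 --genes screen/selected_genes.txt --out sig/
clustsig validate --model sig/signature.json --expression cohort/validation/expression.tsv \
                 --survival cohort/validation/survival.tsv \
                 --train-expression cohort/train/expression.tsv --out val/
```

Estimator classes (`ConstrainedGaussianMixture`, `CoxPH`, `GeneScreen`,
`ClusterSignature`, `CombatAdjuster`) follow scikit-learn conventions
(`fit` / `predict` / `transform`, `get_params`, fitted attributes with a
trailing underscore) and compose with sklearn tooling; the module-level
functions shown above are thin wrappers over them.

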