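# Methods

## The statistical problem

A minority of patients — on the order of 5% of a cohort — carries a
shifted expression pattern in a small set of genes and a sharply higher
death hazard.  The pipeline finds such patterns in a discovery cohort
and transfers them, with parameters frozen, to an external cohort
measured on a different platform.  Every stage is a standard, published
procedure; the package's contribution is a tested, reproducible
composition of them with ground-truth simulation.

## Constrained Gaussian mixtures

Cluster structure is modeled as a K-component Gaussian mixture whose
component covariances are constrained geometrically:
Σ_k = λ_k·A_k with volume λ_k > 0 and diagonal shape A_k, det A_k = 1.
Families are named by whether volume and shape are **E**qual across
components, **V**arying, or the **I**dentity: EII (λI), VII (λ_kI),
EEI (λA), VEI (λ_kA), EVI (λA_k), VVI (λ_kA_k); univariate data use E
(shared variance) and V (free variances).  Rotated (full-covariance)
families are an extension point, not implemented: the applications here
need only the spherical/diagonal families, and the per-gene screen is
univariate.

Estimation is EM.  M-step covariance updates follow the standard
closed forms from the responsibility-weighted scatter matrices W_k;
VEI has no joint closed form, so λ_k ← tr(W_k A⁻¹)/(d·n_k) and
A ← diag(Σ_k W_k/λ_k)/det(·)^{1/d} are alternated to a relative change
below 1e-8 (at most 100 inner iterations).  Free-parameter counts m
(for BIC) are (K−1) + K·d + {EII 1, VII K, EEI d, VEI K+d−1,
EVI 1+K(d−1), VVI Kd}.

**Model selection** maximizes BIC = 2·ℓ − m·log n (the model-based
-clustering sign convention; much of the statistics literature minimizes
the negated quantity).  Ties break toward fewer parameters.

**Initialization** is deterministic by default, so results reproduce
without seeds: univariate data start from the contiguous split of the
sorted values minimizing within-group sum of squares (for n ≤ 12,
exhaustive scoring of all two-part subsets, whose best member EM can
only improve on — with per-component variances the optimum need not be
contiguous); multivariate data start from Ward agglomeration.  Seeded
random restarts (random sorted intervals in one dimension, random
centers otherwise) run as a fallback, or as a multi-start when
`init="random"`.

**Convergence** is declared when the log-likelihood increment falls
below a relative tolerance, or when Aitken extrapolation of the
likelihood sequence stabilizes to the same tolerance — EM on overlapping
components converges linearly at a rate near 1, where the raw increment
rule stalls for thousands of iterations; the Aitken rule is the one
model-based-clustering software uses.  Defaults: tol 1e-8, max_iter 500
for single fits; the genome-wide screen uses tol 1e-5 (the reference
software's own default), which leaves per-gene labels and the E/V BIC
ordering unchanged.

**Degeneracies.**  Zero-variance input is refused.  A fitted variance
below 1e-8 times the data variance is clamped at that floor (flagged
`floor_hit_`): perfectly separated clusters drive a within-component
variance to zero and the likelihood to +∞, and the floor caps it at a
finite, comparable value.  A component whose responsibility-weighted
count drops below 1 ends the run at the last valid parameters
(`collapsed_`); if every start collapses immediately the fit errors.
We chose clamping over abort-and-error because exactly separated data
are legitimate inputs (and the likelihood ascent before a collapse is
still a valid fit); the flags let callers discriminate.

The per-gene screen fits thousands of independent univariate mixtures;
these run batched in a single array program (K=2 reduces the E-step to a
logistic difference of two log-densities and the M-step to two
sufficient-statistic reductions), with converged genes retired from the
active set each iteration.  The batched path and the single-fit path are
asserted against each other in the tests.

## Survival machinery

Cox proportional-hazards regression maximizes the partial likelihood by
Newton–Raphson with step halving, Efron tie handling by default
(Breslow available; they coincide without ties).  Inference is Wald:
HR = exp(β̂), 95% CI exp(β̂ ± 1.959964·se), two-sided p from the normal.
The gradient at the returned β̂ is below 1e-8 in sup-norm.  A monotone
partial likelihood (a covariate perfectly separating the events) is
reported as an explicit error once |β̂| exceeds 15 — an implausible
log-hazard for any real effect — rather than silently returning a
diverged coefficient.  The adverse group is always coded 1, so HRs above
one mean the flagged group dies faster; a reciprocal coding reports
1/HR, the same fit.

Kaplan–Meier curves use the product-limit estimator (censored subjects
leave the risk set at their censoring time).  Benjamini–Hochberg
q-values use the step-up rule q_(i) = min_{j≥i} m·p_(j)/j capped at 1,
applied once across all tested genes of a screen (a single q-value
family).

## The per-gene screen

Per gene: BIC-select between E and V at K=2; hard-label samples by
maximum posterior; code the cluster with the higher observed hazard
(events per unit person-time) as 1 so hazard ratios are comparable
across genes; Cox of survival on that indicator; BH across all
non-skipped genes; select at q < 0.05.  Genes are skipped — excluded
from the BH family, with a recorded reason — when variance is zero,
the mixture cannot be fitted after restarts, the minor cluster has
fewer than `min_cluster` = 3 samples (a Cox fit against 1–2 samples is
numerically fragile and uninformative), or the Cox likelihood is
monotone.  Hard labels (not posterior weights) enter the Cox model,
matching the single-gene-cluster framing; posterior-weighted regression
is a possible extension.

Multi-probe genes collapse to gene level by the per-sample median
across probes before screening.

## The multivariate signature and its transfer

The signature is the ordered selected-gene list, the frozen K=2
constrained mixture over them (family chosen by BIC across all six
diagonal/spherical candidates), and the index of the adverse component —
identified by the higher observed event hazard of its hard-labeled
members, not by size: adverse clusters of this kind happen to be small,
but hazard is the defensible identifying criterion (cluster sizes are
reported alongside).  Equal observed hazards fall
back to component order with a logged warning.

Prediction on new data is pure posterior evaluation under the frozen
model; gene order is enforced, missing genes abort with their names.
Hard calls use posterior > 0.5; posteriors in [0.4, 0.6] carry a
`borderline` flag, because a transferred cohort routinely contains a
sample or two sitting essentially on the decision boundary, and such
calls deserve individual inspection rather than a silent coin flip.  The signature serializes to JSON and round-trips to
bit-identical predictions.

Cross-platform transfer order: collapse probes → intersect genes by
symbol (unresolved symbols abort) → batch adjust over the **full**
shared gene set → restrict to the signature genes → predict.  Adjusting
only the few signature genes would leave the empirical-Bayes priors
moment-matched across a handful of genes, which is meaningless.

## Batch adjustment

Parametric empirical-Bayes location/scale adjustment per gene g and
batch b: Y_gbi = α_g + γ_gb + δ_gb·ε.  After standardizing each gene by
its pooled mean and residual variance, per-batch location γ̂ and scale
δ̂² estimates are shrunk under a normal prior (moment-matched γ̄, τ²) and
an inverse-gamma prior (moment-matched shape/scale), with the coupled
posterior updates iterated to relative change < 1e-6 (max 200).  The
shrunken effects are removed and the pooled scale restored.  A single
batch is returned unchanged.  The nonparametric variant is out of scope.
`reference_batch` keeps one batch untouched and moves the others onto
it — the natural mode when a model frozen on that batch will be applied
afterwards; the default pools batches symmetrically, which is how the
joint training+validation adjustment is run.

## The synthetic cohort generator

The generator emulates the study design the pipeline targets, and its
defaults are those conditions: 450 samples (107 for the paired
validation cohort), 2000 genes of which 3 form the signature, minority
fraction 4.5%, log2-scale baseline means N(7, 1.5²), gene-wise Gaussian
noise with SD 0.5 (the typical per-gene spread of RMA-normalized
arrays; at the 2–2.5 log2-unit shifts used throughout, signature genes
are then cleanly bimodal — the phenomenon a per-gene clusterization
screen exists to detect), signature shift 2.0, survival exponential
with baseline hazard 0.05/year and cluster log-hazard log 4.86,
censoring exponential at 0.02/year (≈27% censored; the follow-up scale
is a modeling choice and both rates are exposed in the config rather
than hard-coded).  Optional binary covariates with specified prevalence and
log-hazard enter the true hazard multiplicatively.  A Weibull option
generalizes the survival model behind a config switch; gene-wise noise
is Gaussian on the log2 scale, matching the mixture model's assumption.

Paired cohorts share gene-level generating parameters; the validation
cohort then receives gene-wise batch effects in exactly the form the
adjustment model assumes: additive γ_g ~ N(0, 1) and multiplicative
δ_g² ~ InverseGamma(3, scale 2) (mean 1) applied to deviations around
each gene's baseline mean.

One integer seed drives everything through independently spawned
sub-streams per block (gene parameters, labels, noise, survival,
covariates, batch), so runs are bit-reproducible and changing one block
does not perturb another.

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: probe-level intensities and RMA
artifacts, correlated gene-gene structure (genes are independent given
cluster), heavy-tailed or multimodal null genes, informative censoring,
treatment-era effects, and covariates correlated with the expression
cluster (confounding is planted explicitly in the tests that need it).

## Design choices and numerical notes

- Efron ties by default; Wald inference to match the HR + CI + p
  reporting convention of clinical studies.
- Sample alignment between expression and survival is an inner join
  with a logged warning naming dropped samples; silent intersection is
  forbidden.  The two cohorts' survival clocks may differ (diagnosis→
  death vs. array→death); the clock is carried as metadata and logged,
  not reconciled.
- The screen's BH family is all non-skipped genes, once, not per batch
  or chromosome.
- Collinear covariates in the adjusted Cox model abort with the
  offending columns named (QR diagnostic); incomplete cases are dropped
  with a count.
- Pipeline runs write a manifest (config hash excluding output paths,
  package version, SHA-256 of every artifact); identical config + seeds
  reproduce bit-identical manifests.

## Known limitations

- Hazard-ratio estimates from ~20-sample minority clusters are noisy
  and slightly biased away from zero; confidence-interval coverage is
  verified by simulation (0.90–0.98) but individual estimates can be
  far from truth.
- At FDR 0.05 with a handful of true positives among thousands of null
  genes, the selected set contains at least one false positive in
  roughly 1 replicate in 5 — this is the designed behavior of BH
  selection, not a defect; downstream stages tolerate extra genes.
- The screen's power depends on marginal (unadjusted) per-gene hazard
  ratios; strong prognostic covariates attenuate these through frailty,
  and all genes share one survival realization, so screen failures are
  correlated across genes within a cohort.
- EM finds local optima; the deterministic initialization makes results
  reproducible but not certifiably global except for tiny samples,
  where initialization is exhaustive.
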