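"""Synthetic CLL-like cohorts with a planted minority expression cluster.

The generator emulates the kind of data the pipeline targets: a few
hundred samples on a log2 microarray scale, a small minority cluster
(roughly 4-6% of patients) whose members have a handful of *signature*
genes shifted in mean and a sharply elevated death hazard, independent
exponential censoring, and optional cohort-level gene-wise batch effects
(additive location gamma_g, multiplicative scale delta_g) of the form
batch-adjustment procedures assume.

Every draw is reproducible: one integer seed spawns independent
sub-streams per block (gene parameters, labels, expression noise,
survival, covariates, batch), so e.g. changing the censoring rate does
not perturb the expression values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, SurvivalTable

__all__ = ["SyntheticConfig", "SyntheticCohort", "generate_cohort",
           "generate_paired_cohorts"]


@dataclass
class SyntheticConfig:
    """Generating parameters for one synthetic cohort.

    Defaults mirror the discovery-cohort conditions the pipeline is built
    for: 450 samples, 2000 genes of which 3 form the signature, a 4.5%
    minority cluster shifted by 2 log2 units, gene-wise noise of 0.5
    log2 units (the typical per-gene spread of RMA-normalized arrays,
    and a separation at which signature genes are cleanly bimodal -
    the phenomenon the per-gene screen exists to detect), a
    baseline hazard of 0.05 events per time unit with a cluster hazard
    ratio of 4.86, and censoring at 0.02 per time unit (just under 30%
    censored observations overall).
    """

    n_samples: int = 450
    n_genes: int = 2000
    n_signature_genes: int = 3
    minority_fraction: float = 0.045
    shift: float | tuple = 2.0
    noise_sd: float = 0.5
    baseline_hazard: float = 0.05
    true_log_hr: float = float(np.log(4.86))
    censor_rate: float = 0.02
    batch_gamma_sd: float = 1.0
    batch_delta_shape: float = 3.0
    covariate_spec: list = field(default_factory=list)  # (name, prevalence, log_hr)
    survival_model: str = "exponential"  # or "weibull"
    weibull_shape: float = 1.0
    mean_loc: float = 7.0
    mean_scale: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.minority_fraction < 0.5):
            raise ValueError("minority_fraction must lie in (0, 0.5)")
        if self.n_signature_genes > self.n_genes:
            raise ValueError("n_signature_genes exceeds n_genes")
        if self.minority_fraction * self.n_samples < 2:
            raise ValueError(
                "expected minority cluster below 2 samples: unfittable"
            )
        if self.noise_sd <= 0 or self.baseline_hazard <= 0:
            raise ValueError("noise_sd and baseline_hazard must be positive")
        if self.censor_rate < 0 or self.batch_gamma_sd < 0:
            raise ValueError("rates must be non-negative")
        if self.batch_delta_shape <= 2:
            raise ValueError("batch_delta_shape must exceed 2 (finite variance)")
        if self.survival_model not in ("exponential", "weibull"):
            raise ValueError(f"unknown survival model {self.survival_model!r}")
        shift = np.atleast_1d(np.asarray(self.shift, dtype=float))
        if shift.size not in (1, self.n_signature_genes):
            raise ValueError("shift must be scalar or one value per signature gene")

    def shift_vector(self) -> np.ndarray:
        shift = np.atleast_1d(np.asarray(self.shift, dtype=float))
        if shift.size == 1:
            shift = np.repeat(shift, self.n_signature_genes)
        return shift

    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(d["shift"], tuple):
            d["shift"] = list(d["shift"])
        return d


@dataclass
class SyntheticCohort:
    """One generated cohort plus its ground truth."""

    expression: ExpressionMatrix
    survival: SurvivalTable
    true_labels: pd.Series  # 0 = majority, 1 = minority
    true_params: dict


def _spawn(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _gene_params(config: SyntheticConfig, rng: np.random.Generator) -> dict:
    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    means = rng.normal(config.mean_loc, config.mean_scale, size=config.n_genes)
    sig_idx = np.sort(
        rng.choice(config.n_genes, size=config.n_signature_genes, replace=False)
    )
    return {
        "gene_ids": gene_ids,
        "gene_means": means,
        "signature_index": sig_idx,
        "signature_genes": [gene_ids[i] for i in sig_idx],
        "shift": config.shift_vector(),
        "noise_sd": config.noise_sd,
    }


def _draw_cohort(
    config: SyntheticConfig,
    gene_params: dict,
    sample_prefix: str,
    batch_label: str,
    rngs,
) -> SyntheticCohort:
    rng_label, rng_noise, rng_surv, rng_cov = rngs
    n, G = config.n_samples, config.n_genes
    sample_ids = [f"{sample_prefix}{i:04d}" for i in range(n)]
    labels = (rng_label.random(n) < config.minority_fraction).astype(int)

    mu = np.tile(gene_params["gene_means"][:, None], (1, n))
    sig_idx = gene_params["signature_index"]
    mu[sig_idx[:, None], np.nonzero(labels)[0][None, :]] += gene_params["shift"][:, None]
    values = mu + rng_noise.normal(0.0, gene_params["noise_sd"], size=(G, n))

    # covariates and their hazard contribution
    log_risk = config.true_log_hr * labels.astype(float)
    cov_cols = {}
    for name, prevalence, log_hr in config.covariate_spec:
        x = (rng_cov.random(n) < prevalence).astype(int)
        cov_cols[name] = x
        log_risk = log_risk + log_hr * x
    hazard = config.baseline_hazard * np.exp(log_risk)

    if config.survival_model == "exponential":
        t_event = rng_surv.exponential(1.0 / hazard)
    else:
        # Weibull with proportional hazards: S(t) = exp(-(h0 t)^k * e^eta)
        u = rng_surv.random(n)
        k = config.weibull_shape
        t_event = (-np.log(u) / hazard) ** (1.0 / k) * config.baseline_hazard ** (
            1.0 / k - 1.0
        )
    if config.censor_rate > 0:
        t_cens = rng_surv.exponential(1.0 / config.censor_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    expr = ExpressionMatrix(
        pd.DataFrame(values, index=gene_params["gene_ids"], columns=sample_ids),
        batch=pd.Series(batch_label, index=sample_ids),
        metadata={"log_base": 2, "batch": batch_label},
    )
    surv_df = pd.DataFrame({"time": time, "event": event, **cov_cols},
                           index=pd.Index(sample_ids, name="sample"))
    surv = SurvivalTable(surv_df, metadata={"time_unit": "years",
                                            "clock": "synthetic origin"})
    true_params = {
        **{k: v for k, v in gene_params.items() if k != "gene_means"},
        "gene_means": gene_params["gene_means"],
        "baseline_hazard": config.baseline_hazard,
        "true_log_hr": config.true_log_hr,
        "censor_rate": config.censor_rate,
        "config": config.to_dict(),
    }
    return SyntheticCohort(
        expression=expr,
        survival=surv,
        true_labels=pd.Series(labels, index=sample_ids, name="true_label"),
        true_params=true_params,
    )


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Draw one cohort under ``config``; bit-reproducible from its seed."""
    config.validate()
    rng_params, *rngs = _spawn(config.seed, 5)
    gene_params = _gene_params(config, rng_params)
    return _draw_cohort(config, gene_params, "S", "cohort0", rngs)


def generate_paired_cohorts(
    config_train: SyntheticConfig,
    config_valid: SyntheticConfig,
    shared_params: bool = True,
):
    """Draw a training and a validation cohort.

    With ``shared_params`` the validation cohort re-uses the training
    cohort's gene-level generating distributions (same baseline means,
    same signature genes and shifts) and then receives gene-wise batch
    effects drawn from ``config_valid``: additive
    ``gamma_g ~ N(0, batch_gamma_sd^2)`` and multiplicative
    ``delta_g^2 ~ InvGamma(batch_delta_shape, scale=batch_delta_shape-1)``
    (mean 1) applied to deviations around each gene's baseline mean, i.e.
    the location/scale model empirical-Bayes batch adjustment assumes.
    """
    config_train.validate()
    config_valid.validate()
    rng_params, *train_rngs = _spawn(config_train.seed, 5)
    gene_params = _gene_params(config_train, rng_params)
    train = _draw_cohort(config_train, gene_params, "T", "train", train_rngs)

    rng_vparams, rng_vlabel, rng_vnoise, rng_vsurv, rng_vcov, rng_batch = _spawn(
        config_valid.seed, 6
    )
    if shared_params:
        if config_valid.n_genes != config_train.n_genes:
            raise ValueError("shared_params requires equal n_genes")
        v_gene_params = gene_params
    else:
        v_gene_params = _gene_params(config_valid, rng_vparams)
    valid = _draw_cohort(
        config_valid, v_gene_params, "V", "validation",
        [rng_vlabel, rng_vnoise, rng_vsurv, rng_vcov],
    )

    G = config_valid.n_genes
    gamma = rng_batch.normal(0.0, config_valid.batch_gamma_sd, size=G)
    shape = config_valid.batch_delta_shape
    if np.isinf(shape):  # degenerate prior: no scale effect
        delta_sq = np.ones(G)
    else:
        delta_sq = stats.invgamma(a=shape, scale=shape - 1.0).rvs(
            size=G, random_state=rng_batch
        )
    alpha = v_gene_params["gene_means"][:, None]
    vals = valid.expression.values.to_numpy()
    adjusted = alpha + gamma[:, None] + np.sqrt(delta_sq)[:, None] * (vals - alpha)
    valid.expression.values.iloc[:, :] = adjusted
    for cohort in (train, valid):
        cohort.true_params["batch_gamma"] = gamma
        cohort.true_params["batch_delta_sq"] = delta_sq
    return train, valid
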