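"""Multivariate signature: fit, identify the adverse cluster, transfer.

The signature is a frozen K=2 constrained Gaussian mixture over a small
ordered gene list plus the index of the *adverse* component - the one
whose hard-labeled members show the higher observed death hazard
(events per unit person-time).  Applying the signature to a new cohort
is pure posterior evaluation: no parameter is refitted, so the cluster
definition genuinely transfers across cohorts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, SurvivalTable, align_samples
from .errors import CollinearityError, DegenerateDataError
from .mixture import (
    MULTIVARIATE_FAMILIES,
    ClusterAssignment,
    ConstrainedGaussianMixture,
)
from .survival import CoxFit, CoxPH

__all__ = [
    "ClusterSignature",
    "fit_signature",
    "apply_signature",
    "adjusted_cox",
    "sensitivity_drop",
]

logger = logging.getLogger(__name__)


class ClusterSignature:
    """Survival-stratifying expression signature (estimator style).

    ``fit(expr, surv)`` selects the best-BIC covariance family at K=2
    over the signature genes, labels the higher-hazard component as
    adverse, and stores the training survival association.
    ``predict(expr_new)`` / ``predict_proba`` evaluate new samples under
    the frozen mixture; a hard adverse call is made at posterior > 0.5
    and posteriors within ``borderline_band`` are flagged for review.

    Parameters
    ----------
    families : candidate covariance families (diagonal/spherical codes).
    borderline_band : (low, high) posterior interval flagged borderline.
    ties : Cox tie handling for the stored survival association.
    random_state : seed for mixture restart streams.
    """

    def __init__(self, families=MULTIVARIATE_FAMILIES, borderline_band=(0.4, 0.6),
                 ties="efron", random_state=None):
        self.families = families
        self.borderline_band = borderline_band
        self.ties = ties
        self.random_state = random_state

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in (
            "families", "borderline_band", "ties", "random_state")}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    # ------------------------------------------------------------------
    def fit(self, expr, surv, genes=None):
        if not isinstance(expr, ExpressionMatrix):
            expr = ExpressionMatrix(pd.DataFrame(expr))
        if genes is not None:
            expr = expr.subset_genes(genes)
        if not isinstance(surv, SurvivalTable):
            surv = SurvivalTable(pd.DataFrame(surv))
        if expr.n_genes < 2:
            raise ValueError("signature needs at least 2 genes")
        expr, surv = align_samples(expr, surv, logger=logger)
        X = expr.values.to_numpy(dtype=float).T  # samples x genes

        model = ConstrainedGaussianMixture(
            n_components=2, family=tuple(self.families),
            random_state=self.random_state,
        ).fit(X)
        z = model.responsibilities_
        labels = np.argmax(z, axis=1)
        counts = np.bincount(labels, minlength=2)
        if counts.min() == 0:
            raise DegenerateDataError(
                "degenerate clustering: one component captured no samples; "
                f"BIC table: {model.bic_table_}"
            )

        time, event = surv.time, surv.event
        rates = np.array([
            event[labels == k].sum() / max(time[labels == k].sum(), 1e-300)
            for k in (0, 1)
        ])
        if rates[0] == rates[1]:
            logger.warning(
                "identical observed hazards in both components; adverse "
                "cluster falls back to component order"
            )
            adverse = 1
        else:
            adverse = int(np.argmax(rates))

        adv = (labels == adverse).astype(float)
        cox = CoxPH(ties=self.ties).fit(adv[:, None], time, event)

        self.genes_ = expr.gene_ids
        self.mixture_ = model
        self.adverse_cluster_ = adverse
        self.bic_table_ = model.bic_table_
        self.training_assignment_ = ClusterAssignment.from_responsibilities(z)
        self.training_labels_ = pd.Series(adv.astype(int), index=expr.sample_ids,
                                          name="adverse")
        self.training_cox_ = cox.result_
        self.training_summary_ = {
            "n": int(len(adv)),
            "n_adverse": int(adv.sum()),
            "adverse_fraction": float(adv.mean()),
            "family": model.family_,
            "hr": float(cox.result_.hr[0]),
            "p": float(cox.result_.p[0]),
        }
        return self

    # ------------------------------------------------------------------
    def _matrix_for(self, expr) -> tuple[np.ndarray, list]:
        if not isinstance(expr, ExpressionMatrix):
            expr = ExpressionMatrix(pd.DataFrame(expr))
        missing = [g for g in self.genes_ if g not in set(expr.gene_ids)]
        if missing:
            raise KeyError(f"signature genes absent from matrix: {missing}")
        sub = expr.values.loc[self.genes_]  # enforce training gene order
        return sub.to_numpy(dtype=float).T, list(sub.columns)

    def predict_proba(self, expr) -> np.ndarray:
        """Posterior probability of the adverse component per sample."""
        X, _ = self._matrix_for(expr)
        return self.mixture_.predict_proba(X)[:, self.adverse_cluster_]

    def predict(self, expr) -> np.ndarray:
        """Hard adverse calls (posterior > 0.5)."""
        return (self.predict_proba(expr) > 0.5).astype(int)

    def assignment_table(self, expr) -> pd.DataFrame:
        """Per-sample adverse posterior, hard call, and borderline flag."""
        X, samples = self._matrix_for(expr)
        post = self.mixture_.predict_proba(X)[:, self.adverse_cluster_]
        lo, hi = self.borderline_band
        return pd.DataFrame(
            {
                "adverse_posterior": post,
                "adverse": (post > 0.5).astype(int),
                "borderline": (post >= lo) & (post <= hi),
            },
            index=pd.Index(samples, name="sample"),
        )

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "genes": list(self.genes_),
            "adverse_cluster": int(self.adverse_cluster_),
            "borderline_band": list(self.borderline_band),
            "mixture": self.mixture_.to_dict(),
            "training_summary": self.training_summary_,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ClusterSignature":
        sig = cls(borderline_band=tuple(payload["borderline_band"]))
        sig.genes_ = list(payload["genes"])
        sig.adverse_cluster_ = int(payload["adverse_cluster"])
        sig.mixture_ = ConstrainedGaussianMixture.from_dict(payload["mixture"])
        sig.training_summary_ = payload["training_summary"]
        return sig

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load_json(cls, path) -> "ClusterSignature":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def fit_signature(expr, surv, genes=None, families=MULTIVARIATE_FAMILIES,
                  random_state=None) -> ClusterSignature:
    """Fit the multivariate signature on the selected genes."""
    return ClusterSignature(families=families, random_state=random_state).fit(
        expr, surv, genes=genes
    )


def apply_signature(model: ClusterSignature, expr_new) -> pd.DataFrame:
    """Score a new cohort under a frozen signature (no refitting)."""
    return model.assignment_table(expr_new)


def _complete_case_design(surv: SurvivalTable, cluster, covariates):
    cluster = pd.Series(np.asarray(cluster, dtype=float), index=surv.sample_ids,
                        name="cluster")
    design = pd.DataFrame({"cluster": cluster})
    if covariates is not None:
        if isinstance(covariates, (list, tuple)):
            cov = surv.covariates(covariates)
        else:
            cov = pd.DataFrame(covariates).astype(float)
            cov = cov.loc[surv.sample_ids]
        design = pd.concat([design, cov], axis=1)
    complete = design.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("adjusted Cox dropped %d incomplete cases", n_dropped)
    design = design.loc[complete].astype(float)

    centered = design.to_numpy() - design.to_numpy().mean(axis=0)
    rank = np.linalg.matrix_rank(centered)
    if rank < design.shape[1]:
        # name the offending columns via near-zero diagonal of R in a QR
        _, R = np.linalg.qr(centered)
        diag = np.abs(np.diag(R))
        bad = [design.columns[j] for j in range(design.shape[1])
               if diag[j] < 1e-8 * max(diag.max(), 1.0)]
        raise CollinearityError(
            f"collinear covariates in adjusted model: {bad or list(design.columns)}",
            columns=bad,
        )
    return design, complete, n_dropped


def adjusted_cox(surv, cluster, covariates=None, ties="efron") -> CoxFit:
    """Multivariate Cox of survival on the cluster indicator plus covariates.

    ``covariates`` may be a list of column names present in the survival
    table (e.g. age, Binet stage, IGHV status, TP53/del17p, ATM/del11q,
    NOTCH1, SF3B1, BIRC3) or a DataFrame aligned on sample id.  Only
    complete cases enter the fit; the dropped count is logged.  With an
    empty covariate set this reduces to the unadjusted cluster fit.
    """
    if not isinstance(surv, SurvivalTable):
        surv = SurvivalTable(pd.DataFrame(surv))
    design, complete, n_dropped = _complete_case_design(surv, cluster, covariates)
    sub = surv.data.loc[complete]
    fit = CoxPH(ties=ties).fit(design, sub["time"].to_numpy(),
                               sub["event"].to_numpy(dtype=int))
    result = fit.result_
    result.dropped_samples = list(surv.data.index[~complete])
    return result


def sensitivity_drop(surv, labels, drop_ids, ties="efron") -> dict:
    """Refit the cluster~survival Cox excluding the named samples.

    Returns both fits side by side together with the adverse fraction
    recomputed over the remaining samples.
    """
    if not isinstance(surv, SurvivalTable):
        surv = SurvivalTable(pd.DataFrame(surv))
    labels = pd.Series(np.asarray(labels, dtype=float), index=surv.sample_ids)
    unknown = [s for s in drop_ids if s not in set(surv.sample_ids)]
    if unknown:
        raise KeyError(f"drop_ids not in survival table: {unknown}")
    keep = [s for s in surv.sample_ids if s not in set(drop_ids)]
    if labels.loc[keep].sum() == 0:
        raise ValueError("dropping the named samples removes every adverse case")
    full = CoxPH(ties=ties).fit(
        labels.to_numpy()[:, None], surv.time, surv.event
    ).result_
    sub_surv = surv.subset(keep)
    reduced = CoxPH(ties=ties).fit(
        labels.loc[keep].to_numpy()[:, None], sub_surv.time, sub_surv.event
    ).result_
    return {
        "full": full,
        "reduced": reduced,
        "n_dropped": len(list(drop_ids)),
        "adverse_fraction_full": float(labels.mean()),
        "adverse_fraction_reduced": float(labels.loc[keep].mean()),
    }
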