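"""Parametric empirical-Bayes location/scale batch adjustment (ComBat).

Model per gene g, batch b, sample i:  ``Y_gbi = alpha_g + gamma_gb +
delta_gb * eps_gbi``.  Gene-wise batch locations ``gamma`` get a normal
prior and scales ``delta^2`` an inverse-gamma prior, both moment-matched
across genes within each batch; the coupled posterior-mode updates are
iterated to a fixed point and the shrunken estimates are removed.
Shrinkage stabilizes the per-gene estimates exactly where they are
noisiest - genes measured in few samples per batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

__all__ = ["CombatAdjuster", "BatchAdjustment", "combat_adjust"]


@dataclass
class BatchAdjustment:
    """Diagnostics of one adjustment: raw and shrunken batch effects."""

    batches: list
    gamma_hat: pd.DataFrame      # genes x batches, raw standardized locations
    gamma_star: pd.DataFrame     # genes x batches, EB-shrunk
    delta_hat_sq: pd.DataFrame   # genes x batches, raw standardized scales
    delta_star_sq: pd.DataFrame  # genes x batches, EB-shrunk
    gamma_bar: pd.Series         # per-batch normal prior mean
    tau_sq: pd.Series            # per-batch normal prior variance
    ig_shape: pd.Series          # per-batch inverse-gamma shape (lambda)
    ig_scale: pd.Series          # per-batch inverse-gamma scale (theta)
    grand_mean: pd.Series        # pooled per-gene mean (alpha_hat)
    pooled_var: pd.Series        # pooled per-gene residual variance
    dropped_genes: list          # zero-pooled-variance genes removed

    def to_tsv(self, out_dir) -> None:
        """Dump the per-gene diagnostics as TSV files for inspection."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("gamma_hat", "gamma_star", "delta_hat_sq",
                     "delta_star_sq"):
            getattr(self, name).to_csv(out / f"{name}.tsv", sep="\t",
                                       index_label="gene")
        hyper = pd.DataFrame({
            "gamma_bar": self.gamma_bar, "tau_sq": self.tau_sq,
            "ig_shape": self.ig_shape, "ig_scale": self.ig_scale,
        })
        hyper.to_csv(out / "hyperparameters.tsv", sep="\t",
                     index_label="batch")


def _moment_match_invgamma(mean: float, var: float):
    """Shape/scale of an inverse-gamma with the given mean and variance."""
    shape = (2.0 * var + mean**2) / var
    scale = (mean * var + mean**3) / var
    return shape, scale


def _eb_fixed_point(Z, gamma_hat, delta_hat_sq, gamma_bar, tau_sq,
                    ig_shape, ig_scale, tol=1e-6, max_iter=200):
    """Coupled posterior updates for (gamma*, delta*^2) in one batch.

    Z is the standardized data restricted to the batch (genes x samples).
    """
    n_b = Z.shape[1]
    g_star = gamma_hat.copy()
    d_star = delta_hat_sq.copy()
    for _ in range(max_iter):
        g_new = (n_b * tau_sq * gamma_hat + d_star * gamma_bar) / (
            n_b * tau_sq + d_star
        )
        sum2 = ((Z - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (ig_scale + 0.5 * sum2) / (n_b / 2.0 + ig_shape - 1.0)
        change = max(
            np.max(np.abs(g_new - g_star) / np.maximum(np.abs(g_star), 1e-12)),
            np.max(np.abs(d_new - d_star) / np.maximum(d_star, 1e-12)),
        )
        g_star, d_star = g_new, d_new
        if change < tol:
            break
    return g_star, d_star


class CombatAdjuster:
    """Empirical-Bayes batch adjustment as a fit/transform estimator.

    ``fit_transform(X, batch)`` is the usual entry point and adjusts the
    samples that defined the standardization.  ``reference_batch`` keeps
    the named batch untouched and moves every other batch onto it, which
    is the natural mode when a frozen model trained on that batch will be
    applied afterwards.

    Parameters
    ----------
    parametric : bool
        Only the parametric EB variant is implemented; ``False`` raises.
    reference_batch : label or None
        None (default) pools all batches symmetrically.
    tol, max_iter : fixed-point controls for the coupled EB updates.
    """

    def __init__(self, parametric=True, reference_batch=None,
                 tol=1e-6, max_iter=200):
        self.parametric = parametric
        self.reference_batch = reference_batch
        self.tol = tol
        self.max_iter = max_iter

    def get_params(self, deep=True):
        return {
            "parametric": self.parametric,
            "reference_batch": self.reference_batch,
            "tol": self.tol,
            "max_iter": self.max_iter,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit_transform(self, X, batch):
        """Adjust a genes x samples frame; returns the adjusted frame.

        Stores the full :class:`BatchAdjustment` as ``adjustment_``.
        """
        if not self.parametric:
            raise NotImplementedError("nonparametric ComBat is not implemented")
        if isinstance(X, ExpressionMatrix):
            frame = X.values
        else:
            frame = pd.DataFrame(X)
        batch = pd.Series(np.asarray(batch), index=frame.columns)
        vals = frame.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite values in expression matrix")
        levels = list(pd.unique(batch))
        sizes = batch.value_counts()
        small = [b for b in levels if sizes[b] < 2]
        if small:
            raise ValueError(f"batches with fewer than 2 samples: {small}")

        pooled_var_all = None
        if len(levels) == 1:
            # nothing to adjust; identity transform with trivial diagnostics
            genes = frame.index
            zero = pd.DataFrame(0.0, index=genes, columns=levels)
            one = pd.DataFrame(1.0, index=genes, columns=levels)
            self.adjustment_ = BatchAdjustment(
                batches=levels, gamma_hat=zero, gamma_star=zero.copy(),
                delta_hat_sq=one, delta_star_sq=one.copy(),
                gamma_bar=pd.Series(0.0, index=levels),
                tau_sq=pd.Series(0.0, index=levels),
                ig_shape=pd.Series(np.nan, index=levels),
                ig_scale=pd.Series(np.nan, index=levels),
                grand_mean=frame.mean(axis=1),
                pooled_var=frame.var(axis=1, ddof=1),
                dropped_genes=[],
            )
            self.n_dropped_ = 0
            return frame.copy()

        masks = {b: (batch == b).to_numpy() for b in levels}
        n = vals.shape[1]
        batch_means = np.column_stack([vals[:, masks[b]].mean(axis=1) for b in levels])
        if self.reference_batch is not None:
            if self.reference_batch not in levels:
                raise ValueError(
                    f"reference batch {self.reference_batch!r} not among {levels}"
                )
            ref = levels.index(self.reference_batch)
            grand = batch_means[:, ref]
            ref_vals = vals[:, masks[self.reference_batch]]
            pooled = ((ref_vals - grand[:, None]) ** 2).mean(axis=1)
        else:
            w = np.array([masks[b].sum() / n for b in levels])
            grand = batch_means @ w
            fitted = np.zeros_like(vals)
            for j, b in enumerate(levels):
                fitted[:, masks[b]] = batch_means[:, [j]]
            pooled = ((vals - fitted) ** 2).mean(axis=1)

        keep = pooled > 0.0
        dropped = list(frame.index[~keep])
        if dropped:
            vals = vals[keep]
            grand = grand[keep]
            pooled = pooled[keep]
            batch_means = batch_means[keep]
        genes = frame.index[keep]
        sd = np.sqrt(pooled)
        Z = (vals - grand[:, None]) / sd[:, None]

        gamma_hat = np.column_stack([Z[:, masks[b]].mean(axis=1) for b in levels])
        delta_hat = np.column_stack(
            [Z[:, masks[b]].var(axis=1, ddof=1) for b in levels]
        )
        gamma_bar = gamma_hat.mean(axis=0)
        tau_sq = gamma_hat.var(axis=0, ddof=1)
        gamma_star = np.zeros_like(gamma_hat)
        delta_star = np.ones_like(delta_hat)
        ig_shape = np.empty(len(levels))
        ig_scale = np.empty(len(levels))
        for j, b in enumerate(levels):
            ig_shape[j], ig_scale[j] = _moment_match_invgamma(
                delta_hat[:, j].mean(), delta_hat[:, j].var(ddof=1)
            )
            if self.reference_batch is not None and b == self.reference_batch:
                gamma_star[:, j] = 0.0
                delta_star[:, j] = 1.0
                continue
            gamma_star[:, j], delta_star[:, j] = _eb_fixed_point(
                Z[:, masks[b]], gamma_hat[:, j], delta_hat[:, j],
                gamma_bar[j], tau_sq[j], ig_shape[j], ig_scale[j],
                tol=self.tol, max_iter=self.max_iter,
            )

        adjusted = Z.copy()
        for j, b in enumerate(levels):
            adjusted[:, masks[b]] = (
                Z[:, masks[b]] - gamma_star[:, [j]]
            ) / np.sqrt(delta_star[:, [j]])
        adjusted = adjusted * sd[:, None] + grand[:, None]

        def _df(a):
            return pd.DataFrame(a, index=genes, columns=levels)

        self.adjustment_ = BatchAdjustment(
            batches=levels,
            gamma_hat=_df(gamma_hat), gamma_star=_df(gamma_star),
            delta_hat_sq=_df(delta_hat), delta_star_sq=_df(delta_star),
            gamma_bar=pd.Series(gamma_bar, index=levels),
            tau_sq=pd.Series(tau_sq, index=levels),
            ig_shape=pd.Series(ig_shape, index=levels),
            ig_scale=pd.Series(ig_scale, index=levels),
            grand_mean=pd.Series(grand, index=genes),
            pooled_var=pd.Series(pooled, index=genes),
            dropped_genes=dropped,
        )
        self.n_dropped_ = len(dropped)
        return pd.DataFrame(adjusted, index=genes, columns=frame.columns)


def combat_adjust(expr, batch=None, parametric=True, reference_batch=None):
    """Adjust an expression matrix for batch; returns (adjusted, diagnostics).

    ``expr`` may be an :class:`ExpressionMatrix` (its ``batch`` labels are
    used when ``batch`` is None) or a plain genes x samples DataFrame.
    """
    if batch is None:
        if isinstance(expr, ExpressionMatrix) and expr.batch is not None:
            batch = expr.batch
        else:
            raise ValueError("batch labels required")
    adj = CombatAdjuster(parametric=parametric, reference_batch=reference_batch)
    out = adj.fit_transform(expr, batch)
    if isinstance(expr, ExpressionMatrix):
        out = ExpressionMatrix(out, batch=pd.Series(np.asarray(batch),
                                                    index=out.columns),
                               metadata={**expr.metadata, "combat": True})
    return out, adj.adjustment_
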