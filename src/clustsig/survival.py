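"""Right-censored survival machinery.

Cox proportional-hazards regression by Newton-Raphson on the partial
likelihood (Efron or Breslow handling of tied event times), the
Kaplan-Meier product-limit estimator, and Benjamini-Hochberg step-up
adjustment of p-value families.  Inference is Wald-type: hazard ratio
``exp(beta)`` with 95% limits ``exp(beta +- 1.959964*se)``.

The adverse group is always coded 1 in this package, so a hazard ratio
above one means the indicated group dies faster; an analysis coding the
reference group as 1 instead reports the reciprocal ratio, the same fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .containers import SurvivalTable
from .errors import SeparationError

__all__ = ["CoxPH", "CoxFit", "fit_cox", "km_estimate", "bh_adjust"]

_Z975 = 1.959964


@dataclass
class CoxFit:
    """Fitted Cox model summary (one row per covariate)."""

    names: list
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    ties: str
    n: int
    n_events: int
    dropped_samples: list = field(default_factory=list)

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def ci_low(self) -> np.ndarray:
        return np.exp(self.beta - _Z975 * self.se)

    @property
    def ci_high(self) -> np.ndarray:
        return np.exp(self.beta + _Z975 * self.se)

    @property
    def p(self) -> np.ndarray:
        z = np.abs(self.beta) / self.se
        return 2.0 * norm.sf(z)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.beta,
                "se": self.se,
                "hr": self.hr,
                "hr_ci_low": self.ci_low,
                "hr_ci_high": self.ci_high,
                "p": self.p,
            },
            index=self.names,
        )


def _cox_loglik_grad_hess(beta, X, time, event, ties):
    """Partial log-likelihood and derivatives.

    Samples sorted ascending in time; the risk set of an event time t is
    every sample with time >= t.
    """
    n, p = X.shape
    eta = X @ beta
    theta = np.exp(eta)
    tx = theta[:, None] * X
    txx = theta[:, None, None] * (X[:, :, None] * X[:, None, :])
    # reverse cumulative sums: entry i = sum over samples with index >= i
    S0 = np.cumsum(theta[::-1])[::-1]
    S1 = np.cumsum(tx[::-1], axis=0)[::-1]
    S2 = np.cumsum(txx[::-1], axis=0)[::-1]

    # per unique time: first index (= risk-set anchor) and event-group sums
    _, first = np.unique(time, return_index=True)
    d = np.add.reduceat(event.astype(float), first)
    etaD = np.add.reduceat(event * eta, first)
    XD = np.add.reduceat(event[:, None] * X, first, axis=0)

    ev = d > 0
    s0, s1, s2 = S0[first][ev], S1[first][ev], S2[first][ev]
    dm = d[ev]
    ll = float(etaD[ev].sum())
    grad = XD[ev].sum(axis=0)
    hess = np.zeros((p, p))
    simple = (dm == 1) if ties == "efron" else np.ones(dm.size, dtype=bool)
    if simple.any():
        ds, s0s, s1s, s2s = dm[simple], s0[simple], s1[simple], s2[simple]
        ll -= float((ds * np.log(s0s)).sum())
        grad -= (ds[:, None] * s1s / s0s[:, None]).sum(axis=0)
        hess -= np.einsum("j,jab->ab", ds, s2s / s0s[:, None, None])
        r = s1s / s0s[:, None]
        hess += np.einsum("j,ja,jb->ab", ds, r, r)
    if ties == "efron" and (~simple).any():
        # tied event groups: average over the d equally likely orderings
        anchors = np.nonzero(ev)[0][~simple]
        firsts_all = first
        for j, gi in zip(anchors, range(anchors.size)):
            i0 = firsts_all[j]
            i1 = firsts_all[j + 1] if j + 1 < firsts_all.size else n
            D = [k for k in range(i0, i1) if event[k]]
            dd = len(D)
            s0D = theta[D].sum()
            s1D = tx[D].sum(axis=0)
            s2D = txx[D].sum(axis=0)
            for l in range(dd):
                f = l / dd
                r0 = S0[i0] - f * s0D
                r1 = S1[i0] - f * s1D
                r2 = S2[i0] - f * s2D
                ll -= np.log(r0)
                grad -= r1 / r0
                hess -= r2 / r0 - np.outer(r1, r1) / r0**2
    return ll, grad, hess


class CoxPH:
    """Cox proportional-hazards regression (scikit-learn style).

    ``fit(X, time, event)`` maximizes the partial likelihood by
    Newton-Raphson with step halving.  Monotone likelihoods (perfect
    separation of events) raise :class:`SeparationError` instead of
    silently returning a diverged coefficient.

    Parameters
    ----------
    ties : "efron" (default, more accurate) or "breslow"
    gtol : gradient sup-norm at which Newton stops
    max_iter : Newton iteration cap
    allow_constant_columns : permit zero-variance design columns
        (their coefficients are unidentifiable; off by default)
    """

    def __init__(self, ties="efron", gtol=1e-9, max_iter=100,
                 allow_constant_columns=False):
        self.ties = ties
        self.gtol = gtol
        self.max_iter = max_iter
        self.allow_constant_columns = allow_constant_columns

    def get_params(self, deep=True):
        return {
            "ties": self.ties,
            "gtol": self.gtol,
            "max_iter": self.max_iter,
            "allow_constant_columns": self.allow_constant_columns,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, time, event):
        if self.ties not in ("efron", "breslow"):
            raise ValueError(f"unknown ties method {self.ties!r}")
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = np.atleast_2d(np.asarray(X, dtype=float))
            if X.shape[0] == 1 and np.asarray(time).shape[0] != 1:
                X = X.T
            names = [f"x{i}" for i in range(X.shape[1])]
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
        n, p = X.shape
        if event.sum() == 0:
            raise ValueError("no events: partial likelihood undefined")
        if not self.allow_constant_columns:
            const = [names[j] for j in range(p) if np.ptp(X[:, j]) == 0.0]
            if const:
                raise ValueError(f"constant design columns: {const}")

        order = np.argsort(time, kind="stable")
        Xs, ts, es = X[order], time[order], event[order]

        beta = np.zeros(p)
        ll, grad, hess = _cox_loglik_grad_hess(beta, Xs, ts, es, self.ties)
        ll_path = [ll]
        converged = False
        for _ in range(self.max_iter):
            if np.max(np.abs(grad)) < self.gtol:
                converged = True
                break
            try:
                step = np.linalg.solve(hess, -grad)
            except np.linalg.LinAlgError as exc:
                raise SeparationError(
                    f"singular information matrix at beta={beta}", beta=beta,
                    loglik_path=ll_path,
                ) from exc
            # step halving keeps the likelihood monotone
            scale = 1.0
            for _half in range(30):
                cand = beta + scale * step
                ll_new, grad_new, hess_new = _cox_loglik_grad_hess(
                    cand, Xs, ts, es, self.ties
                )
                if ll_new >= ll - 1e-12:
                    break
                scale *= 0.5
            beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
            ll_path.append(ll)
            if np.max(np.abs(beta)) > 15.0:
                raise SeparationError(
                    "monotone partial likelihood: coefficient diverging "
                    f"(|beta| > 15, beta={beta}); a covariate perfectly "
                    "separates the events",
                    beta=beta,
                    loglik_path=ll_path,
                )
        if not converged and np.max(np.abs(grad)) >= self.gtol:
            raise SeparationError(
                f"Newton-Raphson did not converge in {self.max_iter} "
                f"iterations (|grad|={np.max(np.abs(grad)):.2e})",
                beta=beta,
                loglik_path=ll_path,
            )
        info = -hess
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))

        self.names_ = names
        self.coef_ = beta
        self.se_ = se
        self.cov_ = cov
        self.loglik_ = float(ll)
        self.n_ = n
        self.n_events_ = int(event.sum())
        self.result_ = CoxFit(
            names=names, beta=beta, se=se, loglik=float(ll),
            ties=self.ties, n=n, n_events=int(event.sum()),
        )
        return self

    @property
    def hazard_ratios_(self):
        return np.exp(self.coef_)

    def summary(self) -> pd.DataFrame:
        return self.result_.summary()


def fit_cox(surv, design, ties="efron") -> CoxFit:
    """Cox regression of a survival table on a design matrix.

    ``surv`` is a :class:`SurvivalTable` (or DataFrame with ``time`` and
    ``event`` columns); ``design`` an (n, p) matrix or DataFrame aligned
    with it row-wise.
    """
    if isinstance(surv, SurvivalTable):
        time, event = surv.time, surv.event
    else:
        time = np.asarray(surv["time"], dtype=float)
        event = np.asarray(surv["event"], dtype=int)
    model = CoxPH(ties=ties).fit(design, time, event)
    return model.result_


def km_estimate(surv, groups=None):
    """Kaplan-Meier product-limit curves, one per group.

    Returns ``{group_label: DataFrame(time, n_risk, n_events, n_censored,
    survival)}`` with one row per distinct observed time.  ``S(0) = 1`` and
    the curve is non-increasing.
    """
    if isinstance(surv, SurvivalTable):
        time, event = surv.time, surv.event
    else:
        time = np.asarray(surv["time"], dtype=float)
        event = np.asarray(surv["event"], dtype=int)
    n = time.shape[0]
    if groups is None:
        groups = np.zeros(n, dtype=int)
    groups = np.asarray(groups)
    if groups.shape[0] != n:
        raise ValueError("groups length does not match survival table")
    out = {}
    for g in pd.unique(groups):
        mask = groups == g
        if not mask.any():
            raise ValueError(f"empty group {g!r}")
        t, e = time[mask], event[mask]
        order = np.argsort(t, kind="stable")
        t, e = t[order], e[order]
        uniq = np.unique(t)
        rows = []
        surv_prob = 1.0
        for u in uniq:
            at = t == u
            n_risk = int((t >= u).sum())
            d = int(e[at].sum())
            c = int((~e[at].astype(bool)).sum())
            if d:
                surv_prob *= 1.0 - d / n_risk
            rows.append((u, n_risk, d, c, surv_prob))
        out[g] = pd.DataFrame(
            rows, columns=["time", "n_risk", "n_events", "n_censored", "survival"]
        )
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    ``q_(i) = min_{j >= i} m * p_(j) / j`` on the sorted p-values, capped
    at 1; monotone in p.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
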