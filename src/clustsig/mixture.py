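"""Gaussian mixtures under geometric (spherical/diagonal) covariance constraints.

The covariance of component k is written ``Sigma_k = lambda_k * A_k`` with
``lambda_k > 0`` the *volume* and ``A_k`` a diagonal *shape* matrix of
determinant 1.  Families are named by whether volume and shape are Equal
across components, Varying, or the Identity:

====== =========================== ==========================
code   covariance                  free covariance parameters
====== =========================== ==========================
E      shared variance (d=1)       1
V      per-component variance      K
EII    lambda * I                  1
VII    lambda_k * I                K
EEI    lambda * A                  d
VEI    lambda_k * A                K + d - 1
EVI    lambda * A_k                1 + K(d-1)
VVI    lambda_k * A_k              K d
====== =========================== ==========================

BIC follows the model-based-clustering convention ``2*loglik - m*log(n)``
and is MAXIMIZED.  (Much of the wider statistics literature uses the
opposite sign and minimizes; callers comparing against other software
should check the sign first.)

Fitting is plain EM.  The default initialization is deterministic:
the optimal contiguous split of the sorted values for univariate data,
Ward agglomeration for multivariate data, so repeated runs agree without
seeding.  Seeded random restarts are used when a fit collapses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.special import expit, logsumexp

from .errors import DegenerateDataError, FitFailedError

__all__ = [
    "ConstrainedGaussianMixture",
    "ClusterAssignment",
    "UNIVARIATE_FAMILIES",
    "MULTIVARIATE_FAMILIES",
    "fit_mixture",
    "select_model",
    "predict_mixture",
    "bic",
]

UNIVARIATE_FAMILIES = ("E", "V")
MULTIVARIATE_FAMILIES = ("EII", "VII", "EEI", "VEI", "EVI", "VVI")

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class ClusterAssignment:
    """Posterior component memberships for a set of samples.

    Attributes
    ----------
    responsibilities : (n, K) array
        Posterior probability of each component given each sample; rows
        sum to one.
    labels : (n,) int array
        Argmax component per sample.
    uncertainty : (n,) array
        ``1 - max_k responsibility`` per sample.
    """

    responsibilities: np.ndarray
    labels: np.ndarray
    uncertainty: np.ndarray

    @classmethod
    def from_responsibilities(cls, z: np.ndarray) -> "ClusterAssignment":
        z = np.asarray(z, dtype=float)
        return cls(
            responsibilities=z,
            labels=np.argmax(z, axis=1),
            uncertainty=1.0 - np.max(z, axis=1),
        )

    def __len__(self) -> int:
        return self.responsibilities.shape[0]


def _n_cov_params(family: str, K: int, d: int) -> int:
    return {
        "E": 1,
        "V": K,
        "EII": 1,
        "VII": K,
        "EEI": d,
        "VEI": K + d - 1,
        "EVI": 1 + K * (d - 1),
        "VVI": K * d,
    }[family]


def n_mixture_params(family: str, K: int, d: int) -> int:
    """Free-parameter count: (K-1) weights + K*d means + covariance terms."""
    return (K - 1) + K * d + _n_cov_params(family, K, d)


def _geometric_mean(v: np.ndarray, axis=None) -> np.ndarray:
    return np.exp(np.mean(np.log(v), axis=axis))


def _covariances_from_scatter(W, nk, n, d, family):
    """M-step covariance update from diagonal scatter matrices.

    Parameters
    ----------
    W : (K, d) array
        Responsibility-weighted scatter diag(sum_i z_ik (x_i-mu_k)(x_i-mu_k)').
    nk : (K,) array
        Effective component counts.

    Returns
    -------
    volumes : (K,) array (shared families hold identical entries)
    shapes : (K, d) array, each row has product 1
    cov : (K, d) array, diagonal covariances ``volumes[:, None] * shapes``
    """
    K = W.shape[0]
    W = np.maximum(W, 1e-300)  # keep log/ratio updates finite on exact-zero scatter
    if family in ("E", "EEI"):
        diag = W.sum(axis=0) / n
        lam = _geometric_mean(diag)
        A = diag / lam
        volumes = np.full(K, lam)
        shapes = np.tile(A, (K, 1))
    elif family in ("V", "VVI"):
        cov = W / nk[:, None]
        volumes = _geometric_mean(cov, axis=1)
        shapes = cov / volumes[:, None]
    elif family == "EII":
        lam = W.sum() / (n * d)
        volumes = np.full(K, lam)
        shapes = np.ones((K, d))
    elif family == "VII":
        volumes = W.sum(axis=1) / (nk * d)
        shapes = np.ones((K, d))
    elif family == "EVI":
        ck = _geometric_mean(W, axis=1)
        shapes = W / ck[:, None]
        lam = ck.sum() / n
        volumes = np.full(K, lam)
    elif family == "VEI":
        # No joint closed form: alternate the volume and shape updates.
        A = W.sum(axis=0)
        A = A / _geometric_mean(A)
        volumes = np.ones(K)
        for _ in range(100):
            volumes_new = (W / A).sum(axis=1) / (d * nk)
            pooled = (W / volumes_new[:, None]).sum(axis=0)
            A_new = pooled / _geometric_mean(pooled)
            delta = max(
                np.max(np.abs(volumes_new - volumes) / np.maximum(volumes_new, 1e-300)),
                np.max(np.abs(A_new - A) / np.maximum(A_new, 1e-300)),
            )
            volumes, A = volumes_new, A_new
            if delta < 1e-8:
                break
        shapes = np.tile(A, (K, 1))
    else:
        raise ValueError(f"unknown family {family!r}")
    cov = volumes[:, None] * shapes
    return volumes, shapes, cov


def _log_gaussian_diag(X, means, cov):
    """(n, K) log density of diagonal Gaussians."""
    # X (n,d), means (K,d), cov (K,d)
    diff2 = (X[:, None, :] - means[None, :, :]) ** 2  # (n,K,d)
    return -0.5 * np.sum(diff2 / cov[None] + np.log(cov)[None] + _LOG2PI, axis=2)


class _EMFailure(Exception):
    def __init__(self, reason):
        self.reason = reason


def _aitken_converged(history, tol):
    """Aitken-accelerated stopping rule on the log-likelihood sequence.

    EM often converges linearly at a rate close to 1 (a near-flat ridge,
    typical when components overlap), where the raw increment criterion
    stalls for thousands of iterations.  Aitken extrapolation estimates
    the limit of a linearly converging sequence from three consecutive
    values; we stop once successive limit estimates agree to ``tol``
    (relative), the criterion model-based-clustering software uses.
    """
    if len(history) < 4:
        return False
    l0, l1, l2, l3 = history[-4:]
    d1, d2, d3 = l1 - l0, l2 - l1, l3 - l2
    if d1 <= 0 or d2 <= 0 or d3 <= 0:
        return True  # numerically stationary
    a_prev, a_curr = d2 / d1, d3 / d2
    if a_prev >= 1.0 or a_curr >= 1.0:
        return False
    linf_prev = l2 + d2 / (1.0 - a_prev)
    linf_curr = l3 + d3 / (1.0 - a_curr)
    return abs(linf_curr - linf_prev) < tol * max(1.0, abs(l3))


def _em_single(X, K, family, z0, tol, max_iter, var_floor):
    """Run EM from responsibilities z0.  Returns a parameter dict.

    Raises ``_EMFailure`` on component collapse or a variance-floor hit.
    """
    n, d = X.shape
    z = z0
    prev_ll = -np.inf
    history = []
    converged = False
    floor_hit = False
    collapsed = False
    params = None
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        nk = z.sum(axis=0)
        if np.any(nk < 1.0):
            # a component died: the trajectory up to here is still a valid
            # (monotone) likelihood ascent, so keep the last parameters
            if params is None:
                raise _EMFailure("component collapse (weighted count < 1)")
            collapsed = True
            break
        weights = nk / n
        means = (z.T @ X) / nk[:, None]
        diff2 = (X[:, None, :] - means[None, :, :]) ** 2
        W = np.einsum("nk,nkd->kd", z, diff2)
        volumes, shapes, cov = _covariances_from_scatter(W, nk, n, d, family)
        if np.any(cov < var_floor[None, :]):
            # clamp rather than abort: perfectly separated clusters drive a
            # within-component variance to zero and the likelihood to +inf;
            # the floor caps it at a finite, comparable value
            floor_hit = True
            cov = np.maximum(cov, var_floor[None, :])
            volumes = _geometric_mean(cov, axis=1)
            shapes = cov / volumes[:, None]
        logdens = _log_gaussian_diag(X, means, cov) + np.log(weights)[None, :]
        ll_i = logsumexp(logdens, axis=1)
        ll = float(ll_i.sum())
        z = np.exp(logdens - ll_i[:, None])
        history.append(ll)
        params = dict(
            weights=weights,
            means=means,
            volumes=volumes,
            shapes=shapes,
            covariances=cov,
            loglik=ll,
            responsibilities=z,
        )
        if np.isfinite(prev_ll) and (
            ll - prev_ll <= tol * max(1.0, abs(ll))
            or _aitken_converged(history, tol)
        ):
            converged = True
            break
        prev_ll = ll
    params.update(
        n_iter=n_iter,
        converged=converged,
        collapsed=collapsed,
        floor_hit=floor_hit,
        history=np.asarray(history),
    )
    return params


def _init_split_1d(x: np.ndarray, K: int) -> np.ndarray:
    """Deterministic univariate init: the contiguous K-split of the sorted
    values minimizing total within-group sum of squares (K=2 exact scan;
    K>2 falls back to quantile cuts)."""
    n = x.shape[0]
    order = np.argsort(x, kind="stable")
    xs = x[order]
    if K == 2:
        c1 = np.cumsum(xs)
        c2 = np.cumsum(xs**2)
        idx = np.arange(1, n)  # left group size
        ssl = c2[:-1] - c1[:-1] ** 2 / idx
        nr = n - idx
        sr1 = c1[-1] - c1[:-1]
        sr2 = c2[-1] - c2[:-1]
        ssr = sr2 - sr1**2 / nr
        split = int(np.argmin(ssl + ssr)) + 1
        labels_sorted = (np.arange(n) >= split).astype(int)
    else:
        cuts = np.linspace(0, n, K + 1).astype(int)
        labels_sorted = np.zeros(n, dtype=int)
        for k in range(K):
            labels_sorted[cuts[k] : cuts[k + 1]] = k
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels


def _best_partition_init(x: np.ndarray, family: str, floor: float) -> np.ndarray:
    """Exhaustive two-part partition init for tiny univariate samples (K=2).

    Scores every split of the points into two groups by the mixture
    log-likelihood of its hard-assignment parameters and returns the best
    labeling; EM's monotone ascent from here can only improve on it.
    With per-group variances the optimum need not be contiguous in sorted
    order, so all 2^(n-1)-1 subsets are scored (n is at most 12 here).
    """
    n = x.size
    best_ll, best_labels = -np.inf, None
    for code in range(1, 1 << (n - 1)):  # point 0 fixed to group 0
        inside = np.array([(code >> i) & 1 for i in range(n)], dtype=bool)
        g1, g0 = x[inside], x[~inside]
        mu = np.array([g0.mean(), g1.mean()])
        w = np.array([g0.size / n, g1.size / n])
        if family == "E":
            v = max((((g0 - mu[0]) ** 2).sum()
                     + ((g1 - mu[1]) ** 2).sum()) / n, floor)
            v = np.array([v, v])
        else:
            if min(g0.size, g1.size) < 2:
                continue  # singleton variance is degenerate for V
            v = np.maximum(
                [((g0 - mu[0]) ** 2).mean(), ((g1 - mu[1]) ** 2).mean()],
                floor,
            )
        logdens = (
            -0.5 * ((x[:, None] - mu[None, :]) ** 2 / v[None, :]
                    + np.log(v)[None, :] + _LOG2PI)
            + np.log(w)[None, :]
        )
        ll = float(logsumexp(logdens, axis=1).sum())
        if ll > best_ll:
            best_ll, best_labels = ll, inside.astype(int)
    if best_labels is None:  # e.g. n=3 under V's two-per-group requirement
        return _init_split_1d(x, 2)
    return best_labels


def _init_ward(X: np.ndarray, K: int) -> np.ndarray:
    Z = linkage(X, method="ward")
    return fcluster(Z, t=K, criterion="maxclust") - 1


def _labels_to_resp(labels: np.ndarray, K: int) -> np.ndarray:
    z = np.zeros((labels.shape[0], K))
    z[np.arange(labels.shape[0]), labels] = 1.0
    return z


def _random_resp(X: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    n, d = X.shape
    if d == 1 and K == 2:
        # univariate: likelihood-relevant hard partitions are intervals of
        # the sorted values (a tight cluster can sit in the middle), so
        # restarts draw a random interval vs. its complement
        a, b = np.sort(rng.choice(n + 1, size=2, replace=False))
        if a == 0 and b == n:
            a = int(rng.integers(1, n))
        ranks = np.argsort(np.argsort(X[:, 0], kind="stable"), kind="stable")
        return _labels_to_resp(((ranks >= a) & (ranks < b)).astype(int), K)
    centers = X[rng.choice(n, size=K, replace=False)]
    dist = np.linalg.norm(X[:, None, :] - centers[None], axis=2)
    return _labels_to_resp(np.argmin(dist, axis=1), K)


class ConstrainedGaussianMixture:
    """K-component Gaussian mixture with a constrained diagonal covariance.

    scikit-learn style estimator: ``fit(X)`` runs EM, ``predict`` /
    ``predict_proba`` score new samples against the frozen parameters.

    Parameters
    ----------
    n_components : int
        Number of mixture components (K).
    family : str or sequence of str
        Covariance family code, or several codes, in which case each is
        fitted and the one with the highest BIC is kept (ties go to the
        family with fewer parameters).  ``"auto"`` tries every family
        valid for the data dimension.
    tol : float
        Relative log-likelihood convergence tolerance.
    max_iter : int
        EM iteration cap.
    n_restarts : int
        Seeded random restarts attempted after the deterministic
        initialization fails (component collapse or variance floor).
    var_floor_frac : float
        Any fitted variance below ``var_floor_frac * var(column)`` aborts
        the run; guards against likelihood blow-up on near-degenerate data.
    init : "deterministic" or "random"
        Deterministic = sorted-split (d=1) / Ward agglomeration (d>1).
    random_state : int or None
        Seed for the restart stream.

    Attributes (after ``fit``)
    --------------------------
    weights_, means_, volumes_, shapes_, covariances_ : arrays
        ``covariances_[k] = volumes_[k] * shapes_[k]`` (diagonals).
    loglik_, bic_, n_params_, n_iter_, converged_ : fit summary
    family_ : the family actually kept
    bic_table_ : dict family -> BIC (or error string) when selecting
    responsibilities_ : training-data posteriors
    loglik_path_ : per-iteration log-likelihood (monotone non-decreasing)
    """

    def __init__(
        self,
        n_components: int = 2,
        family="VVI",
        tol: float = 1e-8,
        max_iter: int = 500,
        n_restarts: int = 10,
        var_floor_frac: float = 1e-8,
        init: str = "deterministic",
        random_state=None,
    ):
        self.n_components = n_components
        self.family = family
        self.tol = tol
        self.max_iter = max_iter
        self.n_restarts = n_restarts
        self.var_floor_frac = var_floor_frac
        self.init = init
        self.random_state = random_state

    # -- sklearn plumbing -------------------------------------------------
    def get_params(self, deep=True):
        return {
            k: getattr(self, k)
            for k in (
                "n_components",
                "family",
                "tol",
                "max_iter",
                "n_restarts",
                "var_floor_frac",
                "init",
                "random_state",
            )
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- fitting ----------------------------------------------------------
    def _candidate_families(self, d: int):
        fam = self.family
        if isinstance(fam, str) and fam != "auto":
            fams = (fam,)
        elif fam == "auto":
            fams = UNIVARIATE_FAMILIES if d == 1 else MULTIVARIATE_FAMILIES
        else:
            fams = tuple(fam)
        valid = UNIVARIATE_FAMILIES if d == 1 else MULTIVARIATE_FAMILIES
        for f in fams:
            if f not in valid:
                raise ValueError(
                    f"family {f!r} is not valid for d={d}; choose from {valid}"
                )
        if len(fams) == 0:
            raise ValueError("empty family list")
        return fams

    @staticmethod
    def _as_matrix(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.ndim != 2:
            raise ValueError("X must be 1- or 2-dimensional")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        return X

    def fit(self, X, y=None):
        X = self._as_matrix(X)
        n, d = X.shape
        K = self.n_components
        if n <= K:
            raise ValueError(f"need more samples ({n}) than components ({K})")
        col_var = X.var(axis=0)
        if np.any(col_var == 0.0):
            raise DegenerateDataError("degenerate input: zero-variance column")
        var_floor = self.var_floor_frac * col_var
        fams = self._candidate_families(d)

        results = {}
        table = {}
        for fam in fams:
            try:
                res = self._fit_one_family(X, K, fam, var_floor)
            except (FitFailedError, _EMFailure) as exc:
                table[fam] = f"failed: {exc}"
                continue
            res["bic"] = 2.0 * res["loglik"] - n_mixture_params(fam, K, d) * np.log(n)
            results[fam] = res
            table[fam] = res["bic"]
        if not results:
            raise FitFailedError(
                "all candidate families failed", diagnostics=table
            )
        # highest BIC; ties to fewer parameters (stable because dicts keep
        # insertion order and we sort on (-bic, n_params))
        best_fam = min(
            results,
            key=lambda f: (-results[f]["bic"], n_mixture_params(f, K, d)),
        )
        best = results[best_fam]

        self.family_ = best_fam
        self.n_ = n
        self.d_ = d
        self.weights_ = best["weights"]
        self.means_ = best["means"]
        self.volumes_ = best["volumes"]
        self.shapes_ = best["shapes"]
        self.covariances_ = best["covariances"]
        self.loglik_ = best["loglik"]
        self.n_params_ = n_mixture_params(best_fam, K, d)
        self.bic_ = best["bic"]
        self.n_iter_ = best["n_iter"]
        self.converged_ = best["converged"]
        self.collapsed_ = best["collapsed"]
        self.floor_hit_ = best["floor_hit"]
        self.responsibilities_ = best["responsibilities"]
        self.loglik_path_ = best["history"]
        self.bic_table_ = table
        return self

    def _fit_one_family(self, X, K, family, var_floor):
        n, d = X.shape
        if K == 1:
            # closed form: weights 1, mean = sample mean, family-projected
            # covariance of the full sample
            means = X.mean(axis=0, keepdims=True)
            W = ((X - means) ** 2).sum(axis=0, keepdims=True)
            volumes, shapes, cov = _covariances_from_scatter(
                W, np.array([float(n)]), n, d, family
            )
            ll = float(_log_gaussian_diag(X, means, cov).sum())
            return dict(
                weights=np.array([1.0]),
                means=means,
                volumes=volumes,
                shapes=shapes,
                covariances=cov,
                loglik=ll,
                responsibilities=np.ones((n, 1)),
                n_iter=0,
                converged=True,
                collapsed=False,
                floor_hit=False,
                history=np.array([ll]),
            )

        rng = np.random.default_rng(self.random_state)
        attempts = []
        best_collapsed = None
        if self.init == "deterministic":
            # one deterministic run; seeded random restarts only as fallback
            if d == 1 and K == 2 and n <= 12:
                labels = _best_partition_init(
                    X[:, 0], family if family in ("E", "V") else "V",
                    float(var_floor[0]))
            elif d == 1:
                labels = _init_split_1d(X[:, 0], K)
            else:
                labels = _init_ward(X, K)
            starts = [_labels_to_resp(labels, K)] + [
                _random_resp(X, K, rng) for _ in range(self.n_restarts)
            ]
            for z0 in starts:
                try:
                    res = _em_single(
                        X, K, family, z0, self.tol, self.max_iter, var_floor)
                except _EMFailure as exc:
                    attempts.append(exc.reason)
                    continue
                if not res["collapsed"]:
                    # a collapsed earlier run may still hold the higher
                    # likelihood; never trade likelihood away for cleanliness
                    if (best_collapsed is not None
                            and best_collapsed["loglik"] > res["loglik"]):
                        return best_collapsed
                    return res
                attempts.append("component collapse")
                if (best_collapsed is None
                        or res["loglik"] > best_collapsed["loglik"]):
                    best_collapsed = res
        elif self.init == "random":
            # multi-start: run every seeded restart, keep the best likelihood
            best = None
            for _ in range(max(1, self.n_restarts)):
                try:
                    res = _em_single(
                        X, K, family, _random_resp(X, K, rng),
                        self.tol, self.max_iter, var_floor)
                except _EMFailure as exc:
                    attempts.append(exc.reason)
                    continue
                if res["collapsed"]:
                    if (best_collapsed is None
                            or res["loglik"] > best_collapsed["loglik"]):
                        best_collapsed = res
                    continue
                if best is None or res["loglik"] > best["loglik"]:
                    best = res
            if best is not None:
                return best
        else:
            raise ValueError(f"unknown init strategy {self.init!r}")
        if best_collapsed is not None:
            # every start collapsed: report the best ascent reached instead
            # of refusing outright; callers can inspect `collapsed`
            return best_collapsed
        raise FitFailedError(
            f"EM failed for family {family} after {len(attempts)} starts",
            diagnostics={"family": family, "reasons": attempts},
        )

    # -- prediction -------------------------------------------------------
    def _check_fitted(self):
        if not hasattr(self, "means_"):
            raise RuntimeError("model is not fitted")

    def score_samples(self, X) -> np.ndarray:
        """Per-sample log density under the fitted mixture."""
        self._check_fitted()
        X = self._as_matrix(X)
        if X.shape[1] != self.d_:
            raise ValueError(
                f"dimension mismatch: model has d={self.d_}, data has d={X.shape[1]}"
            )
        logdens = _log_gaussian_diag(X, self.means_, self.covariances_)
        return logsumexp(logdens + np.log(self.weights_)[None, :], axis=1)

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        X = self._as_matrix(X)
        if X.shape[1] != self.d_:
            raise ValueError(
                f"dimension mismatch: model has d={self.d_}, data has d={X.shape[1]}"
            )
        logdens = _log_gaussian_diag(X, self.means_, self.covariances_) + np.log(
            self.weights_
        )
        return np.exp(logdens - logsumexp(logdens, axis=1)[:, None])

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)

    def assign(self, X) -> ClusterAssignment:
        """Full posterior assignment (responsibilities, labels, uncertainty)."""
        return ClusterAssignment.from_responsibilities(self.predict_proba(X))

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "family": self.family_,
            "n_components": int(self.n_components),
            "d": int(self.d_),
            "n": int(self.n_),
            "weights": self.weights_.tolist(),
            "means": self.means_.tolist(),
            "volumes": self.volumes_.tolist(),
            "shapes": self.shapes_.tolist(),
            "loglik": float(self.loglik_),
            "n_params": int(self.n_params_),
            "bic": float(self.bic_),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ConstrainedGaussianMixture":
        model = cls(n_components=payload["n_components"], family=payload["family"])
        model.family_ = payload["family"]
        model.d_ = payload["d"]
        model.n_ = payload["n"]
        model.weights_ = np.asarray(payload["weights"], dtype=float)
        model.means_ = np.asarray(payload["means"], dtype=float)
        model.volumes_ = np.asarray(payload["volumes"], dtype=float)
        model.shapes_ = np.asarray(payload["shapes"], dtype=float)
        model.covariances_ = model.volumes_[:, None] * model.shapes_
        model.loglik_ = payload["loglik"]
        model.n_params_ = payload["n_params"]
        model.bic_ = payload["bic"]
        return model

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load_json(cls, path) -> "ConstrainedGaussianMixture":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# batched univariate EM: the per-gene screen fits thousands of independent
# one-dimensional two-component mixtures; doing them all at once in a single
# array program is orders of magnitude faster than a python loop.
# ---------------------------------------------------------------------------

def _batch_split_init(X: np.ndarray) -> np.ndarray:
    """Vectorized K=2 sorted-split init for rows of X (B, n) -> z0 (B, n, 2)."""
    B, n = X.shape
    Xs = np.sort(X, axis=1)
    c1 = np.cumsum(Xs, axis=1)
    c2 = np.cumsum(Xs**2, axis=1)
    sizes = np.arange(1, n)[None, :]
    ssl = c2[:, :-1] - c1[:, :-1] ** 2 / sizes
    nr = n - sizes
    sr1 = c1[:, -1:] - c1[:, :-1]
    sr2 = c2[:, -1:] - c2[:, :-1]
    ssr = sr2 - sr1**2 / nr
    split = np.argmin(ssl + ssr, axis=1) + 1  # left-group size per row
    # label by rank so ties at the cut value still split deterministically
    ranks = np.argsort(np.argsort(X, kind="stable", axis=1), axis=1)
    labels = (ranks >= split[:, None]).astype(int)
    z0 = np.zeros((B, n, 2))
    np.put_along_axis(z0, labels[:, :, None], 1.0, axis=2)
    return z0


def em_univariate_batch(
    X: np.ndarray,
    family: str,
    tol: float = 1e-8,
    max_iter: int = 500,
    var_floor_frac: float = 1e-8,
    z0: np.ndarray | None = None,
):
    """Fit independent univariate K=2 mixtures to every row of X.

    Parameters
    ----------
    X : (B, n) array
        Each row is one dataset (one gene's expression across samples).
    family : "E" (shared variance) or "V" (per-component variance)

    Returns
    -------
    dict with per-row arrays: weights (B,2), means (B,2), variances (B,2),
    loglik (B,), bic (B,), responsibilities (B,n,2), labels (B,n),
    converged (B,), failed (B,)
    """
    if family not in UNIVARIATE_FAMILIES:
        raise ValueError(f"family must be E or V, got {family!r}")
    X = np.asarray(X, dtype=float)
    B, n = X.shape
    if z0 is None:
        z0 = _batch_split_init(X)
    var_floor = var_floor_frac * X.var(axis=1)  # (B,)

    weights = np.full((B, 2), np.nan)
    means = np.full((B, 2), np.nan)
    var = np.full((B, 2), np.nan)
    ll = np.full(B, np.nan)
    resp1 = np.ascontiguousarray(z0[:, :, 1], dtype=float)
    converged = np.zeros(B, dtype=bool)
    failed = var_floor <= 0.0  # zero-variance rows never fit

    # K=2 lets the whole EM run on (rows, n) arrays: z0 = 1 - z1, and the
    # M-step only needs the sufficient statistics sum(z1*x), sum(z1*x^2).
    # Rows are centered so those sums do not cancel catastrophically.
    # Active-set compaction: rows leave the working arrays as soon as they
    # converge or fail, so late stragglers do not make every row pay.
    idx = np.nonzero(~failed)[0]
    center = X.mean(axis=1)
    Xa = X[idx] - center[idx, None]
    Xa2 = Xa**2
    sx = Xa.sum(axis=1)
    qx = Xa2.sum(axis=1)
    z1 = resp1[idx].copy()
    fa = var_floor[idx]
    hist = np.full((4, idx.size), -np.inf)  # rolling loglik history (Aitken)
    last = None  # (w1, mu0, mu1, v0, v1, ll) of the surviving active rows

    def _store(rows, w1, mu0, mu1, v0, v1, l, z):
        weights[rows, 0], weights[rows, 1] = 1.0 - w1, w1
        means[rows, 0] = mu0 + center[rows]
        means[rows, 1] = mu1 + center[rows]
        var[rows, 0], var[rows, 1] = v0, v1
        ll[rows] = l
        resp1[rows] = z

    for _ in range(max_iter):
        if idx.size == 0:
            break
        nk1 = z1.sum(axis=1)
        nk0 = n - nk1
        bad = (nk1 < 1.0) | (nk0 < 1.0)
        if bad.any():
            failed[idx[bad]] = True
            keep = ~bad
            idx, Xa, Xa2, sx, qx, z1, fa, hist = (
                idx[keep], Xa[keep], Xa2[keep], sx[keep], qx[keep],
                z1[keep], fa[keep], hist[:, keep])
            if idx.size == 0:
                break
            nk1, nk0 = nk1[keep], nk0[keep]
        s1 = np.einsum("bn,bn->b", z1, Xa)
        q1 = np.einsum("bn,bn->b", z1, Xa2)
        mu1 = s1 / nk1
        mu0 = (sx - s1) / nk0
        W1 = q1 - s1 * mu1
        W0 = (qx - q1) - (sx - s1) * mu0
        # clamp at the floor (see _em_single): caps the unbounded
        # likelihood of an exactly-fitted component
        if family == "E":
            v0 = v1 = np.maximum((W0 + W1) / n, fa)
        else:
            v0 = np.maximum(W0 / nk0, fa)
            v1 = np.maximum(W1 / nk1, fa)
        w1 = nk1 / n
        a0 = Xa - mu0[:, None]
        a0 = -0.5 * (a0 * a0 / v0[:, None]) - (
            0.5 * (np.log(v0) + _LOG2PI) - np.log(1.0 - w1))[:, None]
        diff = Xa - mu1[:, None]
        diff = -0.5 * (diff * diff / v1[:, None]) - (
            0.5 * (np.log(v1) + _LOG2PI) - np.log(w1))[:, None]
        diff -= a0
        ll_new = (a0 + np.logaddexp(0.0, diff)).sum(axis=1)
        z1 = expit(diff)

        # convergence: raw increment below tol, or Aitken limit stabilized
        prev = hist[3]
        inc = ll_new - prev
        scale = np.maximum(1.0, np.abs(ll_new))
        done = np.isfinite(prev) & (inc <= tol * scale)
        with np.errstate(divide="ignore", invalid="ignore"):
            d1, d2, d3 = hist[1] - hist[0], hist[2] - hist[1], ll_new - hist[2]
            pos = (d1 > 0) & (d2 > 0) & (d3 > 0)
            a_prev, a_curr = d2 / d1, d3 / d2
            usable = pos & (a_prev < 1.0) & (a_curr < 1.0)
            linf_prev = hist[2] + d2 / (1.0 - a_prev)
            linf_curr = ll_new + d3 / (1.0 - a_curr)
            aitken = usable & (np.abs(linf_curr - linf_prev) < tol * scale)
            stationary = np.isfinite(hist).all(axis=0) & ~pos
        done |= aitken | stationary
        hist = np.vstack([hist[1:], ll_new])
        if done.any():
            rows = idx[done]
            converged[rows] = True
            _store(rows, w1[done], mu0[done], mu1[done], v0[done], v1[done],
                   ll_new[done], z1[done])
            keep = ~done
            idx, Xa, Xa2, sx, qx, z1, fa, hist = (
                idx[keep], Xa[keep], Xa2[keep], sx[keep], qx[keep],
                z1[keep], fa[keep], hist[:, keep])
            last = (w1[keep], mu0[keep], mu1[keep], v0[keep], v1[keep],
                    ll_new[keep])
        else:
            last = (w1, mu0, mu1, v0, v1, ll_new)
    # rows exhausting max_iter: record their last state, not converged
    if idx.size and last is not None:
        _store(idx, *last, z1)

    m = n_mixture_params(family, 2, 1)
    with np.errstate(invalid="ignore"):
        bic_vals = 2.0 * ll - m * np.log(n)
    labels = (resp1 > 0.5).astype(int)
    resp = np.stack([1.0 - resp1, resp1], axis=2)
    for arr in (weights, means, var, ll, bic_vals):
        arr[failed] = np.nan
    return dict(
        weights=weights,
        means=means,
        variances=var,
        loglik=ll,
        bic=bic_vals,
        responsibilities=resp,
        labels=labels,
        converged=converged,
        failed=failed,
        n_params=m,
    )


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def fit_mixture(
    data,
    K: int = 2,
    family: str = "VVI",
    init: str = "deterministic",
    seed=None,
    tol: float = 1e-8,
    max_iter: int = 500,
    n_restarts: int = 10,
):
    """Fit a K-component constrained mixture; returns (model, assignment)."""
    model = ConstrainedGaussianMixture(
        n_components=K,
        family=family,
        tol=tol,
        max_iter=max_iter,
        n_restarts=n_restarts,
        init=init,
        random_state=seed,
    ).fit(data)
    return model, ClusterAssignment.from_responsibilities(model.responsibilities_)


def bic(model: ConstrainedGaussianMixture) -> float:
    """``2*loglik - m*log(n)`` (maximized)."""
    model._check_fitted()
    return 2.0 * model.loglik_ - model.n_params_ * np.log(model.n_)


def select_model(data, K: int = 2, families=None, seed=None, **kwargs):
    """Fit every candidate family, keep the best BIC.

    Returns ``(model, assignment, bic_table)`` where ``bic_table`` maps each
    family to its BIC (or an error message for failed fits).
    """
    if families is None:
        families = "auto"
    model = ConstrainedGaussianMixture(
        n_components=K, family=families, random_state=seed, **kwargs
    ).fit(data)
    return (
        model,
        ClusterAssignment.from_responsibilities(model.responsibilities_),
        model.bic_table_,
    )


def predict_mixture(model: ConstrainedGaussianMixture, newdata) -> ClusterAssignment:
    """Posterior responsibilities of new samples under a frozen model."""
    return model.assign(newdata)
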