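"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's EM / Newton code paths: the
mixture oracle enumerates hard partitions and evaluates the mixture
log-likelihood directly; the Cox oracle maximizes the partial likelihood
by grid search.
"""

from itertools import combinations

import numpy as np

_LOG2PI = np.log(2.0 * np.pi)


def gaussian_mixture_loglik(x, weights, means, variances):
    """Observed-data log-likelihood of a univariate Gaussian mixture."""
    x = np.asarray(x, dtype=float)[:, None]
    logdens = (
        -0.5 * ((x - means[None, :]) ** 2 / variances[None, :]
                + np.log(variances[None, :]) + _LOG2PI)
        + np.log(weights)[None, :]
    )
    m = logdens.max(axis=1)
    return float((m + np.log(np.exp(logdens - m[:, None]).sum(axis=1))).sum())


def best_partition_loglik(x, family, var_floor_frac=1e-8):
    """Exhaustive two-part partition oracle for univariate K=2 mixtures.

    For every split of the points into two non-empty groups, estimate the
    hard-assignment parameters under the family constraint (shared
    variance for E, per-group for V, clamped below at the same relative
    floor the EM uses), evaluate the *mixture* log-likelihood at those
    parameters, and return the maximum.  Any EM solution should match or
    beat this bound.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    floor = var_floor_frac * x.var()
    best = -np.inf
    idx = np.arange(n)
    # V: singleton groups have an unbounded (variance -> 0) likelihood and
    # are not admissible clusterings; demand two points per group
    min_size = 2 if family == "V" else 1
    for size in range(min_size, n // 2 + 1):
        for group in combinations(idx, size):
            mask = np.zeros(n, dtype=bool)
            mask[list(group)] = True
            m1, m0 = x[mask], x[~mask]
            mu = np.array([m0.mean(), m1.mean()])
            w = np.array([m0.size / n, m1.size / n])
            if family == "E":
                v_shared = (((m0 - mu[0]) ** 2).sum()
                            + ((m1 - mu[1]) ** 2).sum()) / n
                v = np.full(2, max(v_shared, floor))
            else:
                v = np.array([
                    max(((m0 - mu[0]) ** 2).mean(), floor),
                    max(((m1 - mu[1]) ** 2).mean(), floor),
                ])
            best = max(best, gaussian_mixture_loglik(x, w, mu, v))
    return best


def cox_grid_oracle(loglik_fn, lo=-5.0, hi=5.0, step=1e-4):
    """1-D grid-search maximizer of a partial log-likelihood."""
    grid = np.arange(lo, hi + step, step)
    values = np.array([loglik_fn(b) for b in grid])
    return float(grid[np.argmax(values)])
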