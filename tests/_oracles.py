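"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations — enumeration, O(n^2) pair counting,
hand-rolled Newton-Raphson, zoomed grid search — kept separate from the
package code paths they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def outcome_distribution_enumerated(u: float, e) -> np.ndarray:
    """Marginalize over all latent (receptive, viable_1..m) states."""
    e = list(e)
    m = len(e)
    probs = np.zeros(m + 1)
    for states in itertools.product([0, 1], repeat=1 + m):
        r, viable = states[0], states[1:]
        p = u if r else (1 - u)
        for ej, vj in zip(e, viable):
            p *= ej if vj else (1 - ej)
        sacs = r * sum(viable)
        probs[sacs] += p
    return probs


def loglik_enumerated(u, e_per_cycle, y) -> float:
    """Sum of log enumerated outcome probabilities over cycles."""
    total = 0.0
    for ui, ei, yi in zip(u, e_per_cycle, y):
        total += math.log(outcome_distribution_enumerated(ui, ei)[yi])
    return total


def auc_pair_count(scores, outcomes) -> float:
    """All-pairs concordance with ties counted one half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes).astype(bool)
    pos = s[y]
    neg = s[~y]
    total = conc = 0.0
    for a in pos:
        for b in neg:
            total += 1
            if a > b:
                conc += 1
            elif a == b:
                conc += 0.5
    return conc / total


def logistic_newton(X, y, max_iter: int = 100, tol: float = 1e-12) -> np.ndarray:
    """Plain Newton-Raphson logistic regression (intercept included in X)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1 - p)
        grad = X.T @ (y - p)
        H = (X * W[:, None]).T @ X
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def grid_search_two_param_mle(
    counts: dict[str, int], lo: float = -4.0, hi: float = 4.0, n_grid: int = 200, zooms: int = 5
) -> tuple[float, float]:
    """Zoomed grid search for the 2-parameter EU model (E and U intercepts).

    ``counts``: set0, set1, det0, det1, det2 cycle counts.  The likelihood
    depends on the data only through these counts, so each grid point is a
    closed-form evaluation.  Each stage recenters a fresh n_grid x n_grid
    grid on the best point with a 10x smaller span; five stages bring the
    grid resolution below 1e-4.
    """

    def loglik(be, bu):
        e = 1.0 / (1.0 + np.exp(-be))
        u = 1.0 / (1.0 + np.exp(-bu))
        p1s = u * e
        p2d = u * e * e
        p1d = u * 2 * e * (1 - e)
        p0d = 1 - u * (2 * e - e * e)
        with np.errstate(divide="ignore"):
            ll = (
                counts["set1"] * np.log(p1s)
                + counts["set0"] * np.log(1 - p1s)
                + counts["det2"] * np.log(p2d)
                + counts["det1"] * np.log(p1d)
                + counts["det0"] * np.log(p0d)
            )
        return ll

    be_lo, be_hi, bu_lo, bu_hi = lo, hi, lo, hi
    best = (0.0, 0.0)
    for _ in range(zooms):
        be_grid = np.linspace(be_lo, be_hi, n_grid)
        bu_grid = np.linspace(bu_lo, bu_hi, n_grid)
        ll = loglik(be_grid[:, None], bu_grid[None, :])
        i, j = np.unravel_index(np.nanargmax(ll), ll.shape)
        best = (float(be_grid[i]), float(bu_grid[j]))
        span_be = (be_hi - be_lo) / 10
        span_bu = (bu_hi - bu_lo) / 10
        be_lo, be_hi = best[0] - span_be, best[0] + span_be
        bu_lo, bu_hi = best[1] - span_bu, best[1] + span_bu
    return best
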