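"""Independent reference implementations used only to check the package.

These deliberately use different algorithms from the implementation:
exhaustive recursion instead of dynamic programming, direct set
construction instead of loop enumeration, and textbook closed forms
instead of iterative solvers.
"""

from __future__ import annotations

import numpy as np

PAIR_WEIGHTS = {
    ("G", "C"): -3.0,
    ("C", "G"): -3.0,
    ("A", "U"): -2.0,
    ("U", "A"): -2.0,
    ("G", "U"): -1.0,
    ("U", "G"): -1.0,
}


def brute_force_fold(seq: str, min_loop: int = 3) -> float:
    """Minimum weighted-pair score over all nested structures, by exhaustive
    recursion on whether the first base pairs and with whom."""

    def rec(i: int, j: int) -> float:  # half-open [i, j)
        if j - i < min_loop + 2:
            return 0.0
        best = rec(i + 1, j)  # first base unpaired
        for k in range(i + min_loop + 1, j):
            w = PAIR_WEIGHTS.get((seq[i], seq[k]))
            if w is not None:
                best = min(best, w + rec(i + 1, k) + rec(k + 1, j))
        return best

    return rec(0, len(seq))


def brute_force_window_slots(
    max_offset: int, min_len: int, max_len: int, step: int
) -> set[tuple[int, int]]:
    """All (slot_start, slot_end) windows, built by filtering every possible
    slot pair rather than by nested loops over lengths and placements."""
    span = 2 * max_offset
    lengths = set(range(min_len, max_len + 1, step))
    return {
        (a, b)
        for a in range(span)
        for b in range(a, span)
        if (b - a + 1) in lengths and a % step == 0
    }


def ridge_closed_form(
    X: np.ndarray, y: np.ndarray, lam: float
) -> tuple[float, np.ndarray]:
    """Exact minimizer of ||y - a - Xb||^2 + lam * ||b||^2 (intercept
    unpenalized): center, solve the normal equations, restore intercept."""
    xm, ym = X.mean(axis=0), y.mean()
    Xc, yc = X - xm, y - ym
    p = X.shape[1]
    beta = np.linalg.solve(Xc.T @ Xc + lam * np.eye(p), Xc.T @ yc)
    return float(ym - xm @ beta), beta


def soft_threshold(rho: float, thresh: float) -> float:
    return float(np.sign(rho) * max(abs(rho) - thresh, 0.0))


def lasso_1d_paper_scale(x: np.ndarray, y: np.ndarray, lam: float) -> float:
    """Exact 1-feature LASSO coefficient for the objective
    sum((y - a - b x)^2) + lam * |b| with x standardized (mean 0, ssq = n)."""
    n = len(y)
    yc = y - y.mean()
    rho = float(x @ yc)  # = n * corr-scale inner product
    return soft_threshold(rho, lam / 2.0) / float(x @ x)
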