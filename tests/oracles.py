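"""Independent reference implementations used only to check the package.

Each oracle takes a deliberately different computational route from the code
it validates: eigen/SVD algebra instead of NIPALS, exact rational enumeration
instead of log-space recursion, closed-form formulas instead of regression
residuals.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np
from scipy import stats


def svd_pls(X: np.ndarray, Y: np.ndarray, n_components: int):
    """PLS2 via repeated SVD of the cross-covariance matrix.

    The first left singular vector of ``X'Y`` is the NIPALS weight vector, so
    scores from this route must match NIPALS up to sign.
    Returns (T, W, P) on centered inputs.
    """
    X = X - X.mean(axis=0)
    Y = Y - Y.mean(axis=0)
    n, p = X.shape
    T = np.zeros((n, n_components))
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    for a in range(n_components):
        U, _, _ = np.linalg.svd(X.T @ Y, full_matrices=False)
        w = U[:, 0]
        t = X @ w
        pv = X.T @ t / (t @ t)
        q = Y.T @ t / (t @ t)
        X = X - np.outer(t, pv)
        Y = Y - np.outer(t, q)
        T[:, a], W[:, a], P[:, a] = t, w, pv
    return T, W, P


def vip_formula(weights: np.ndarray, ssy_explained: np.ndarray) -> np.ndarray:
    """Direct spreadsheet-style evaluation of the VIP definition."""
    p, A = weights.shape
    ssy = np.asarray(ssy_explained, dtype=float)
    out = np.empty(p)
    for j in range(p):
        acc = 0.0
        for a in range(A):
            wa = weights[:, a]
            acc += ssy[a] * (wa[j] / math.sqrt(float(wa @ wa))) ** 2
        out[j] = math.sqrt(p * acc / ssy.sum())
    return out


def fisher_exact_bruteforce(table) -> float:
    """Exact two-sided Freeman-Halton p by exhaustive rational enumeration.

    Enumerates every nonnegative integer matrix with the observed margins via
    itertools compositions and sums exact Fraction probabilities of tables no
    more probable than the observed one.
    """
    T = np.asarray(table, dtype=int)
    row = T.sum(axis=1).tolist()
    col = T.sum(axis=0).tolist()
    n = int(T.sum())

    def prob(cells) -> Fraction:
        num = Fraction(1)
        for r in row:
            num *= math.factorial(r)
        for c in col:
            num *= math.factorial(c)
        den = Fraction(math.factorial(n))
        for v in cells:
            den *= math.factorial(v)
        return num / den

    def compositions(total, bounds):
        if len(bounds) == 1:
            if total <= bounds[0]:
                yield (total,)
            return
        for v in range(min(total, bounds[0]) + 1):
            for rest in compositions(total - v, bounds[1:]):
                yield (v,) + rest

    def tables(rows_left, colrem):
        if len(rows_left) == 1:
            yield tuple(colrem)
            return
        for first in compositions(rows_left[0], colrem):
            rest_colrem = [c - v for c, v in zip(colrem, first)]
            for rest in tables(rows_left[1:], rest_colrem):
                yield first + rest

    p_obs = prob(T.ravel().tolist())
    total = Fraction(0)
    for cells in tables(row, col):
        p = prob(cells)
        if p <= p_obs:
            total += p
    return float(total)


def partial_corr_first_order(x, y, z) -> float:
    """Textbook recursive formula r_xy.z on the ranks of x and y."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    z = stats.rankdata(np.asarray(z, dtype=float))
    r_xy = stats.pearsonr(rx, ry)[0]
    r_xz = stats.pearsonr(rx, z)[0]
    r_yz = stats.pearsonr(ry, z)[0]
    return (r_xy - r_xz * r_yz) / math.sqrt((1 - r_xz**2) * (1 - r_yz**2))


def anova_sums_of_squares(groups) -> tuple[float, float]:
    """From-scratch one-way ANOVA via explicit sums of squares."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    allv = np.concatenate(arrays)
    grand = allv.mean()
    ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    dfb = len(arrays) - 1
    dfw = len(allv) - len(arrays)
    f = (ssb / dfb) / (ssw / dfw)
    return float(f), float(stats.f.sf(f, dfb, dfw))


def shape_truth_table(fc_sga: float, fc_lga: float) -> str:
    """Independent one-compartment shape rule written as a lookup table."""
    sign = lambda v: 0 if v == 1.0 else (1 if v > 1.0 else -1)
    key = (sign(fc_sga), sign(fc_lga))
    table = {
        (1, 1): "U_up", (-1, -1): "U_down",
        (-1, 1): "line_up", (1, -1): "line_down",
    }
    return table.get(key, "none")
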