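"""Cohort demographic summaries: one-way ANOVA and exact Fisher r x c tests.

Continuous characteristics are compared across the three birthweight groups by
classical one-way ANOVA — either from raw values or reconstructed from printed
group means, SDs and sizes — and categorical characteristics by the
Fisher-Freeman-Halton exact test (the r x c generalization of Fisher's exact
test, two-sided by probability ordering).  The exact test enumerates every
contingency table with the observed margins, accumulating hypergeometric
probabilities in log space; a seeded Monte-Carlo mode covers tables beyond the
enumeration budget.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

#: relative tolerance for probability ties in the two-sided tail definition
TIE_RTOL = 1e-12


def anova_oneway(groups: list) -> tuple[float, float]:
    """Classical fixed-effects one-way ANOVA over >= 2 groups of raw values."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs n >= 2")
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def anova_from_summary(means, sds, ns) -> tuple[float, float]:
    """One-way ANOVA reconstructed from per-group means, SDs and sizes.

    ``SS_between`` is rebuilt from the group means about the grand mean and
    ``SS_within = sum (n_i - 1) sd_i^2``; exact when the summaries carry full
    precision, and within printed-rounding error otherwise.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=int)
    if not (len(means) == len(sds) == len(ns)) or len(means) < 2:
        raise ValueError("means, sds, ns must be equal-length with >= 2 groups")
    if np.any(ns < 2):
        raise ValueError("every group needs n >= 2")
    if np.any(sds <= 0):
        raise ValueError("SDs must be positive for groups with n >= 2")
    n_total = int(ns.sum())
    k = len(means)
    grand = float((ns * means).sum() / n_total)
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * sds**2).sum())
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0:
        return float("inf"), 0.0
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return float(f), p


# ---------------------------------------------------------------------------
# Fisher-Freeman-Halton exact r x c test
# ---------------------------------------------------------------------------

class EnumerationBudgetError(RuntimeError):
    """Raised when exact enumeration would exceed the table budget."""


def _log_prob_const(row: np.ndarray, col: np.ndarray, lfact: np.ndarray) -> float:
    return float(lfact[row].sum() + lfact[col].sum() - lfact[row.sum()])


def fisher_exact_rxc(
    table,
    budget: int = 10_000_000,
    monte_carlo: bool = False,
    n_samples: int = 200_000,
    seed: int = 0,
) -> float:
    """Two-sided exact p for an r x c contingency table (Freeman-Halton).

    The p value sums the conditional hypergeometric probabilities of every
    table sharing the observed margins whose probability does not exceed the
    observed table's (relative tie tolerance 1e-12).  Enumeration aborts with
    :class:`EnumerationBudgetError` past ``budget`` candidate tables; set
    ``monte_carlo=True`` for a seeded margin-conditional sampling estimate.
    """
    T = np.asarray(table, dtype=int)
    if T.ndim != 2 or np.any(T < 0) or not np.array_equal(T, np.asarray(table)):
        raise ValueError("table must be a 2-D array of nonnegative integers")
    row, col = T.sum(axis=1), T.sum(axis=0)
    n = int(T.sum())
    if n == 0:
        raise ValueError("empty table")
    lfact = gammaln(np.arange(n + 2) + 1.0)  # lfact[m] = log m!
    const = _log_prob_const(row, col, lfact)
    logp_obs = const - float(lfact[T].sum())
    cutoff = logp_obs + np.log1p(TIE_RTOL)

    if monte_carlo:
        return _fisher_monte_carlo(row, col, lfact, const, cutoff, n_samples, seed)

    r, c = T.shape
    total_p = 0.0
    count = 0

    def recurse(i: int, colrem: np.ndarray, acc_lfact: float) -> None:
        nonlocal total_p, count
        if i == r - 1:
            count += 1
            if count > budget:
                raise EnumerationBudgetError(
                    f"more than {budget} candidate tables; "
                    "rerun with monte_carlo=True for a seeded estimate"
                )
            logp = const - acc_lfact - float(lfact[colrem].sum())
            if logp <= cutoff:
                total_p += float(np.exp(logp))
            return
        # enumerate row i as compositions of row[i] bounded by colrem
        def fill(j: int, remaining: int, colrem_: np.ndarray, acc: float) -> None:
            if j == c - 1:
                if remaining <= colrem_[j]:
                    nxt = colrem_.copy()
                    nxt[j] -= remaining
                    recurse(i + 1, nxt, acc + float(lfact[remaining]))
                return
            hi = min(remaining, colrem_[j])
            for v in range(hi + 1):
                nxt = colrem_.copy()
                nxt[j] -= v
                fill(j + 1, remaining - v, nxt, acc + float(lfact[v]))

        fill(0, int(row[i]), colrem, acc_lfact)

    recurse(0, col.copy(), 0.0)
    return min(total_p, 1.0)


def _fisher_monte_carlo(
    row: np.ndarray, col: np.ndarray, lfact: np.ndarray,
    const: float, cutoff: float, n_samples: int, seed: int,
) -> float:
    """Margin-conditional sampling: fill rows by multivariate hypergeometric
    draws from the remaining column totals (exactly the null distribution)."""
    rng = np.random.default_rng(seed)
    r = len(row)
    hits = 0
    for _ in range(n_samples):
        colrem = col.copy()
        acc = 0.0
        for i in range(r - 1):
            v = rng.multivariate_hypergeometric(colrem, int(row[i]))
            colrem = colrem - v
            acc += float(lfact[v].sum())
        acc += float(lfact[colrem].sum())
        if const - acc <= cutoff:
            hits += 1
    return hits / n_samples


# ---------------------------------------------------------------------------
# Table-1 style summaries
# ---------------------------------------------------------------------------

def _format_p(p: float) -> str:
    if not np.isfinite(p):
        return "NA"
    return "< 0.001" if p < 0.001 else f"{p:.2f}"


def summarize_cohort(
    phenotypes: pd.DataFrame, group_col: str = "group",
    group_order: tuple[str, ...] = ("SGA", "AGA", "LGA"),
) -> pd.DataFrame:
    """Demographics table: mean (SD) + ANOVA p for continuous variables,
    n (%) per level + exact Fisher p for categorical ones.

    Display follows the clinical convention — means/SDs and percentages to one
    decimal, p to two decimals with a "< 0.001" floor.
    """
    if group_col not in phenotypes.columns:
        raise ValueError(f"phenotype table lacks the {group_col!r} column")
    g = phenotypes[group_col]
    rows = []
    for var in phenotypes.columns:
        if var == group_col:
            continue
        col = phenotypes[var]
        if pd.api.types.is_numeric_dtype(col):
            groups = [col[g == lv].dropna().to_numpy() for lv in group_order]
            try:
                f, p = anova_oneway(groups)
            except ValueError as exc:
                warnings.warn(f"skipping {var!r}: {exc}", stacklevel=2)
                continue
            display = {
                lv: f"{vals.mean():.1f} ({vals.std(ddof=1):.1f})"
                for lv, vals in zip(group_order, groups)
            }
            rows.append(
                {"variable": var, "level": "", **display, "test": "anova",
                 "statistic": f, "p": p, "p_display": _format_p(p)}
            )
        elif col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.dropna().unique().tolist())
            counts = np.array(
                [[int(((col == lv) & (g == grp)).sum()) for grp in group_order]
                 for lv in levels]
            )
            if len(levels) == 1:
                p = 1.0
            else:
                p = fisher_exact_rxc(counts)
            for i, lv in enumerate(levels):
                totals = counts.sum(axis=0)
                display = {
                    grp: f"{counts[i, j]} ({100 * counts[i, j] / totals[j]:.1f})"
                    for j, grp in enumerate(group_order)
                }
                rows.append(
                    {"variable": var, "level": str(lv), **display, "test": "fisher",
                     "statistic": float("nan"), "p": p, "p_display": _format_p(p)}
                )
        else:
            warnings.warn(f"skipping {var!r}: unsupported dtype {col.dtype}", stacklevel=2)
    return pd.DataFrame(rows)
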