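"""Spearman and covariate-adjusted (partial Spearman) correlation analyses.

Two models mirror the clinical-correlation tables: Model 1 is the crude
Spearman correlation between a metabolite and a clinical variable; Model 2 is
a nonparametric partial correlation — both variables are rank-transformed
(average ranks), residualized on the covariate design by least squares, and
the Pearson correlation of the residuals is tested on ``n - 2 - k`` degrees
of freedom.  The default covariate preset adjusts for maternal age, parity,
GDM, gestational age and fetal sex; a second preset omits GDM.

All records use complete cases and report the n actually used; p values are
two-sided with no multiple-testing correction (an optional BH-FDR column can
be added for convenience).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .prep import IntensityMatrix

COVARIATE_PRESETS = {
    # clinical-table footnote: maternal age, parity, GDM, gestational age, fetal sex
    "table": ("maternal_age", "parity", "gdm", "gestational_age", "newborn_sex"),
    # methods-text variant without GDM
    "methods": ("maternal_age", "parity", "gestational_age", "newborn_sex"),
}


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks; two-sided t-based p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 4:
        raise ValueError("need >= 4 paired non-missing observations")
    x, y = x[ok], y[ok]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)


def _design_matrix(covariates: pd.DataFrame) -> np.ndarray:
    """Intercept + rank-transformed numeric columns + dummy-coded categoricals.

    Numeric covariates enter as average ranks so the adjustment is fully
    nonparametric: a variable identical to a covariate partials to exactly 0.
    """
    cols = [np.ones(len(covariates))]
    for name in covariates.columns:
        col = covariates[name]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(stats.rankdata(col.to_numpy(dtype=float), method="average"))
        else:
            dummies = pd.get_dummies(col.astype(str), drop_first=True)
            for d in dummies.columns:
                cols.append(dummies[d].to_numpy(dtype=float))
    return np.column_stack(cols)


def partial_spearman(x, y, covariates: pd.DataFrame | np.ndarray | None) -> tuple[float, float, int]:
    """Partial Spearman correlation of x and y given covariates.

    Returns ``(r, p, k)`` where ``k`` is the effective number of covariate
    columns after dropping collinear ones.  With no covariates this reduces
    exactly to :func:`spearman`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None or (hasattr(covariates, "shape") and np.size(covariates) == 0):
        r, p = spearman(x, y)
        return r, p, 0
    if not isinstance(covariates, pd.DataFrame):
        covariates = pd.DataFrame(np.asarray(covariates))
    Z = _design_matrix(covariates)
    ok = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(Z), axis=1)
    x, y, Z = x[ok], y[ok], Z[ok]
    n = len(x)
    rank = int(np.linalg.matrix_rank(Z))
    k = rank - 1
    if rank < Z.shape[1]:
        warnings.warn(
            f"collinear covariate design: rank {rank} < {Z.shape[1]} columns; "
            "redundant directions carry no adjustment", stacklevel=2,
        )
    if n < k + 4:
        raise ValueError(f"need >= {k + 4} complete cases for {k} covariates; have {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan"), k
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    # residualize the ranks on the covariate design (least squares handles
    # rank deficiency; redundant columns simply contribute nothing)
    bx, *_ = np.linalg.lstsq(Z, rx, rcond=None)
    by, *_ = np.linalg.lstsq(Z, ry, rcond=None)
    ex, ey = rx - Z @ bx, ry - Z @ by
    # a variable lying in the covariate span leaves only numerical noise:
    # its partial correlation is exactly zero
    tol = 1e-12 * n**3  # relative to the scale of rank sums of squares
    if ex @ ex < tol or ey @ ey < tol:
        return 0.0, 1.0, k
    denom = np.sqrt((ex @ ex) * (ey @ ey))
    if denom == 0:
        return float("nan"), float("nan"), k
    r = float((ex @ ey) / denom)
    r = max(-1.0, min(1.0, r))
    df = n - 2 - k
    if df < 1:
        return r, float("nan"), k
    if abs(r) >= 1.0:
        return r, 0.0, k
    t = r * np.sqrt(df / (1.0 - r * r))
    p = float(2 * stats.t.sf(abs(t), df))
    return r, p, k


def correlate_panel(
    matrix: IntensityMatrix,
    phenotypes: pd.DataFrame,
    metabolite_ids,
    clinical_variables,
    model: int = 1,
    covariate_preset: str = "table",
    fdr: bool = False,
) -> pd.DataFrame:
    """Metabolite x clinical-variable correlation records for one compartment.

    Model 1 is crude Spearman; Model 2 adjusts for the chosen covariate
    preset.  One record per (metabolite, variable) with r, two-sided p and the
    complete-case n used.
    """
    if model not in (1, 2):
        raise ValueError("model must be 1 or 2")
    bad = [m for m in metabolite_ids if m not in matrix.data.columns]
    if bad:
        raise ValueError(f"unknown metabolite id(s): {bad}")
    bad = [v for v in clinical_variables if v not in phenotypes.columns]
    if bad:
        raise ValueError(
            f"unknown clinical variable(s) {bad}; valid: {sorted(phenotypes.columns)}"
        )
    covars = list(COVARIATE_PRESETS[covariate_preset]) if model == 2 else []
    missing_cov = [c for c in covars if c not in phenotypes.columns]
    if missing_cov:
        raise ValueError(f"phenotype table lacks covariate(s) {missing_cov}")
    pheno = phenotypes.reindex(matrix.data.index)
    records = []
    for met in metabolite_ids:
        xv = matrix.data[met]
        for var in clinical_variables:
            yv = pheno[var].astype(float)
            try:
                if model == 1:
                    ok = xv.notna() & yv.notna()
                    r, p = spearman(xv[ok], yv[ok])
                    n_used, k = int(ok.sum()), 0
                else:
                    cov_df = pheno[covars]
                    ok = xv.notna() & yv.notna() & cov_df.notna().all(axis=1)
                    r, p, k = partial_spearman(xv[ok], yv[ok], cov_df[ok])
                    n_used = int(ok.sum())
                flagged = not np.isfinite(r)
            except ValueError:
                r, p, n_used, k, flagged = float("nan"), float("nan"), 0, len(covars), True
            records.append(
                {
                    "metabolite_id": met, "variable": var,
                    "compartment": matrix.compartment, "model": model,
                    "covariates": ";".join(covars), "r": r, "p": p,
                    "n": n_used, "flagged": flagged,
                }
            )
    out = pd.DataFrame(records)
    if fdr:
        out["q_bh"] = _bh_fdr(out["p"].to_numpy())
    return out


def _bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p values (NaN-safe)."""
    q = np.full_like(p, np.nan, dtype=float)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = stats.false_discovery_control(p[ok], method="bh")
    return q


def maternal_cord_correlation(
    maternal: IntensityMatrix, cord: IntensityMatrix, metabolite_ids=None
) -> pd.DataFrame:
    """Spearman correlation of each metabolite's maternal vs cord abundance."""
    if maternal.compartment != "maternal" or cord.compartment != "cord":
        raise ValueError("pass (maternal, cord) matrices in that order")
    if set(maternal.data.index) != set(cord.data.index):
        diff = sorted(map(str, set(maternal.data.index) ^ set(cord.data.index)))
        raise ValueError(f"unmatched dyads between compartments: {diff}")
    cord_aligned = cord.data.loc[maternal.data.index]
    if metabolite_ids is None:
        metabolite_ids = [m for m in maternal.data.columns if m in cord.data.columns]
    records = []
    for met in metabolite_ids:
        if met not in maternal.data.columns or met not in cord_aligned.columns:
            raise ValueError(f"metabolite {met!r} absent from one compartment")
        xv, yv = maternal.data[met], cord_aligned[met]
        ok = xv.notna() & yv.notna()
        try:
            r, p = spearman(xv[ok], yv[ok])
            flagged = not np.isfinite(r)
        except ValueError:
            r, p, flagged = float("nan"), float("nan"), True
        records.append(
            {
                "metabolite_id": met, "variable": "cord counterpart",
                "compartment": "maternal", "model": 1, "covariates": "",
                "r": r, "p": p, "n": int(ok.sum()), "flagged": flagged,
            }
        )
    return pd.DataFrame(records)
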