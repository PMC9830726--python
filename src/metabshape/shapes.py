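"""Differential-metabolite selection, four-way intersection, and U/line calls.

The discovery procedure: for each compartment (maternal, cord) fit two-class
OPLS-DA models for SGA vs AGA and LGA vs AGA, keep metabolites with VIP > 1
(differential metabolites, DMs), intersect the four DM sets, and classify each
shared metabolite by the pattern of its two fold changes — FC(SGA/AGA) and
FC(LGA/AGA), ratios of group means of raw intensity:

* both FC > 1            -> ``U_up``    (elevated in both birthweight tails)
* both FC < 1            -> ``U_down``
* FC_SGA < 1 < FC_LGA    -> ``line_up``  (monotone increase SGA -> AGA -> LGA)
* FC_SGA > 1 > FC_LGA    -> ``line_down``
* any FC exactly 1       -> ``none``

A final label is assigned only when the maternal and cord patterns agree;
discordant metabolites are labelled ``none``.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .prep import IntensityMatrix

COMPARISONS = ("SGAvAGA_maternal", "SGAvAGA_cord", "LGAvAGA_maternal", "LGAvAGA_cord")
SHAPE_LABELS = ("U_up", "U_down", "line_up", "line_down", "none")


def select_dms(vip_table: pd.Series, threshold: float = 1.0) -> set:
    """Metabolite ids with VIP strictly greater than ``threshold``."""
    if len(vip_table) == 0:
        raise ValueError("empty VIP table")
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    return set(vip_table.index[vip_table > threshold])


def intersect_dms(dm_sets: dict[str, set]) -> dict:
    """All Venn region counts of the four DM sets plus the 4-way intersection.

    Returns ``{"regions": {frozenset-of-comparison-names as '+'-joined key:
    count}, "intersection": set, "counts": per-set sizes}``.  The 15 region
    counts are exclusive (each id counted in exactly one region).
    """
    missing = [c for c in COMPARISONS if c not in dm_sets]
    if missing:
        raise ValueError(f"missing comparison set(s): {missing}")
    sets = {c: set(dm_sets[c]) for c in COMPARISONS}
    universe = set().union(*sets.values())
    regions: dict[str, int] = {}
    for r in range(1, 5):
        for combo in combinations(COMPARISONS, r):
            inside = set.intersection(*(sets[c] for c in combo))
            outside = set().union(*(sets[c] for c in COMPARISONS if c not in combo)) \
                if r < 4 else set()
            regions["+".join(combo)] = len(inside - outside)
    intersection = set.intersection(*sets.values())
    return {
        "regions": regions,
        "intersection": intersection,
        "counts": {c: len(sets[c]) for c in COMPARISONS},
        "n_universe": len(universe),
    }


def fold_change(
    raw_matrix: IntensityMatrix,
    groups: pd.Series,
    numerator_group: str,
    denominator_group: str,
    method: str = "mean",
) -> pd.Series:
    """Per-metabolite fold change: ratio of group means of raw intensity.

    Missing values are excluded per metabolite.  ``method="geometric"`` uses
    geometric instead of arithmetic group means.  Metabolites whose
    denominator-group mean is zero (or either group has < 2 observed values)
    come back as NaN.
    """
    if raw_matrix.normalized:
        raise ValueError("fold changes are defined on raw intensities")
    groups = pd.Series(groups).reindex(raw_matrix.data.index)
    if groups.isna().any():
        raise ValueError("group labels missing for some samples")
    num = raw_matrix.data.loc[groups == numerator_group]
    den = raw_matrix.data.loc[groups == denominator_group]
    if len(num) < 2 or len(den) < 2:
        raise ValueError("both groups need >= 2 samples")

    def group_mean(df: pd.DataFrame) -> pd.Series:
        if method == "mean":
            m = df.mean(axis=0, skipna=True)
        elif method == "geometric":
            m = np.exp(np.log(df.where(df > 0)).mean(axis=0, skipna=True))
        else:
            raise ValueError(f"unknown fold-change method {method!r}")
        return m.where(df.notna().sum(axis=0) >= 2)

    m_num, m_den = group_mean(num), group_mean(den)
    fc = m_num / m_den.where(m_den > 0)
    fc.name = f"FC_{numerator_group}/{denominator_group}"
    return fc


def _pattern_label(fc_sga: float, fc_lga: float) -> str:
    """Shape implied by one compartment's (FC_SGA, FC_LGA) pair."""
    if not np.isfinite(fc_sga) or not np.isfinite(fc_lga):
        return "none"
    if fc_sga == 1.0 or fc_lga == 1.0:
        return "none"
    if fc_sga > 1 and fc_lga > 1:
        return "U_up"
    if fc_sga < 1 and fc_lga < 1:
        return "U_down"
    if fc_sga < 1 and fc_lga > 1:
        return "line_up"
    return "line_down"


def classify_shape(fc_table: pd.DataFrame, concordance: str = "both") -> pd.DataFrame:
    """Assign a U/line label from the four fold changes of each metabolite.

    ``fc_table`` needs columns ``fc_sga_maternal``, ``fc_lga_maternal``,
    ``fc_sga_cord``, ``fc_lga_cord``.  With ``concordance="both"`` (default)
    the maternal and cord patterns must agree for a final label; with
    ``"maternal"`` the maternal pattern alone decides (lenient sensitivity
    mode).  Metabolites with any missing fold change are labelled ``none``
    and flagged unclassifiable rather than dropped.
    """
    required = ["fc_sga_maternal", "fc_lga_maternal", "fc_sga_cord", "fc_lga_cord"]
    missing_cols = [c for c in required if c not in fc_table.columns]
    if missing_cols:
        raise ValueError(f"fold-change table lacks column(s) {missing_cols}")
    if concordance not in ("both", "maternal"):
        raise ValueError("concordance must be 'both' or 'maternal'")
    out = fc_table[required].copy()
    maternal = [
        _pattern_label(s, l)
        for s, l in zip(out["fc_sga_maternal"], out["fc_lga_maternal"])
    ]
    cord = [
        _pattern_label(s, l) for s, l in zip(out["fc_sga_cord"], out["fc_lga_cord"])
    ]
    out["maternal_pattern"] = maternal
    out["cord_pattern"] = cord
    if concordance == "both":
        out["label"] = [
            m if (m == c and m != "none") else "none" for m, c in zip(maternal, cord)
        ]
    else:
        out["label"] = maternal
    out["unclassifiable"] = out[required].isna().any(axis=1)
    return out


def discover_shapes(
    vip_tables: dict[str, pd.Series],
    raw_maternal: IntensityMatrix,
    raw_cord: IntensityMatrix,
    groups: pd.Series,
    threshold: float = 1.0,
    fc_method: str = "mean",
    concordance: str = "both",
) -> dict:
    """Full selection chain: VIP > threshold -> 4-way intersection -> shapes.

    ``vip_tables`` maps each comparison name in :data:`COMPARISONS` to its VIP
    Series over the merged-mode feature space.
    """
    dm_sets = {name: select_dms(v, threshold) for name, v in vip_tables.items()}
    venn = intersect_dms(dm_sets)
    shared = sorted(venn["intersection"])
    fc = pd.DataFrame(
        {
            "fc_sga_maternal": fold_change(raw_maternal, groups, "SGA", "AGA", fc_method),
            "fc_lga_maternal": fold_change(raw_maternal, groups, "LGA", "AGA", fc_method),
            "fc_sga_cord": fold_change(raw_cord, groups, "SGA", "AGA", fc_method),
            "fc_lga_cord": fold_change(raw_cord, groups, "LGA", "AGA", fc_method),
        }
    )
    calls = classify_shape(fc.loc[shared], concordance=concordance) if shared else \
        classify_shape(fc.iloc[:0], concordance=concordance)
    return {
        "dm_sets": dm_sets,
        "venn": venn,
        "fold_changes": fc,
        "shape_calls": calls,
        "threshold": threshold,
    }


def ordered_zscore_matrix(
    normalized: IntensityMatrix, groups: pd.Series, metabolite_ids
) -> pd.DataFrame:
    """Group-mean Z-score matrix (rows SGA/AGA/LGA), ordered for heatmap export."""
    if not normalized.normalized:
        raise ValueError("expects a Z-scored matrix")
    ids = [m for m in metabolite_ids if m in normalized.data.columns]
    df = normalized.data[ids]
    g = pd.Series(groups).reindex(df.index)
    means = df.groupby(g, observed=True).mean().reindex(["SGA", "AGA", "LGA"])
    # order columns by the SGA-vs-AGA deviation so like shapes cluster together
    order = (means.loc["SGA"] - means.loc["AGA"]).sort_values().index
    return means[order]
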