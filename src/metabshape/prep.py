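"""Intensity-matrix container, Z-score normalization, mode merging and imputation.

The analysis operates on sample x metabolite peak-intensity matrices, one per
(compartment, ionization mode) pair.  Fold changes are always computed on raw
intensities; multivariate models and heatmap ordering consume column-standardized
(Z-scored) values.  Standardization uses the sample standard deviation
(denominator ``n - 1``), the usual chemometrics convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("metabshape")

COMPARTMENTS = ("maternal", "cord")
MODES = ("pos", "neg")

#: absolute tolerance for the "column mean 0 / SD 1" normalization invariant
NORM_TOL = 1e-9


@dataclass
class IntensityMatrix:
    """A sample x metabolite abundance matrix for one compartment/mode.

    Parameters
    ----------
    data
        DataFrame indexed by sample id with one column per metabolite id.
        Raw matrices hold nonnegative abundances; missing cells are NaN.
    compartment
        ``"maternal"`` or ``"cord"``.
    mode
        Ionization mode: ``"pos"``, ``"neg"``, or ``"merged"`` after
        :func:`merge_modes`.
    normalized
        True once the matrix has been Z-scored column-wise.
    """

    data: pd.DataFrame
    compartment: str
    mode: str
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate metabolite ids: {dupes}")
        if not self.normalized:
            vals = self.data.to_numpy(dtype=float)
            if np.nanmin(vals, initial=np.inf) < 0:
                raise ValueError("raw intensities must be nonnegative")

    @property
    def samples(self) -> list:
        return list(self.data.index)

    @property
    def metabolites(self) -> list:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def znormalize(matrix: IntensityMatrix, *, within_compartment: bool = True) -> IntensityMatrix:
    """Z-score each metabolite column: subtract the mean, divide by the sample SD.

    Missing entries are preserved; the per-column statistics use non-missing
    values only.  Columns with zero variance (or fewer than two non-missing
    values) are undefined under the transform and are dropped with a warning.

    ``within_compartment`` is informational only (this function always sees one
    compartment); it is recorded so pooled-normalization pipelines can assert
    their choice.
    """
    if matrix.normalized:
        # idempotent in effect: re-standardizing changes nothing beyond fp noise
        return replace(matrix, data=matrix.data.copy())
    df = matrix.data.astype(float)
    counts = df.notna().sum(axis=0)
    sds = df.std(axis=0, ddof=1)
    bad = df.columns[(counts < 2) | sds.isna() | (sds <= 0)]
    if len(bad):
        warnings.warn(
            f"dropping {len(bad)} constant or all-missing column(s) before Z-scoring: "
            f"{list(bad[:5])}{'...' if len(bad) > 5 else ''}",
            stacklevel=2,
        )
        logger.warning("znormalize: dropped %d undefined column(s)", len(bad))
        df = df.drop(columns=bad)
    out = (df - df.mean(axis=0)) / df.std(axis=0, ddof=1)
    return IntensityMatrix(out, matrix.compartment, matrix.mode, normalized=True)


def merge_modes(pos: IntensityMatrix, neg: IntensityMatrix) -> IntensityMatrix:
    """Concatenate positive- and negative-mode features into one matrix.

    Metabolite ids are prefixed ``pos:`` / ``neg:`` so the merged feature space
    keeps both detections of any compound; no cross-mode deduplication is done.
    Column order is positive-mode features first.
    """
    if pos.compartment != neg.compartment:
        raise ValueError(
            f"compartment mismatch: {pos.compartment!r} vs {neg.compartment!r}"
        )
    if pos.normalized != neg.normalized:
        raise ValueError("cannot merge a raw matrix with a normalized one")
    s_pos, s_neg = set(pos.samples), set(neg.samples)
    if s_pos != s_neg:
        diff = sorted(map(str, s_pos.symmetric_difference(s_neg)))
        raise ValueError(f"sample sets differ between modes: {diff}")
    left = pos.data.add_prefix("pos:")
    right = neg.data.add_prefix("neg:").loc[pos.data.index]
    merged = pd.concat([left, right], axis=1)
    return IntensityMatrix(merged, pos.compartment, "merged", normalized=pos.normalized)


def impute_missing(matrix: IntensityMatrix, method: str = "half-min") -> IntensityMatrix:
    """Fill missing cells of a raw matrix.

    ``"half-min"`` replaces each missing value with half the metabolite's
    minimum observed intensity (the conventional limit-of-detection surrogate);
    ``"none"`` returns the matrix unchanged and downstream statistics use
    pairwise-complete observations.
    """
    if matrix.normalized:
        raise ValueError("impute_missing expects a raw matrix")
    if method == "none":
        return replace(matrix, data=matrix.data.copy())
    if method != "half-min":
        raise ValueError(f"unknown imputation method {method!r}; use 'half-min' or 'none'")
    df = matrix.data.astype(float)
    fill = df.min(axis=0, skipna=True) / 2.0
    out = df.fillna(fill)
    return replace(matrix, data=out)
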