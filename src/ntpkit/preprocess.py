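"""Normalization and scaling steps required by the classifier's contract.

The classifier compares each sample's marker-gene profile against class
indicator vectors by cosine similarity; on row-centered data this equals
Pearson correlation, so expression should be log-scale, comparably
distributed across samples (quantile normalization) and gene-wise centered
and scaled before classification.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .errors import DegenerateDataWarning, ValidationError
from .io import validate_expression

logger = logging.getLogger("ntpkit")

__all__ = ["log2_transform", "quantile_normalize", "row_center_scale"]


def log2_transform(emat: pd.DataFrame, offset: float = 1.0) -> pd.DataFrame:
    """Replace each value v by log2(v + offset).

    Raises if any value is negative — that usually means the data is
    already on log scale.
    """
    emat = validate_expression(emat)
    if offset < 0:
        raise ValidationError(f"offset must be non-negative, got {offset}")
    values = emat.to_numpy()
    if np.nanmin(values) < 0:
        raise ValidationError(
            "negative expression values found; data may already be log scale"
        )
    return pd.DataFrame(np.log2(values + offset), index=emat.index, columns=emat.columns)


def quantile_normalize(emat: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the same empirical distribution.

    The reference distribution is the mean across samples of the per-rank
    sorted values.  Tied values within a column receive the mean of the
    reference values at their tied ranks.  Missing values are excluded from
    rank computation per column (the reference is interpolated onto the
    column's reduced rank grid) and stay missing.
    """
    emat = validate_expression(emat)
    if emat.shape[1] < 2:
        raise ValidationError(
            "quantile normalization needs >=2 samples; skip normalization for a single sample"
        )
    values = emat.to_numpy()
    n = values.shape[0]

    # Reference: per-column sorted non-missing values interpolated onto a
    # common n-point quantile grid, then averaged across columns.
    grid = np.linspace(0.0, 1.0, n)
    ref_cols = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        finite = col[~np.isnan(col)]
        if finite.size == 0:
            raise ValidationError(f"sample {emat.columns[j]!r} has no observed values")
        src = np.sort(finite)
        src_grid = np.linspace(0.0, 1.0, finite.size) if finite.size > 1 else np.array([0.5])
        ref_cols[:, j] = np.interp(grid, src_grid, src)
    ref = ref_cols.mean(axis=1)  # sorted by construction

    out = np.full_like(values, np.nan)
    for j in range(values.shape[1]):
        col = values[:, j]
        mask = ~np.isnan(col)
        m = int(mask.sum())
        ref_m = ref if m == n else np.interp(np.linspace(0.0, 1.0, m), grid, ref)
        observed = col[mask]
        order = np.argsort(observed, kind="mergesort")
        assigned = np.empty(m)
        assigned[order] = ref_m
        # ties: mean of the reference values at the tied ranks
        uniq, inverse = np.unique(observed, return_inverse=True)
        if uniq.size < m:
            sums = np.bincount(inverse, weights=assigned)
            counts = np.bincount(inverse)
            assigned = (sums / counts)[inverse]
        out[mask, j] = assigned
    return pd.DataFrame(out, index=emat.index, columns=emat.columns)


def row_center_scale(emat: pd.DataFrame, center: bool = True, scale: bool = True) -> pd.DataFrame:
    """Gene-wise center (subtract mean) and scale (divide by sd, ddof=1).

    Zero-variance rows cannot be scaled; they are set to all-zero with a
    warning.  Statistics are computed across the samples of the supplied
    matrix, so small cohorts yield unstable standardization.
    """
    emat = validate_expression(emat)
    values = emat.to_numpy()
    out = values.copy()
    if center:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            out = out - np.nanmean(out, axis=1, keepdims=True)
    if scale:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sd = np.nanstd(values, axis=1, ddof=1, keepdims=True)
            mean_mag = np.abs(np.nanmean(values, axis=1, keepdims=True))
        # relative tolerance: constant rows can carry float-noise variance
        tol = 1e-12 * np.maximum(1.0, mean_mag)
        degenerate = (~np.isfinite(sd)) | (sd <= tol)
        if degenerate.any():
            warnings.warn(
                f"{int(degenerate.sum())} zero-variance gene rows set to all-zero",
                DegenerateDataWarning,
                stacklevel=2,
            )
        safe_sd = np.where(degenerate, 1.0, sd)
        out = out / safe_sd
        if not center:
            # scaling alone still leaves degenerate rows unusable
            out = np.where(degenerate & ~np.isnan(values), 0.0, out)
        else:
            out = np.where(np.broadcast_to(degenerate, out.shape) & ~np.isnan(values), 0.0, out)
    return pd.DataFrame(out, index=emat.index, columns=emat.columns)
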