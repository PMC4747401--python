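"""Normalization and probe-to-gene collapsing of expression matrices.

The expected entry path for array data that has already been summarized to
probe-set intensities is::

    matrix = log2_quantile_normalize(matrix)   # linear -> log2, columns equalized
    matrix, report = aggregate_probes(matrix, probe_map)
    matrix = delog(matrix)                     # back to linear for FC/AD ranking

Quantile normalization follows the usual sort/average/unsort scheme: every
column is forced onto the mean quantile profile; tied values within a column
receive the mean of the quantile values their ranks span.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .matrix import LINEAR, LOG2, ExpressionMatrix


@dataclass
class ProbeAggregationReport:
    """Bookkeeping from :func:`aggregate_probes`."""

    n_probes_in: int
    n_probes_mapped: int
    n_probes_unmapped: int
    n_genes_out: int
    probes_per_gene: pd.Series  # gene_id -> number of probes averaged


def aggregate_probes(
    matrix: ExpressionMatrix, probe_map: pd.Series
) -> tuple[ExpressionMatrix, ProbeAggregationReport]:
    """Collapse a probe-level matrix to gene level by arithmetic mean.

    Probes mapping to the same gene are averaged row-wise on the matrix's
    *current* scale (the default pipeline aggregates on the linear scale;
    see the package methods note).  Probes absent from ``probe_map`` are
    dropped and counted in the report.

    Raises
    ------
    ValueError
        If no probe of the matrix appears in ``probe_map``.
    """
    mapped = probe_map.reindex(matrix.feature_ids).dropna()
    if mapped.empty:
        raise ValueError("no overlap between matrix features and the probe map")
    sub = matrix.values.loc[mapped.index]
    gene_values = sub.groupby(mapped).mean()
    gene_values.index.name = "feature_id"
    report = ProbeAggregationReport(
        n_probes_in=matrix.n_genes,
        n_probes_mapped=len(mapped),
        n_probes_unmapped=matrix.n_genes - len(mapped),
        n_genes_out=gene_values.shape[0],
        probes_per_gene=mapped.groupby(mapped).size().rename("n_probes"),
    )
    return replace(matrix, values=gene_values), report


def _quantile_normalize_columns(x: np.ndarray) -> np.ndarray:
    """Force every column of ``x`` onto the mean quantile profile.

    Ties within a column get the mean of the quantile values they span.
    """
    n, m = x.shape
    profile = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x, dtype=float)
    for j in range(m):
        order = np.argsort(x[:, j], kind="stable")
        col_sorted = x[order, j]
        # average the profile over runs of tied values
        assigned = pd.Series(profile).groupby(pd.Series(col_sorted)).transform("mean")
        out[order, j] = assigned.to_numpy()
    return out


def log2_quantile_normalize(
    matrix: ExpressionMatrix, epsilon: float = 1.0
) -> ExpressionMatrix:
    """log2-transform a linear-scale matrix and quantile-normalize columns.

    Values <= 0 (possible after background correction) are floored to
    ``epsilon`` before the log.  With a single sample, quantile
    normalization is degenerate: the matrix is returned log2-transformed
    with a warning.
    """
    if matrix.scale != LINEAR:
        raise ValueError("log2_quantile_normalize expects a linear-scale matrix")
    x = matrix.values.to_numpy(dtype=float).copy()
    if (x <= 0).any():
        warnings.warn(
            f"{int((x <= 0).sum())} values <= 0 floored to epsilon={epsilon}",
            stacklevel=2,
        )
        x[x <= 0] = epsilon
    logx = np.log2(x)
    if matrix.n_samples == 1:
        warnings.warn(
            "single-sample matrix: quantile normalization skipped", stacklevel=2
        )
        norm = logx
    else:
        norm = _quantile_normalize_columns(logx)
    values = pd.DataFrame(norm, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(values=values, samples=matrix.samples, scale=LOG2)


def log2_transform(matrix: ExpressionMatrix, epsilon: float = 1.0) -> ExpressionMatrix:
    """Plain log2 transform (no quantile step); floors values <= 0 to epsilon."""
    if matrix.scale != LINEAR:
        raise ValueError("log2_transform expects a linear-scale matrix")
    x = matrix.values.to_numpy(dtype=float).copy()
    x[x <= 0] = epsilon
    values = pd.DataFrame(
        np.log2(x), index=matrix.values.index, columns=matrix.values.columns
    )
    return ExpressionMatrix(values=values, samples=matrix.samples, scale=LOG2)


def delog(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Return the matrix on the linear scale (2**values).

    Fold changes and average differences are defined on non-log values, so
    log2 matrices are de-logged before ranking.  A matrix that is already
    linear is returned unchanged with a warning.
    """
    if matrix.scale == LINEAR:
        warnings.warn("matrix already on linear scale; delog is a no-op", stacklevel=2)
        return matrix
    values = np.exp2(matrix.values)
    return ExpressionMatrix(values=values, samples=matrix.samples, scale=LINEAR)
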