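"""Cell-type deconvolution of bulk brain expression (marker-median DSA).

The Digital Sorting Algorithm models the signal of genes exclusive to one
cell type as proportional to that type's proportion in the mixture:
O[t, i] = g_t^{-1} * p[t, i].  Here the per-type signal is the *median*
CPM over the type's marker genes (robust variant), and the per-type scale
factors g are found by non-negative least squares on the constraint that
proportions sum to one in every sample.  Estimated proportions are clipped
to [0, 1] and renormalized per sample.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

CELL_TYPES = ("astrocyte", "endothelial", "microglia", "neuron", "oligodendrocyte")

__all__ = ["CELL_TYPES", "validate_markers", "filter_markers", "marker_median_signal", "dsa_estimate", "deconvolve"]


def validate_markers(markers: Mapping[str, Sequence[str]]) -> None:
    """Marker sets must be pairwise disjoint (exclusivity is the DSA premise)."""
    seen: dict[str, str] = {}
    for ct, genes in markers.items():
        for g in genes:
            if g in seen:
                raise ValueError(f"marker {g!r} assigned to both {seen[g]!r} and {ct!r}")
            seen[g] = ct


def filter_markers(
    expr: pd.DataFrame,
    markers: Mapping[str, Sequence[str]],
    min_mean_cpm: float = 2.0,
) -> dict[str, list[str]]:
    """Keep markers whose cross-sample mean expression is >= ``min_mean_cpm``.

    ``expr`` is samples x genes on the CPM scale.  Markers absent from the
    matrix are dropped.  A cell type losing every marker is an error.
    """
    validate_markers(markers)
    means = expr.mean(axis=0)
    out: dict[str, list[str]] = {}
    for ct, genes in markers.items():
        kept = [g for g in genes if g in means.index and means[g] >= min_mean_cpm]
        if not kept:
            raise ValueError(f"cell type {ct!r} has no marker passing mean >= {min_mean_cpm} cpm")
        out[ct] = kept
    return out


def marker_median_signal(expr: pd.DataFrame, markers: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Per-type median marker expression: O (cell types x samples)."""
    rows = {}
    for ct, genes in markers.items():
        missing = [g for g in genes if g not in expr.columns]
        if missing:
            raise KeyError(f"markers {missing} for {ct!r} absent from expression matrix")
        rows[ct] = expr[list(genes)].median(axis=1)
    return pd.DataFrame(rows).T


def dsa_estimate(O: pd.DataFrame) -> pd.DataFrame:
    """Solve for proportions from the marker-median signal matrix.

    Finds g >= 0 minimizing sum_i (sum_t g_t * O[t, i] - 1)^2, i.e. the
    non-negative least-squares solution of O^T g = 1; proportions are
    p[t, i] = g_t * O[t, i], clipped to [0, 1] and renormalized so each
    sample sums to one.  Returns samples x cell types.
    """
    A = O.to_numpy(dtype=float).T  # samples x types
    if np.any(A < 0):
        raise ValueError("signal matrix must be non-negative")
    if np.any(A.max(axis=0) <= 0):
        dead = O.index[np.where(A.max(axis=0) <= 0)[0]].tolist()
        raise ValueError(f"all-zero signal for cell types {dead}")
    g, residual = nnls(A, np.ones(A.shape[0]))
    if not np.all(np.isfinite(g)):
        raise RuntimeError(f"NNLS failed to converge (residual {residual})")
    P = A * g[None, :]
    P = np.clip(P, 0.0, 1.0)
    row_sums = P.sum(axis=1, keepdims=True)
    if np.any(row_sums <= 0):
        raise ValueError("a sample received zero total signal; cannot renormalize")
    P /= row_sums
    return pd.DataFrame(P, index=O.columns, columns=O.index)


def deconvolve(
    expr: pd.DataFrame,
    markers: Mapping[str, Sequence[str]],
    min_mean_cpm: float = 2.0,
) -> pd.DataFrame:
    """Full pipeline: filter markers, form median signals, solve DSA."""
    kept = filter_markers(expr, markers, min_mean_cpm)
    O = marker_median_signal(expr, kept)
    return dsa_estimate(O)
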