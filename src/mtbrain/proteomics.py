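"""Proteomic summary scores of mitochondrial mass and respiratory chain.

Three families of per-sample scores are computed from a (samples x proteins)
abundance matrix, each as the median of z-standardized member proteins:

* mitochondrial content — ten mitochondria-specific marker proteins
  (CS, LRPPRC, SLC25A24, TIMM44, GCDH, TRAP1, HSPD1, VDAC2, VDAC3, TOMM20);
* respiratory complexes I..V — detected subunits and assembly factors of
  each complex, weighted equally;
* mtDNA-encoded proteins — the 13 mitochondrially encoded respiratory
  subunits (11 typically detected by TMT proteomics).

Standardize-then-median makes every score invariant to affine rescaling of
any single protein column, and the median gives a breakdown point of one
half against corrupted member proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence
import warnings

import numpy as np
import pandas as pd

CONTENT_MARKERS = (
    "CS", "LRPPRC", "SLC25A24", "TIMM44", "GCDH",
    "TRAP1", "HSPD1", "VDAC2", "VDAC3", "TOMM20",
)
MTDNA_ENCODED = (
    "MT-ND1", "MT-ND2", "MT-ND3", "MT-ND4", "MT-ND5", "MT-ND6",
    "MT-CO1", "MT-CO2", "MT-CO3", "MT-ATP6", "MT-CYB",
)
COMPLEX_NAMES = ("complex_I", "complex_II", "complex_III", "complex_IV", "complex_V")

__all__ = [
    "CONTENT_MARKERS",
    "MTDNA_ENCODED",
    "ProteinScoreConfig",
    "score_median",
    "score_suite",
]


@dataclass
class ProteinScoreConfig:
    """Protein membership lists behind each score."""

    content_markers: Sequence[str] = CONTENT_MARKERS
    complex_membership: Mapping[str, Sequence[str]] = field(default_factory=dict)
    mtdna_encoded: Sequence[str] = MTDNA_ENCODED

    def __post_init__(self) -> None:
        if len(self.content_markers) != 10:
            raise ValueError("content marker list must have exactly 10 entries")
        if len(self.mtdna_encoded) != 11:
            raise ValueError("mtDNA-encoded list must have exactly 11 entries")


def _standardize(matrix: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    sd = matrix.std(axis=0, ddof=ddof)
    if (sd == 0).any():
        dead = sd.index[sd == 0].tolist()
        raise ValueError(f"constant protein columns cannot be standardized: {dead}")
    return (matrix - matrix.mean(axis=0)) / sd


def score_median(
    matrix: pd.DataFrame,
    protein_ids: Sequence[str],
    min_present: int = 3,
    *,
    ddof: int = 0,
) -> pd.Series:
    """Per-sample median of z-standardized abundances over ``protein_ids``.

    Proteins absent from the matrix are dropped with a warning (partial panels
    are normal for mass-spectrometry data); fewer than ``min_present`` present
    proteins is an error.
    """
    present = [p for p in protein_ids if p in matrix.columns]
    missing = sorted(set(protein_ids) - set(present))
    if missing:
        warnings.warn(f"proteins not detected, dropped from score: {missing}", stacklevel=2)
    if len(present) < min_present:
        raise ValueError(
            f"only {len(present)} of {len(protein_ids)} score proteins present; "
            f"need at least {min_present}"
        )
    z = _standardize(matrix[present], ddof=ddof)
    return z.median(axis=1)


def score_suite(matrix: pd.DataFrame, config: ProteinScoreConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All seven scores plus their pairwise Pearson correlation matrix.

    Returns ``(scores, correlations)`` where ``scores`` has columns
    ``content, complex_I..complex_V, mtdna_encoded`` indexed by sample.
    """
    scores = pd.DataFrame(index=matrix.index)
    scores["content"] = score_median(matrix, config.content_markers)
    for name in COMPLEX_NAMES:
        members = config.complex_membership.get(name)
        if members is None:
            raise ValueError(f"complex membership missing for {name!r}")
        scores[name] = score_median(matrix, members)
    scores["mtdna_encoded"] = score_median(matrix, config.mtdna_encoded)
    return scores, scores.corr(method="pearson")
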