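"""Mitochondrial DNA copy number (mtDNAcn) from WGS coverage.

The copy number of the mitochondrial genome per diploid nuclear genome is
estimated from whole-genome sequencing depth as

    mtDNAcn = 2 * cov_mt / cov_nuc

where ``cov_nuc`` is the median per-base depth over autosomal positions that
pass an ambiguity mask and ``cov_mt`` is the median per-base depth over the
mitochondrial contig.  The factor 2 converts the haploid-vs-diploid coverage
ratio into copies per diploid genome.

Raw estimates are comparable only within one extraction protocol, so for
cross-batch analyses they are natural-log transformed and z-standardized
within each batch (region x DNA-extraction-kit label).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CoverageSummary",
    "MtDNAcnEstimate",
    "masked_median_depth",
    "summarize_coverage",
    "estimate_mtdnacn",
    "normalize_mtdnacn",
]


class CoverageError(ValueError):
    """Raised when a coverage track / mask combination is unusable."""


@dataclass(frozen=True)
class CoverageSummary:
    """Masked median depths for the two contig classes of one sample."""

    cov_nuc: float
    cov_mt: float
    n_bases_nuc: int
    n_bases_mt: int

    def __post_init__(self) -> None:
        if self.cov_nuc < 0 or self.cov_mt < 0:
            raise CoverageError("median depths must be non-negative")
        if self.n_bases_nuc <= 0 or self.n_bases_mt <= 0:
            raise CoverageError("n_bases_used must be positive for both contig classes")


@dataclass(frozen=True)
class MtDNAcnEstimate:
    raw: float
    normalized: float
    batch: str


def _merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Merge possibly-overlapping half-open intervals given as an (n, 2) array."""
    if len(intervals) == 0:
        return intervals.reshape(0, 2)
    iv = intervals[np.argsort(intervals[:, 0])]
    merged = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged)


def _masked_length(start: int, end: int, mask: np.ndarray) -> int:
    """Number of positions of [start, end) covered by merged mask intervals."""
    total = 0
    for ms, me in mask:
        lo, hi = max(start, ms), min(end, me)
        if hi > lo:
            total += hi - lo
    return total


def _weighted_median(values: np.ndarray, weights: np.ndarray, tie: str) -> float:
    """Median of ``values`` each repeated ``weights`` times, without expansion.

    ``tie``: 'mean' averages the two central order statistics of an even-length
    expansion; 'lower' takes the lower one (integer-median emulation).
    """
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    n = cum[-1]
    if n % 2 == 1:
        k = (n + 1) // 2  # 1-based rank of the single middle element
        return float(v[np.searchsorted(cum, k)])
    k_lo, k_hi = n // 2, n // 2 + 1
    lo = v[np.searchsorted(cum, k_lo)]
    if tie == "lower":
        return float(lo)
    hi = v[np.searchsorted(cum, k_hi)]
    return float((lo + hi) / 2.0)


def masked_median_depth(
    track: pd.DataFrame,
    mask: pd.DataFrame | None,
    contigs: Sequence[str],
    *,
    apply_mask: bool = True,
    tie: str = "mean",
) -> tuple[float, int]:
    """Median per-base depth over ``contigs``, excluding masked positions.

    Parameters
    ----------
    track
        bedGraph-style frame with columns ``contig, start, end, depth``
        (0-based half-open intervals, non-overlapping within a contig).
    mask
        BED-style frame with columns ``contig, start, end`` marking positions
        to exclude, or None.  Ignored when ``apply_mask`` is False (the
        mitochondrial contig is never masked).
    contigs
        Contig names defining the contig class (autosomes or MT).

    Returns
    -------
    (median_depth, n_bases_used)
    """
    if tie not in ("mean", "lower"):
        raise ValueError(f"unknown tie convention {tie!r}")
    contig_set = set(contigs)
    sub = track[track["contig"].isin(contig_set)]
    if sub.empty or int((sub["end"] - sub["start"]).sum()) == 0:
        raise CoverageError(f"empty coverage track for contigs {sorted(contig_set)}")

    depths: list[float] = []
    weights: list[int] = []
    for contig, grp in sub.groupby("contig", sort=False):
        if apply_mask and mask is not None:
            m = mask[mask["contig"] == contig]
            merged = _merge_intervals(m[["start", "end"]].to_numpy(dtype=np.int64))
        else:
            merged = np.empty((0, 2), dtype=np.int64)
        for s, e, d in grp[["start", "end", "depth"]].itertuples(index=False):
            usable = (e - s) - _masked_length(int(s), int(e), merged)
            if usable > 0:
                depths.append(float(d))
                weights.append(int(usable))
    if not weights:
        raise CoverageError(
            f"all positions masked for contigs {sorted(contig_set)} "
            "(track non-empty, so the mask removed everything)"
        )
    return (
        _weighted_median(np.asarray(depths), np.asarray(weights, dtype=np.int64), tie),
        int(np.sum(weights)),
    )


def summarize_coverage(
    track: pd.DataFrame,
    mask: pd.DataFrame | None,
    nuclear_contigs: Sequence[str],
    mt_contig: str = "MT",
    *,
    tie: str = "mean",
) -> CoverageSummary:
    """Masked autosomal and (unmasked) mitochondrial median depths."""
    cov_nuc, n_nuc = masked_median_depth(track, mask, nuclear_contigs, tie=tie)
    cov_mt, n_mt = masked_median_depth(track, None, [mt_contig], apply_mask=False, tie=tie)
    return CoverageSummary(cov_nuc=cov_nuc, cov_mt=cov_mt, n_bases_nuc=n_nuc, n_bases_mt=n_mt)


def estimate_mtdnacn(cov_mt: float, cov_nuc: float) -> float:
    """Raw mtDNAcn, (cov_mt / cov_nuc) * 2."""
    if cov_nuc <= 0:
        raise ZeroDivisionError(
            f"cov_nuc must be positive to form the coverage ratio (got {cov_nuc})"
        )
    if cov_mt < 0:
        raise ValueError(f"cov_mt must be non-negative (got {cov_mt})")
    return 2.0 * cov_mt / cov_nuc


def normalize_mtdnacn(
    raw: Iterable[float],
    batches: Iterable[str],
    *,
    ddof: int = 0,
) -> pd.Series:
    """Natural-log transform then z-standardize raw mtDNAcn within each batch.

    Batches are region x extraction-kit labels.  Log first, z second: the
    reverse order is undefined because z-scores are negative for half the
    samples.  Population SD (``ddof=0``) by default so that re-standardizing
    an already-normalized batch is the identity.
    """
    raw = pd.Series(np.asarray(list(raw), dtype=float))
    batches = pd.Series(list(batches))
    if len(raw) != len(batches):
        raise ValueError("raw values and batch labels differ in length")
    if (raw <= 0).any():
        bad = raw.index[raw <= 0].tolist()
        raise ValueError(f"raw mtDNAcn must be > 0 to log-transform; offending rows {bad}")
    logged = np.log(raw)
    out = pd.Series(np.empty(len(raw)), index=raw.index, dtype=float)
    for batch, idx in batches.groupby(batches).groups.items():
        vals = logged.loc[idx]
        if len(vals) < 2:
            raise ValueError(f"batch {batch!r} has fewer than 2 samples")
        sd = vals.std(ddof=ddof)
        if sd == 0:
            raise ValueError(f"batch {batch!r} has zero variance after log transform")
        out.loc[idx] = (vals - vals.mean()) / sd
    return out


def mtdnacn_table(
    summaries: Mapping[str, CoverageSummary],
    batches: Mapping[str, str],
) -> pd.DataFrame:
    """Per-sample table: coverage medians, raw and normalized mtDNAcn, batch."""
    rows = []
    for sample_id, cs in summaries.items():
        rows.append(
            {
                "sample_id": sample_id,
                "cov_nuc": cs.cov_nuc,
                "cov_mt": cs.cov_mt,
                "raw": estimate_mtdnacn(cs.cov_mt, cs.cov_nuc),
                "batch": batches[sample_id],
            }
        )
    df = pd.DataFrame(rows)
    df["normalized"] = normalize_mtdnacn(df["raw"], df["batch"]).to_numpy()
    return df
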