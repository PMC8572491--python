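"""Heteroplasmic variant calling on the circular mitochondrial genome.

Point mutations and small indels (< 50 bp) are called from per-position
allele-count pileups of the 16,569-bp circular mitochondrial genome.  A
variant is classified heteroplasmic when its alternative-allele fraction
lies in the closed interval [0.03, 0.90]; fractions above 0.90 are treated
as homoplasmic-like, below 0.03 as noise.

Because a linear reference breaks the circle at an arbitrary origin, calls
near the junction are taken from a second pileup built against a reference
rotated by 8,000 bp, and the two call sets are merged: shifted-alignment
calls supply the control-region window (16024..16569 and 1..576, where the
artificial start/end falls), standard-alignment calls supply the rest.

Artifact filters mirror the roles of the usual external tools: a NUMT
filter drops variants whose absolute alternative read support is explicable
by a few nuclear copies of a mitochondrial insertion (alt reads <=
k * cov_nuc), and a contamination filter drops variants whose allele
fraction does not exceed a supplied sample contamination level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

MT_LENGTH = 16569
DEFAULT_SHIFT = 8000
#: Control region (D-loop), 1-based inclusive: 16024..16569 wrapping to 1..576.
CONTROL_REGION = ((16024, 16569), (1, 576))

BASES = ("A", "C", "G", "T")
#: Pileup allele columns; "ins"/"del" aggregate small (< 50 bp) indel alleles.
ALLELE_COLUMNS = BASES + ("ins", "del")

__all__ = [
    "MT_LENGTH",
    "DEFAULT_SHIFT",
    "CONTROL_REGION",
    "ALLELE_COLUMNS",
    "MtVariant",
    "in_control_region",
    "shifted_to_original",
    "call_candidates",
    "classify_heteroplasmy",
    "shift_merge",
    "filter_numt_contamination",
    "compute_burden",
    "annotate_and_enrich",
]


@dataclass
class MtVariant:
    """One mitochondrial variant call (1-based position, original coordinates)."""

    position: int
    ref: str
    alt: str
    alt_count: int
    depth: int
    filter_flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not 1 <= self.position <= MT_LENGTH:
            raise ValueError(f"position {self.position} outside 1..{MT_LENGTH}")
        if self.depth <= 0 or self.alt_count < 0 or self.alt_count > self.depth:
            raise ValueError("require 0 <= alt_count <= depth, depth > 0")

    @property
    def allele_fraction(self) -> float:
        return self.alt_count / self.depth

    @property
    def classification(self) -> str:
        if self.filter_flags:
            return "filtered"
        return "heteroplasmic"


def in_control_region(position: int) -> bool:
    return any(lo <= position <= hi for lo, hi in CONTROL_REGION)


def shifted_to_original(position: int, shift: int = DEFAULT_SHIFT, length: int = MT_LENGTH) -> int:
    """Map a 1-based position on the rotated reference back to the original.

    Position 1 of a reference shifted by ``shift`` corresponds to original
    position ``shift + 1``.
    """
    if not 1 <= position <= length:
        raise ValueError(f"position {position} outside 1..{length}")
    return (position + shift - 1) % length + 1


def _validate_pileup(counts: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("pos", "ref") + ALLELE_COLUMNS if c not in counts.columns]
    if missing:
        raise ValueError(f"pileup missing columns {missing}")
    return counts


def call_candidates(
    counts: pd.DataFrame,
    min_depth: int = 50,
    min_alt_reads: int = 3,
) -> list[MtVariant]:
    """Emit every non-reference allele passing the depth and read-support floor.

    No allele-fraction thresholding happens here; classification is a separate
    step so that candidate generation stays a pure counting operation.
    """
    _validate_pileup(counts)
    out: list[MtVariant] = []
    mat = counts[list(ALLELE_COLUMNS)].to_numpy(dtype=np.int64)
    depth = mat.sum(axis=1)
    positions = counts["pos"].to_numpy(dtype=np.int64)
    refs = counts["ref"].to_numpy()
    for i in range(len(counts)):
        if depth[i] < min_depth:
            continue
        for j, allele in enumerate(ALLELE_COLUMNS):
            if allele == refs[i]:
                continue
            c = int(mat[i, j])
            if c >= min_alt_reads:
                out.append(
                    MtVariant(
                        position=int(positions[i]),
                        ref=str(refs[i]),
                        alt=allele,
                        alt_count=c,
                        depth=int(depth[i]),
                    )
                )
    return out


def classify_heteroplasmy(
    variant: MtVariant,
    min_af: float = 0.03,
    max_af: float = 0.90,
) -> MtVariant:
    """Flag variants outside the closed heteroplasmic AF band [min_af, max_af]."""
    af = variant.allele_fraction
    if af < min_af:
        variant.filter_flags.add("low_maf")
    elif af > max_af:
        variant.filter_flags.add("homoplasmic_like")
    return variant


def shift_merge(
    calls_std: Iterable[MtVariant],
    calls_shifted: Iterable[MtVariant],
    shift: int = DEFAULT_SHIFT,
    length: int = MT_LENGTH,
) -> list[MtVariant]:
    """Merge standard- and shifted-reference call sets into original coordinates.

    The shifted alignment is authoritative inside the junction window (the
    control region, where the standard linearization breaks the circle); the
    standard alignment is authoritative elsewhere.  Output sorted by original
    position.
    """
    merged: list[MtVariant] = []
    for v in calls_std:
        if not in_control_region(v.position):
            merged.append(v)
    for v in calls_shifted:
        orig = shifted_to_original(v.position, shift, length)
        if in_control_region(orig):
            merged.append(
                MtVariant(
                    position=orig,
                    ref=v.ref,
                    alt=v.alt,
                    alt_count=v.alt_count,
                    depth=v.depth,
                    filter_flags=set(v.filter_flags),
                )
            )
    merged.sort(key=lambda v: (v.position, v.alt))
    return merged


def filter_numt_contamination(
    calls: Iterable[MtVariant],
    cov_nuc: float,
    cov_mt: float,
    contamination_level: float = 0.0,
    numt_multiplier: float = 2.0,
) -> list[MtVariant]:
    """Flag NUMT-explicable and contamination-explicable variants.

    A polymorphic nuclear copy of a mitochondrial segment contributes reads in
    proportion to nuclear depth, so alternative support not exceeding
    ``numt_multiplier * cov_nuc`` reads (default 2 nuclear copies) is flagged
    ``numt_suspect``.  Variants whose allele fraction does not exceed the
    sample's estimated contamination level are flagged
    ``contamination_suspect``.  Flags are independent predicates; both may fire.
    """
    if not 0 <= contamination_level < 1:
        raise ValueError("contamination_level must be in [0, 1)")
    out = []
    for v in calls:
        if v.alt_count <= numt_multiplier * cov_nuc:
            v.filter_flags.add("numt_suspect")
        if contamination_level > 0 and v.allele_fraction <= contamination_level:
            v.filter_flags.add("contamination_suspect")
        out.append(v)
    return out


def compute_burden(calls: Iterable[MtVariant]) -> int:
    """Number of variants classified heteroplasmic (the per-sample burden)."""
    return sum(1 for v in calls if v.classification == "heteroplasmic")


def burden_table(calls_by_sample: dict[str, list[MtVariant]]) -> pd.DataFrame:
    rows = []
    for sample_id, calls in calls_by_sample.items():
        het = [v for v in calls if v.classification == "heteroplasmic"]
        rows.append(
            {
                "sample_id": sample_id,
                "heteroplasmy_count": len(het),
                "n_control_region": sum(in_control_region(v.position) for v in het),
                "n_outside_control": sum(not in_control_region(v.position) for v in het),
            }
        )
    return pd.DataFrame(rows)


def _interval_length(intervals: Sequence[tuple[int, int]]) -> int:
    return sum(hi - lo + 1 for lo, hi in intervals)


def annotate_and_enrich(
    calls: Iterable[MtVariant],
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Per-feature heteroplasmy counts with binomial enrichment tests.

    ``annotation`` has columns ``feature, start, end`` (1-based inclusive,
    a feature may span several rows, e.g. the wrapped control region) and must
    tile 1..16,569 without overlaps.  Under positional uniformity a feature of
    length L_g holds Binomial(n, L_g / L) of the n heteroplasmic variants; the
    upper tail is the enrichment p-value, Bonferroni-adjusted over features.
    """
    need = {"feature", "start", "end"}
    if not need.issubset(annotation.columns):
        raise ValueError(f"annotation requires columns {sorted(need)}")
    covered = np.zeros(MT_LENGTH + 1, dtype=bool)
    for s, e in annotation[["start", "end"]].itertuples(index=False):
        s, e = int(s), int(e)
        if not (1 <= s <= e <= MT_LENGTH):
            raise ValueError(f"interval {s}..{e} outside 1..{MT_LENGTH}")
        if covered[s : e + 1].any():
            raise ValueError(f"annotation intervals overlap at {s}..{e}")
        covered[s : e + 1] = True
    if not covered[1:].all():
        raise ValueError("annotation does not cover all of 1..16569")

    het = [v for v in calls if v.classification == "heteroplasmic"]
    n_total = len(het)
    feat_of = np.empty(MT_LENGTH + 1, dtype=object)
    for f, s, e in annotation[["feature", "start", "end"]].itertuples(index=False):
        feat_of[int(s) : int(e) + 1] = f

    lengths = annotation.groupby("feature").apply(
        lambda g: int((g["end"] - g["start"] + 1).sum()), include_groups=False
    )
    counts = {f: 0 for f in lengths.index}
    for v in het:
        counts[feat_of[v.position]] += 1

    n_features = len(lengths)
    rows = []
    for f in lengths.index:
        k, L_g = counts[f], lengths[f]
        p = float(stats.binom.sf(k - 1, n_total, L_g / MT_LENGTH)) if n_total > 0 else 1.0
        rows.append(
            {
                "feature": f,
                "length": L_g,
                "count": k,
                "p_enrichment": p,
                "p_bonferroni": min(1.0, p * n_features),
            }
        )
    return pd.DataFrame(rows).sort_values("p_enrichment", ignore_index=True)


def default_annotation() -> pd.DataFrame:
    """A coarse feature map of the mitochondrial genome used for enrichment.

    The control region is exact (16024..16569 wrapping to 1..576); the coding
    interval 577..16023 is divided into contiguous blocks labeled after the
    canonical gene order.  Positions-only emulation: block boundaries are the
    canonical gene starts, adequate for enrichment bookkeeping on synthetic
    data, not a substitute for a curated annotation of real calls.
    """
    genes = [
        ("MT-RNR1", 648, 1601), ("MT-RNR2", 1671, 3229), ("MT-ND1", 3307, 4262),
        ("MT-ND2", 4470, 5511), ("MT-CO1", 5904, 7445), ("MT-CO2", 7586, 8269),
        ("MT-ATP8", 8366, 8572), ("MT-ATP6", 8527, 9207), ("MT-CO3", 9207, 9990),
        ("MT-ND3", 10059, 10404), ("MT-ND4L", 10470, 10766), ("MT-ND4", 10760, 12137),
        ("MT-ND5", 12337, 14148), ("MT-ND6", 14149, 14673), ("MT-CYB", 14747, 15887),
    ]
    rows = [
        {"feature": "CR", "start": 16024, "end": MT_LENGTH},
        {"feature": "CR", "start": 1, "end": 576},
    ]
    # tile 577..16023 contiguously: each block runs from a gene start to the
    # next gene start - 1 (the stretch before the first gene is non_coding)
    names = ["non_coding"] + [name for name, _, _ in genes]
    starts = [577] + [s for _, s, _ in genes]
    ends = [s - 1 for s in starts[1:]] + [16023]
    for name, s, e in zip(names, starts, ends):
        if e >= s:
            rows.append({"feature": name, "start": s, "end": e})
    return pd.DataFrame(rows)
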