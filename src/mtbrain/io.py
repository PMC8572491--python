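"""Readers and writers for the pipeline's plain-text interchange formats.

Coverage tracks are bedGraph-style TSV (contig, start, end, depth; 0-based
half-open), masks are 3-column BED, pileups are TSV with 1-based positions
and per-allele counts, variant calls are written as VCF 4.2 on chrM, and
tabular results are CSV.  Coordinate conversion (0-based file vs 1-based
in-memory) happens only at this boundary.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .heteroplasmy import ALLELE_COLUMNS, MtVariant

COVERAGE_COLUMNS = ["contig", "start", "end", "depth"]
BED_COLUMNS = ["contig", "start", "end"]


def read_coverage(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=COVERAGE_COLUMNS, comment="#")
    return df.astype({"start": int, "end": int, "depth": float})


def write_coverage(df: pd.DataFrame, path: str | Path) -> None:
    df[COVERAGE_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=BED_COLUMNS, comment="#")
    return df.astype({"start": int, "end": int})


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_pileup(path: str | Path) -> pd.DataFrame:
    """Pileup TSV: pos (1-based), ref, then A/C/G/T/ins/del counts."""
    df = pd.read_csv(path, sep="\t")
    needed = ["pos", "ref", *ALLELE_COLUMNS]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"pileup {path} missing columns {missing}")
    bad = df.index[df[list(ALLELE_COLUMNS)].lt(0).any(axis=1)]
    if len(bad):
        raise ValueError(f"pileup {path}: negative allele count at line {bad[0] + 2}")
    return df[needed]


def write_pileup(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


_VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chrM,length=16569>
##INFO=<ID=AF,Number=1,Type=Float,Description="Alternative allele fraction">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##FILTER=<ID=low_maf,Description="Allele fraction below the heteroplasmy floor">
##FILTER=<ID=homoplasmic_like,Description="Allele fraction above the heteroplasmy ceiling">
##FILTER=<ID=numt_suspect,Description="Alt support explicable by nuclear mitochondrial DNA">
##FILTER=<ID=contamination_suspect,Description="Allele fraction within the contamination level">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(calls: Iterable[MtVariant], path: str | Path) -> None:
    """Write calls as a minimal VCF 4.2; indel alleles use symbolic <INS>/<DEL>."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for v in sorted(calls, key=lambda v: (v.position, v.alt)):
            alt = {"ins": "<INS>", "del": "<DEL>"}.get(v.alt, v.alt)
            filt = ";".join(sorted(v.filter_flags)) if v.filter_flags else "PASS"
            fh.write(
                f"chrM\t{v.position}\t.\t{v.ref}\t{alt}\t.\t{filt}\t"
                f"AF={v.allele_fraction:.6f};DP={v.depth}\n"
            )


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Samples x features TSV with sample ids in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_markers(path: str | Path) -> dict[str, list[str]]:
    """Marker CSV with columns gene, cell_type."""
    df = pd.read_csv(path)
    return {ct: g["gene"].tolist() for ct, g in df.groupby("cell_type")}


def write_markers(markers: dict[str, list[str]], path: str | Path) -> None:
    rows = [{"gene": g, "cell_type": ct} for ct, genes in markers.items() for g in genes]
    pd.DataFrame(rows).to_csv(path, index=False)
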