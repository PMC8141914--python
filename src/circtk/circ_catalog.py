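"""circRNA catalogs: CCR clustering, support/size filters, BED I/O,
and intersection with externally produced circRNA lists.

A circRNA is identified everywhere by (chrom, strand, start, end) — the two
genomic coordinates of its circular junction plus the strand. Clustering is
exact-coordinate: CCRs supporting the same junction are counted, with no
fuzz window, which keeps identity well-defined for intersections and
orthology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .chimeric_detect import CircularChimericRead

logger = logging.getLogger("circtk")

__all__ = [
    "CircRNACandidate",
    "FilterConfig",
    "circ_id",
    "cluster_ccrs",
    "apply_ccr_threshold",
    "size_partition",
    "intersect_catalogs",
    "write_bed",
    "read_bed",
    "read_external_list",
]


@dataclass(frozen=True)
class CircRNACandidate:
    chrom: str
    strand: str
    start: int  # 1-based inclusive, lower junction coordinate
    end: int    # 1-based inclusive, higher junction coordinate
    ccr_count: int
    dataset_id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"circRNA {self.chrom}:{self.start}-{self.end}: start must be < end")
        if self.ccr_count < 1:
            raise ValueError("ccr_count must be >= 1")

    @property
    def genomic_size(self) -> int:
        return self.end - self.start + 1

    @property
    def key(self) -> tuple[str, str, int, int]:
        return (self.chrom, self.strand, self.start, self.end)


def circ_id(chrom: str, strand: str, start: int, end: int) -> str:
    """Canonical circRNA row id used in expression tables."""
    return f"{chrom}:{strand}:{start}:{end}"


@dataclass
class FilterConfig:
    """Catalog filter thresholds.

    ``min_ccr``: minimum CCR support to retain a clustered candidate.
    ``min_bsj``: minimum BSJ count after intersecting two external lists.
    ``min_segment``: minimum CCR segment reference span (used upstream).
    ``read_length`` feeds the size rule: candidates with genomic size
    < read_length/2 + 5 are excluded from annotation (kept in the catalog
    as "size_excluded").
    """

    min_ccr: int = 5
    min_bsj: int = 4
    min_segment: int = 15
    read_length: int | None = None

    def __post_init__(self) -> None:
        for name in ("min_ccr", "min_bsj", "min_segment"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def min_annotatable_size(self) -> float:
        if self.read_length is None:
            raise ValueError("read_length must be set to apply the size rule")
        return self.read_length / 2 + 5


# ---------------------------------------------------------------------------
# Clustering and filters
# ---------------------------------------------------------------------------

def cluster_ccrs(ccrs: Iterable[CircularChimericRead], dataset_id: str = ""
                 ) -> list[CircRNACandidate]:
    """Cluster CCRs on exact junction coordinates into candidates.

    One candidate per distinct (chrom, strand, start, end); ``ccr_count`` is
    the number of contributing reads. Output sorted by (chrom, start, end).
    """
    counts: dict[tuple[str, str, int, int], int] = {}
    for ccr in ccrs:
        key = (ccr.chrom, ccr.strand, ccr.junction_start, ccr.junction_end)
        counts[key] = counts.get(key, 0) + 1
    out = [CircRNACandidate(chrom, strand, start, end, n, dataset_id)
           for (chrom, strand, start, end), n in counts.items()]
    out.sort(key=lambda c: (c.chrom, c.start, c.end, c.strand))
    return out


def apply_ccr_threshold(candidates: Iterable[CircRNACandidate], min_ccr: int = 5
                        ) -> list[CircRNACandidate]:
    """Retain candidates supported by at least ``min_ccr`` CCRs."""
    return [c for c in candidates if c.ccr_count >= min_ccr]


def size_partition(candidates: Iterable[CircRNACandidate], config: FilterConfig
                   ) -> tuple[list[CircRNACandidate], list[CircRNACandidate]]:
    """Split candidates into (annotatable, size_excluded).

    Candidates with genomic size < read_length/2 + 5 are too small to be
    annotated reliably; they stay in the catalog (and in BED output) but are
    reported as unannotated with the "size_excluded" tag instead of being
    sent to the classifier.
    """
    cutoff = config.min_annotatable_size
    annotatable, excluded = [], []
    for c in candidates:
        (excluded if c.genomic_size < cutoff else annotatable).append(c)
    return annotatable, excluded


# ---------------------------------------------------------------------------
# Intersection of external catalogs
# ---------------------------------------------------------------------------

def read_external_list(path: str | Path, zero_based: bool = False) -> pd.DataFrame:
    """Read an externally produced circRNA list (TSV: chrom, start, end,
    strand, bsj). ``zero_based=True`` converts BED-style half-open input to
    the package's 1-based closed convention."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "strand", "bsj"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    df = df.copy()
    if zero_based:
        df["start"] = df["start"] + 1
    return df


def intersect_catalogs(list_a: pd.DataFrame, list_b: pd.DataFrame,
                       min_bsj: int = 4) -> pd.DataFrame:
    """Keep circRNAs present in both lists with BSJ >= ``min_bsj``.

    Identity is (chrom, strand, start, end); strand "." in either list
    matches either strand (logged as a lenient match). The BSJ threshold is
    applied after the intersection, on list A's counts (list A is treated
    as the quantification source).
    """
    for name, df in (("list_a", list_a), ("list_b", list_b)):
        if "bsj" not in df.columns:
            raise ValueError(f"{name}: missing BSJ column")

    def keyset(df: pd.DataFrame) -> tuple[set, set]:
        stranded, unstranded = set(), set()
        for row in df.itertuples(index=False):
            if row.strand == ".":
                unstranded.add((row.chrom, row.start, row.end))
            else:
                stranded.add((row.chrom, row.strand, row.start, row.end))
        return stranded, unstranded

    b_stranded, b_unstranded = keyset(list_b)
    lenient = 0
    rows = []
    for row in list_a.itertuples(index=False):
        if row.strand == ".":
            hit = (any((row.chrom, s, row.start, row.end) in b_stranded for s in "+-")
                   or (row.chrom, row.start, row.end) in b_unstranded)
            if hit:
                lenient += 1
        else:
            hit = (row.chrom, row.strand, row.start, row.end) in b_stranded
            if not hit and (row.chrom, row.start, row.end) in b_unstranded:
                hit = True
                lenient += 1
        if hit and row.bsj >= min_bsj:
            rows.append(row)
    if lenient:
        logger.info("intersect_catalogs: %d lenient strand matches", lenient)
    out = pd.DataFrame(rows, columns=list_a.columns)
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# BED I/O (the one 1-based <-> 0-based conversion point)
# ---------------------------------------------------------------------------

def write_bed(catalog: Sequence[CircRNACandidate], path: str | Path,
              chrom_sizes: dict[str, int] | None = None) -> None:
    """Write a catalog as BED6: 0-based half-open, name = "chrom:start|end"
    (1-based internal coordinates), score = ccr_count."""
    with open(path, "w") as fh:
        for c in catalog:
            if chrom_sizes is not None and c.end > chrom_sizes.get(c.chrom, c.end):
                logger.warning("%s:%d-%d exceeds declared size of %s",
                               c.chrom, c.start, c.end, c.chrom)
            name = f"{c.chrom}:{c.start}|{c.end}"
            fh.write(f"{c.chrom}\t{c.start - 1}\t{c.end}\t{name}\t{c.ccr_count}\t{c.strand}\n")


def read_bed(path: str | Path, dataset_id: str = "") -> list[CircRNACandidate]:
    """Read a BED6 catalog written by :func:`write_bed` (lossless round-trip)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}, line {lineno}: BED6 requires 6 columns")
            chrom, start0, end, _name, score, strand = fields[:6]
            out.append(CircRNACandidate(chrom, strand, int(start0) + 1, int(end),
                                        int(score), dataset_id))
    return out
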