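"""Parsing of STAR-style chimeric junction tables and CCR selection.

A circular chimeric read (CCR) is a read whose two split-alignment segments
map to the same chromosome and strand in inverted genomic order — the read
prefix aligns downstream of the read suffix — which is the signature of a
read crossing a back-splice junction. Selection requires both segments to
span at least ``min_segment`` reference bases (default 15 bp).

Junction coordinates are derived from segment start positions and CIGAR
reference spans, never from the file's donor/acceptor columns (those are
preserved verbatim for cross-checks only, since their semantics differ
across aligner versions).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "Segment",
    "ChimericAlignmentRecord",
    "CircularChimericRead",
    "SelectionReport",
    "ChimericParseError",
    "parse_chimeric_records",
    "ref_span",
    "select_ccrs",
    "junction_from_segments",
    "write_ccr_table",
]

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_REF_OPS = frozenset("MDN=X")
# tokens that identify a header line in column 1
_HEADER_TOKENS = {"chr_donorA", "chr_donora"}


class ChimericParseError(ValueError):
    pass


@dataclass(frozen=True)
class Segment:
    chrom: str
    strand: str
    ref_start: int  # 1-based leftmost reference base
    cigar: str


@dataclass(frozen=True)
class ChimericAlignmentRecord:
    """One line of a chimeric junction file: two aligned segments of one read.

    ``seg1`` is the read-prefix segment (segment A), ``seg2`` the read-suffix
    segment (segment B). The raw donor/acceptor breakpoint columns are kept
    verbatim in ``raw_donor`` / ``raw_acceptor``.
    """

    read_id: str
    seg1: Segment
    seg2: Segment
    junction_type: int
    raw_donor: str = ""
    raw_acceptor: str = ""


@dataclass(frozen=True)
class CircularChimericRead:
    read_id: str
    chrom: str
    strand: str
    junction_start: int  # lower genomic coordinate of the circle
    junction_end: int    # higher genomic coordinate
    seg_ref_spans: tuple[int, int]


@dataclass
class SelectionReport:
    """Counts of accepted CCRs and of rejections per reason."""

    accepted: int = 0
    rejects: Counter = field(default_factory=Counter)
    parse_rejects: int = 0

    def reject(self, reason: str) -> None:
        self.rejects[reason] += 1

    @property
    def total(self) -> int:
        return self.accepted + sum(self.rejects.values())


def ref_span(cigar: str) -> int:
    """Number of reference bases consumed by a CIGAR (M, D, N, =, X ops)."""
    pos = 0
    span = 0
    for m in _CIGAR_RE.finditer(cigar):
        if m.start() != pos:
            raise ValueError(f"unparseable CIGAR {cigar!r}")
        pos = m.end()
        if m.group(2) in _REF_OPS:
            span += int(m.group(1))
    if pos != len(cigar) or pos == 0:
        raise ValueError(f"unparseable CIGAR {cigar!r}")
    return span


def parse_chimeric_records(path: str | Path,
                           report: SelectionReport | None = None,
                           ) -> Iterator[ChimericAlignmentRecord]:
    """Stream records from a STAR-dialect ``chimeric.out.junction`` file.

    The classic 14-column dialect is required; extra trailing columns are
    tolerated. Comment lines and header lines are skipped. Lines with fewer
    than 14 columns raise :class:`ChimericParseError` naming the line number;
    lines whose CIGARs cannot be parsed are skipped and counted in
    ``report.parse_rejects``.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] in _HEADER_TOKENS:
                continue
            if len(fields) < 14:
                raise ChimericParseError(
                    f"{path.name}, line {lineno}: expected >=14 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                seg1 = Segment(fields[0], fields[2], int(fields[10]), fields[11])
                seg2 = Segment(fields[3], fields[5], int(fields[12]), fields[13])
                # validate CIGARs up front so bad records are rejected here
                ref_span(seg1.cigar)
                ref_span(seg2.cigar)
                record = ChimericAlignmentRecord(
                    read_id=fields[9],
                    seg1=seg1,
                    seg2=seg2,
                    junction_type=int(fields[6]),
                    raw_donor=fields[1],
                    raw_acceptor=fields[4],
                )
            except ValueError:
                if report is not None:
                    report.parse_rejects += 1
                continue
            yield record


def junction_from_segments(record: ChimericAlignmentRecord
                           ) -> tuple[str, str, int, int] | None:
    """Back-splice junction (chrom, strand, start, end) implied by the two
    segments, or None when the derived interval is inconsistent (start >= end).

    The read prefix maps to the 3' side of the circle: on ``+`` the junction
    end is the last reference base of seg1 and the start is seg2's first
    base; mirrored on ``-``.
    """
    strand = record.seg1.strand
    if strand == "+":
        end = record.seg1.ref_start + ref_span(record.seg1.cigar) - 1
        start = record.seg2.ref_start
    else:
        end = record.seg2.ref_start + ref_span(record.seg2.cigar) - 1
        start = record.seg1.ref_start
    if start >= end:
        return None
    return record.seg1.chrom, strand, start, end


def select_ccrs(records: Iterable[ChimericAlignmentRecord],
                min_segment: int = 15,
                collapse_read_stem: bool = False,
                splice_motif_types: frozenset[int] | None = None,
                report: SelectionReport | None = None,
                ) -> list[CircularChimericRead]:
    """Select circular chimeric reads from parsed chimeric records.

    Retention requires same chromosome, same strand, inverted segment order
    (read prefix downstream of read suffix on ``+``; mirrored on ``-``) and
    both segment reference spans >= ``min_segment``. Each read counts as one
    CCR; ``collapse_read_stem`` keeps a single CCR per read-name stem (the
    part before the last ``/``), for independently mapped mates of one
    fragment. ``splice_motif_types``, when given, restricts to those
    junction_type codes.
    """
    if report is None:
        report = SelectionReport()
    out: list[CircularChimericRead] = []
    seen_stems: set[tuple[str, str, str, int, int]] = set()
    for rec in records:
        if rec.seg1.chrom != rec.seg2.chrom:
            report.reject("trans_chromosome")
            continue
        if rec.seg1.strand != rec.seg2.strand:
            report.reject("strand_mismatch")
            continue
        if splice_motif_types is not None and rec.junction_type not in splice_motif_types:
            report.reject("junction_type")
            continue
        strand = rec.seg1.strand
        inverted = (rec.seg1.ref_start > rec.seg2.ref_start if strand == "+"
                    else rec.seg1.ref_start < rec.seg2.ref_start)
        if not inverted:
            report.reject("not_inverted")
            continue
        span1 = ref_span(rec.seg1.cigar)
        span2 = ref_span(rec.seg2.cigar)
        if min(span1, span2) < min_segment:
            report.reject("segment_too_short")
            continue
        junction = junction_from_segments(rec)
        if junction is None:
            report.reject("inconsistent_junction")
            continue
        chrom, strand, start, end = junction
        if collapse_read_stem:
            stem = rec.read_id.rsplit("/", 1)[0]
            key = (stem, chrom, strand, start, end)
            if key in seen_stems:
                report.reject("duplicate_mate")
                continue
            seen_stems.add(key)
        report.accepted += 1
        out.append(CircularChimericRead(rec.read_id, chrom, strand, start, end,
                                        (span1, span2)))
    return out


def write_ccr_table(ccrs: Iterable[CircularChimericRead], path: str | Path) -> None:
    """TSV dump: read_id, chrom, strand, start, end, span1, span2."""
    with open(path, "w") as fh:
        fh.write("read_id\tchrom\tstrand\tstart\tend\tspan1\tspan2\n")
        for c in ccrs:
            fh.write(f"{c.read_id}\t{c.chrom}\t{c.strand}\t{c.junction_start}\t"
                     f"{c.junction_end}\t{c.seg_ref_spans[0]}\t{c.seg_ref_spans[1]}\n")
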