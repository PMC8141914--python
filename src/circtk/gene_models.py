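"""Gene annotation models: genes, transcripts, exons, derived introns.

Loads Ensembl-style GTF/GFF3 annotation into a lightweight in-memory model,
derives per-transcript introns from adjacent exon pairs, and builds
interval-tree indexes used by the circRNA classifier.

All coordinates are 1-based, fully closed (GTF convention); the single
conversion to 0-based half-open happens at BED emission in
:mod:`circtk.circ_catalog`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from gffutils.feature import feature_from_line
from intervaltree import IntervalTree

logger = logging.getLogger("circtk")

__all__ = [
    "Exon",
    "Transcript",
    "Gene",
    "GeneModelSet",
    "IntronRecord",
    "FeatureIndex",
    "AnnotationParseError",
    "load_gene_models",
    "derive_introns",
    "build_feature_index",
    "write_intron_table",
]


class AnnotationParseError(ValueError):
    """Raised when a GTF/GFF3 line cannot be parsed; carries the line number."""


@dataclass(frozen=True)
class Exon:
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    exon_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"exon {self.exon_id}: start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Transcript:
    transcript_id: str
    exons: list[Exon] = field(default_factory=list)

    def sort_exons(self) -> None:
        self.exons.sort(key=lambda e: e.start)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0].start, self.exons[-1].end


@dataclass
class Gene:
    gene_id: str
    biotype: str
    chrom: str
    strand: str
    transcripts: dict[str, Transcript] = field(default_factory=dict)

    @property
    def span(self) -> tuple[int, int]:
        starts = [t.span[0] for t in self.transcripts.values() if t.exons]
        ends = [t.span[1] for t in self.transcripts.values() if t.exons]
        return min(starts), max(ends)


@dataclass
class GeneModelSet:
    """All genes of one annotation, keyed by gene_id."""

    genes: dict[str, Gene] = field(default_factory=dict)
    n_orphan_exons: int = 0  # exon lines without a resolvable parent transcript

    def __len__(self) -> int:
        return len(self.genes)

    def iter_exons(self) -> Iterator[tuple[Gene, Transcript, Exon]]:
        for gene in self.genes.values():
            for tx in gene.transcripts.values():
                for exon in tx.exons:
                    yield gene, tx, exon

    @property
    def n_transcripts(self) -> int:
        return sum(len(g.transcripts) for g in self.genes.values())

    @property
    def n_exons(self) -> int:
        return sum(len(t.exons) for g in self.genes.values() for t in g.transcripts.values())


@dataclass(frozen=True)
class IntronRecord:
    """One distinct intron (coordinates deduplicated across transcripts).

    ``donor_pos`` is the strand-aware first intronic base at the 5' side of
    the intron, ``acceptor_pos`` the last intronic base at the 3' side:
    on ``+`` donor == start / acceptor == end, mirrored on ``-``.
    ``attributions`` lists every (gene_id, transcript_id) pair whose adjacent
    exons define this intron.
    """

    chrom: str
    strand: str
    start: int
    end: int
    gene_id: str
    transcript_id: str
    attributions: tuple[tuple[str, str], ...] = ()

    @property
    def donor_pos(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def acceptor_pos(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def _detect_dialect(path: Path) -> str:
    """Return 'gff3' or 'gtf' from the first attribute column seen."""
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                continue
            attrs = fields[8]
            # GTF: key "value"; GFF3: key=value
            if "=" in attrs.split(";")[0] and '"' not in attrs.split(";")[0]:
                return "gff3"
            return "gtf"
    return "gtf"


def _strip_prefix(identifier: str) -> str:
    # Ensembl GFF3 uses ID=gene:ENSG..., Parent=transcript:ENST...
    return identifier.split(":", 1)[1] if ":" in identifier else identifier


def load_gene_models(annotation_path: str | Path) -> GeneModelSet:
    """Load a GTF or GFF3 annotation (dialect auto-detected).

    Exon features must carry gene/transcript identifiers (GTF attributes or
    GFF3 Parent chains). Unknown biotypes are preserved verbatim; exons whose
    parent transcript cannot be resolved are skipped and counted in
    ``GeneModelSet.n_orphan_exons``.
    """
    path = Path(annotation_path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = _detect_dialect(path)

    models = GeneModelSet()
    # GFF3 bookkeeping: feature hierarchy resolved in a second pass
    gff_genes: dict[str, dict] = {}
    gff_tx_parent: dict[str, str] = {}
    gff_exons: list[tuple[str, Exon, str]] = []  # (parent transcript, exon, strand)
    exon_serial = 0

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise AnnotationParseError(
                    f"{path.name}, line {lineno}: expected 9 tab-separated columns, got {len(fields)}"
                )
            try:
                feat = feature_from_line(line, dialect=None)
            except Exception as exc:  # gffutils raises assorted types
                raise AnnotationParseError(f"{path.name}, line {lineno}: {exc}") from exc

            ftype = feat.featuretype
            attrs = feat.attributes

            def first(*keys: str) -> str | None:
                for k in keys:
                    if k in attrs and attrs[k]:
                        return attrs[k][0]
                return None

            if dialect == "gtf":
                if ftype != "exon":
                    continue
                gene_id = first("gene_id")
                tx_id = first("transcript_id")
                if gene_id is None or tx_id is None:
                    models.n_orphan_exons += 1
                    continue
                biotype = first("gene_biotype", "biotype", "gene_type") or "unknown"
                exon_serial += 1
                exon_id = first("exon_id") or f"{tx_id}.exon{exon_serial}"
                gene = models.genes.setdefault(
                    gene_id, Gene(gene_id, biotype, feat.seqid, feat.strand)
                )
                tx = gene.transcripts.setdefault(tx_id, Transcript(tx_id))
                tx.exons.append(Exon(feat.seqid, feat.start, feat.end, exon_id))
            else:  # gff3
                fid = first("ID")
                parent = first("Parent")
                biotype = first("biotype", "gene_biotype")
                if ftype == "gene" or (fid and fid.startswith("gene:")):
                    gid = _strip_prefix(fid) if fid else None
                    if gid:
                        gff_genes[gid] = {
                            "biotype": biotype or "unknown",
                            "chrom": feat.seqid,
                            "strand": feat.strand,
                        }
                elif ftype == "exon":
                    if parent is None:
                        models.n_orphan_exons += 1
                        continue
                    exon_serial += 1
                    exon_id = first("exon_id", "Name") or f"exon{exon_serial}"
                    gff_exons.append(
                        (_strip_prefix(parent), Exon(feat.seqid, feat.start, feat.end, exon_id), feat.strand)
                    )
                elif parent is not None and fid is not None:
                    # transcript-level feature (mRNA, lnc_RNA, transcript, ...)
                    gff_tx_parent[_strip_prefix(fid)] = _strip_prefix(parent)

    if dialect == "gff3":
        for tx_id, exon, strand in gff_exons:
            gid = gff_tx_parent.get(tx_id)
            if gid is None or gid not in gff_genes:
                models.n_orphan_exons += 1
                continue
            info = gff_genes[gid]
            gene = models.genes.setdefault(
                gid, Gene(gid, info["biotype"], info["chrom"], info["strand"])
            )
            gene.transcripts.setdefault(tx_id, Transcript(tx_id)).exons.append(exon)

    for gene in models.genes.values():
        for tx in gene.transcripts.values():
            tx.sort_exons()
    if models.n_orphan_exons:
        logger.warning("%s: skipped %d exon line(s) without parent transcript",
                       path.name, models.n_orphan_exons)
    return models


# ---------------------------------------------------------------------------
# Intron derivation
# ---------------------------------------------------------------------------

def derive_introns(models: GeneModelSet) -> list[IntronRecord]:
    """One intron per adjacent exon pair per transcript.

    Introns sharing (chrom, strand, start, end) across transcripts are
    deduplicated into a single record that retains every (gene, transcript)
    attribution. Mono-exonic transcripts yield none. Overlapping exons within
    a transcript indicate an inconsistent annotation and raise ``ValueError``.
    """
    by_coord: dict[tuple[str, str, int, int], list[tuple[str, str]]] = {}
    order: list[tuple[str, str, int, int]] = []
    for gene in models.genes.values():
        for tx in gene.transcripts.values():
            exons = tx.exons
            for left, right in zip(exons, exons[1:]):
                if right.start <= left.end:
                    raise ValueError(
                        f"transcript {tx.transcript_id}: exons [{left.start}-{left.end}] and "
                        f"[{right.start}-{right.end}] overlap"
                    )
                key = (gene.chrom, gene.strand, left.end + 1, right.start - 1)
                if key not in by_coord:
                    by_coord[key] = []
                    order.append(key)
                by_coord[key].append((gene.gene_id, tx.transcript_id))
    records = []
    for key in order:
        chrom, strand, start, end = key
        attributions = tuple(by_coord[key])
        records.append(
            IntronRecord(chrom, strand, start, end,
                         gene_id=attributions[0][0], transcript_id=attributions[0][1],
                         attributions=attributions)
        )
    return records


def write_intron_table(introns: Iterable[IntronRecord], path: str | Path) -> None:
    """Dump derived introns as TSV (chrom, start, end, strand, gene_id, transcript_id)."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\tgene_id\ttranscript_id\n")
        for i in introns:
            fh.write(f"{i.chrom}\t{i.start}\t{i.end}\t{i.strand}\t{i.gene_id}\t{i.transcript_id}\n")


# ---------------------------------------------------------------------------
# Feature index
# ---------------------------------------------------------------------------

class FeatureIndex:
    """Interval indexes over exons, introns and gene spans plus
    exact-coordinate lookups for exon starts/ends and intron donors.

    Interval trees are half-open internally; public queries take 1-based
    closed intervals like the rest of the package.
    """

    def __init__(self, models: GeneModelSet, introns: list[IntronRecord] | None = None):
        self.models = models
        self.introns = derive_introns(models) if introns is None else introns

        self._exon_trees: dict[str, IntervalTree] = {}
        self._intron_trees: dict[str, IntervalTree] = {}
        self._gene_trees: dict[str, IntervalTree] = {}
        # exact boundary lookups keyed by (chrom, strand, pos)
        self._exon_starts: dict[tuple[str, str, int], list[tuple[Gene, Exon]]] = {}
        self._exon_ends: dict[tuple[str, str, int], list[tuple[Gene, Exon]]] = {}
        self._donors: dict[tuple[str, str, int], list[IntronRecord]] = {}

        seen_exons: set[tuple[str, str, int, int, str, str]] = set()
        for gene, tx, exon in models.iter_exons():
            key = (exon.chrom, gene.strand, exon.start, exon.end, exon.exon_id, gene.gene_id)
            if key in seen_exons:
                continue
            seen_exons.add(key)
            tree = self._exon_trees.setdefault(exon.chrom, IntervalTree())
            tree.addi(exon.start, exon.end + 1, (gene, exon))
            self._exon_starts.setdefault((exon.chrom, gene.strand, exon.start), []).append((gene, exon))
            self._exon_ends.setdefault((exon.chrom, gene.strand, exon.end), []).append((gene, exon))

        for intron in self.introns:
            tree = self._intron_trees.setdefault(intron.chrom, IntervalTree())
            tree.addi(intron.start, intron.end + 1, intron)
            self._donors.setdefault((intron.chrom, intron.strand, intron.donor_pos), []).append(intron)

        for gene in models.genes.values():
            if not any(t.exons for t in gene.transcripts.values()):
                continue
            lo, hi = gene.span
            tree = self._gene_trees.setdefault(gene.chrom, IntervalTree())
            tree.addi(lo, hi + 1, gene)

    # -- overlap queries (1-based closed intervals) --------------------------

    def exons_overlapping(self, chrom: str, start: int, end: int) -> list[tuple[Gene, Exon]]:
        tree = self._exon_trees.get(chrom)
        return [iv.data for iv in tree.overlap(start, end + 1)] if tree else []

    def introns_overlapping(self, chrom: str, start: int, end: int) -> list[IntronRecord]:
        tree = self._intron_trees.get(chrom)
        return [iv.data for iv in tree.overlap(start, end + 1)] if tree else []

    def genes_overlapping(self, chrom: str, start: int, end: int) -> list[Gene]:
        tree = self._gene_trees.get(chrom)
        return [iv.data for iv in tree.overlap(start, end + 1)] if tree else []

    # -- exact boundary lookups ----------------------------------------------

    def exons_starting_at(self, chrom: str, strand: str, pos: int) -> list[tuple[Gene, Exon]]:
        return self._exon_starts.get((chrom, strand, pos), [])

    def exons_ending_at(self, chrom: str, strand: str, pos: int) -> list[tuple[Gene, Exon]]:
        return self._exon_ends.get((chrom, strand, pos), [])

    def introns_with_donor(self, chrom: str, strand: str, pos: int) -> list[IntronRecord]:
        return self._donors.get((chrom, strand, pos), [])

    def has_chromosome(self, chrom: str) -> bool:
        return chrom in self._exon_trees or chrom in self._intron_trees or chrom in self._gene_trees


def build_feature_index(models: GeneModelSet,
                        introns: list[IntronRecord] | None = None) -> FeatureIndex:
    """Build the exon/intron/gene interval index for a model set."""
    return FeatureIndex(models, introns)
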