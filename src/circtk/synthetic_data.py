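"""Self-contained synthetic fixtures with planted ground truth.

Generates toy genomes (multi-exon genes, mono-exonic genes, an rRNA gene,
intergenic space), chimeric junction files with circular chimeric reads
planted for every circRNA class at controlled support counts (plus decoy
records that must never be detected), diverged second genomes with a truth
ortholog map, and negative-binomial count matrices with batch structure.

Chimeric records are synthesized directly at the junction-table level, where
the detection contract starts, so no aligner is ever needed. One random
generator is seeded per spec; all draws flow from it, making every fixture
bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .circ_catalog import CircRNACandidate, circ_id
from .gene_models import Exon, Gene, GeneModelSet, Transcript, derive_introns
from .quant_compare import ExpressionTable

__all__ = [
    "GeneSpec",
    "PlantedCirc",
    "DecoyPlan",
    "SimulationSpec",
    "SyntheticGenome",
    "default_spec",
    "make_genome",
    "plant_chimeric_file",
    "make_ortholog_genome",
    "make_rbh_fixture",
    "simulate_count_matrix",
    "expected_primary_class",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class GeneSpec:
    biotype: str = "protein_coding"
    n_exons: int = 4
    strand: str = "+"
    exon_len: tuple[int, int] = (80, 250)
    intron_len: tuple[int, int] = (200, 800)


@dataclass(frozen=True)
class PlantedCirc:
    """One circRNA to plant. ``circ_class`` is the planting geometry:
    exonic, sub_exonic_sense, sub_exonic_antisense, sub_exonic_rrna,
    intronic, intergenic, multi_gene, size_excluded."""

    circ_class: str
    ccr_count: int = 5
    acceptor_offset: int = 0      # intronic only
    size: int | None = None       # sub-exonic / intergenic / size_excluded


@dataclass(frozen=True)
class DecoyPlan:
    """Chimeric records that must never yield a CCR, plus low-support
    circles that cluster but fall below the retention threshold."""

    linear: int = 10          # two segments in normal (non-inverted) order
    trans_chrom: int = 5      # segments on different chromosomes
    strand_mismatch: int = 5  # segments on opposite strands
    short_segment: int = 5    # inverted order but a 14 bp segment
    low_support: int = 3      # real junction geometry, ccr_count < 5


@dataclass
class SimulationSpec:
    seed: int = 0
    n_chroms: int = 2
    intergenic_gap: tuple[int, int] = (1_500, 3_000)
    genes: tuple[GeneSpec, ...] = ()
    planted_circs: tuple[PlantedCirc, ...] = ()
    decoys: DecoyPlan = field(default_factory=DecoyPlan)
    read_length: int = 100
    min_segment: int = 15
    divergence: float = 0.05

    @property
    def min_annotatable_size(self) -> int:
        return math.ceil(self.read_length / 2 + 5)


def default_spec(seed: int = 0) -> SimulationSpec:
    """The standard study-like scenario: a toy genome with multi-exon coding
    genes, a lncRNA, a pseudogene, mono-exonic genes (incl. mitochondrial-
    style), one rRNA gene and one ribozyme, with >=30 circles planted across
    every class plus the full decoy set. Read length 100 bp (the dominant
    2x100 configuration of the emulated datasets)."""
    genes = (
        GeneSpec("protein_coding", 6, "+"),
        GeneSpec("protein_coding", 5, "-"),
        GeneSpec("protein_coding", 8, "+"),
        GeneSpec("protein_coding", 4, "-"),
        GeneSpec("protein_coding", 7, "+"),   # same strand/chrom as gene 0 -> multi_gene host
        GeneSpec("lncRNA", 4, "+"),
        GeneSpec("pseudogene", 3, "-"),
        GeneSpec("protein_coding", 1, "+", exon_len=(600, 900)),  # mono-exonic (mt-style)
        GeneSpec("rRNA", 1, "+", exon_len=(300, 500)),
        GeneSpec("ribozyme", 1, "-", exon_len=(250, 400)),
    )
    planted = (
        tuple(PlantedCirc("exonic", ccr_count=n) for n in (5, 6, 7, 8, 9, 10, 12, 15, 20, 30))
        + tuple(PlantedCirc("sub_exonic_sense", ccr_count=n) for n in (5, 7, 9, 11, 13, 17))
        + (PlantedCirc("sub_exonic_antisense", ccr_count=6),
           PlantedCirc("sub_exonic_antisense", ccr_count=8),
           PlantedCirc("intronic", ccr_count=5, acceptor_offset=0),
           PlantedCirc("intronic", ccr_count=7, acceptor_offset=5),
           PlantedCirc("intronic", ccr_count=9, acceptor_offset=30),
           PlantedCirc("intronic", ccr_count=6, acceptor_offset=60),
           PlantedCirc("intronic", ccr_count=8, acceptor_offset=61),  # beyond tolerance
           PlantedCirc("intergenic", ccr_count=5),
           PlantedCirc("intergenic", ccr_count=6),
           PlantedCirc("intergenic", ccr_count=9),
           PlantedCirc("intergenic", ccr_count=12),
           PlantedCirc("multi_gene", ccr_count=7),
           PlantedCirc("sub_exonic_rrna", ccr_count=10),
           PlantedCirc("size_excluded", ccr_count=8, size=40),
           PlantedCirc("size_excluded", ccr_count=5, size=54))
    )
    return SimulationSpec(seed=seed, genes=genes, planted_circs=planted)


def expected_primary_class(p: PlantedCirc, acceptor_tolerance: int = 60) -> str:
    """Primary class the annotator must assign to a planted circle."""
    if p.circ_class == "exonic":
        return "exonic"
    if p.circ_class in ("sub_exonic_sense", "sub_exonic_antisense"):
        return "sub_exonic"
    if p.circ_class == "intronic":
        return "intronic" if p.acceptor_offset <= acceptor_tolerance else "unannotated"
    if p.circ_class == "size_excluded":
        return "size_excluded"
    return "unannotated"  # intergenic, multi_gene, sub_exonic_rrna


# ---------------------------------------------------------------------------
# Genome + annotation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGenome:
    sequences: dict[str, str]
    models: GeneModelSet
    gene_chrom: dict[str, str]
    intergenic: list[tuple[str, int, int]]  # gene-free intervals per chrom

    def fasta_text(self) -> str:
        out = []
        for chrom, seq in self.sequences.items():
            out.append(f">{chrom}")
            out.extend(seq[i:i + 70] for i in range(0, len(seq), 70))
        return "\n".join(out) + "\n"

    def gtf_text(self) -> str:
        lines = []
        for gene in self.models.genes.values():
            lo, hi = gene.span
            attrs = f'gene_id "{gene.gene_id}"; gene_biotype "{gene.biotype}";'
            lines.append("\t".join([gene.chrom, "circtk_sim", "gene", str(lo), str(hi),
                                    ".", gene.strand, ".", attrs]))
            for tx in gene.transcripts.values():
                tlo, thi = tx.span
                tattrs = attrs + f' transcript_id "{tx.transcript_id}";'
                lines.append("\t".join([gene.chrom, "circtk_sim", "transcript",
                                        str(tlo), str(thi), ".", gene.strand, ".", tattrs]))
                for exon in tx.exons:
                    eattrs = tattrs + f' exon_id "{exon.exon_id}";'
                    lines.append("\t".join([gene.chrom, "circtk_sim", "exon",
                                            str(exon.start), str(exon.end), ".",
                                            gene.strand, ".", eattrs]))
        return "\n".join(lines) + "\n"

    def write(self, outdir: str | Path) -> tuple[Path, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = outdir / "genome.fa"
        gtf = outdir / "annotation.gtf"
        fasta.write_text(self.fasta_text())
        gtf.write_text(self.gtf_text())
        return fasta, gtf


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def make_genome(spec: SimulationSpec) -> SyntheticGenome:
    """Lay the spec's genes down chromosome by chromosome (round-robin,
    non-overlapping, separated by intergenic gaps) over random sequence."""
    rng = np.random.default_rng(spec.seed)
    models = GeneModelSet()
    gene_chrom: dict[str, str] = {}
    cursors = {f"chr{i + 1}": 1_001 for i in range(spec.n_chroms)}
    intergenic = [(c, 1, 1_000) for c in cursors]
    chrom_names = list(cursors)

    for gi, gspec in enumerate(spec.genes):
        chrom = chrom_names[gi % spec.n_chroms]
        gene_id = f"G{gi + 1}"
        tx_id = f"{gene_id}.t1"
        pos = cursors[chrom]
        exons = []
        for ei in range(gspec.n_exons):
            elen = int(rng.integers(gspec.exon_len[0], gspec.exon_len[1] + 1))
            exons.append(Exon(chrom, pos, pos + elen - 1, f"{gene_id}.e{ei + 1}"))
            pos += elen
            if ei < gspec.n_exons - 1:
                pos += int(rng.integers(gspec.intron_len[0], gspec.intron_len[1] + 1))
        gap = int(rng.integers(*spec.intergenic_gap))
        intergenic.append((chrom, pos + 1, pos + gap))
        cursors[chrom] = pos + gap + 1
        gene = Gene(gene_id, gspec.biotype, chrom, gspec.strand)
        tx = Transcript(tx_id, exons)
        tx.sort_exons()
        gene.transcripts[tx_id] = tx
        models.genes[gene_id] = gene
        gene_chrom[gene_id] = chrom

    sequences = {c: _random_seq(rng, cursors[c] + 2_000) for c in chrom_names}
    return SyntheticGenome(sequences, models, gene_chrom, intergenic)


# ---------------------------------------------------------------------------
# Planting circles and emitting the chimeric junction file
# ---------------------------------------------------------------------------

def _place_circles(spec: SimulationSpec, genome: SyntheticGenome,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Choose genomic coordinates for every planted circle; returns the truth
    table (circ_id, chrom, strand, start, end, circ_class, expected_class,
    parent_gene, ccr_count, acceptor_offset)."""
    models = genome.models
    introns = derive_introns(models)
    min_size = spec.min_annotatable_size
    used: set[tuple[str, str, int, int]] = set()
    rows = []

    genes = list(models.genes.values())
    multi_exon = [g for g in genes if g.biotype != "rRNA"
                  and any(len(t.exons) >= 2 for t in g.transcripts.values())]
    rrna = [g for g in genes if g.biotype == "rRNA"]
    gene_introns: dict[str, list] = {}
    for i in introns:
        gene_introns.setdefault(i.gene_id, []).append(i)

    def register(p: PlantedCirc, chrom: str, strand: str, start: int, end: int,
                 parent: str | None) -> None:
        key = (chrom, strand, start, end)
        if key in used:
            raise RuntimeError(f"planted junction collision at {key}; vary the spec seed")
        used.add(key)
        rows.append({
            "circ_id": circ_id(chrom, strand, start, end),
            "chrom": chrom, "strand": strand, "start": start, "end": end,
            "circ_class": p.circ_class,
            "expected_class": expected_primary_class(p),
            "parent_gene": parent or "",
            "ccr_count": p.ccr_count,
            "acceptor_offset": p.acceptor_offset if p.circ_class == "intronic" else -1,
        })

    exonic_cycle = 0
    for p in spec.planted_circs:
        if p.circ_class == "exonic":
            gene = multi_exon[exonic_cycle % len(multi_exon)]
            exons = next(iter(gene.transcripts.values())).exons
            for _ in range(50):
                i = int(rng.integers(0, len(exons)))
                j = int(rng.integers(i, len(exons)))
                start, end = exons[i].start, exons[j].end
                if (gene.chrom, gene.strand, start, end) not in used and end - start + 1 >= min_size:
                    break
            register(p, gene.chrom, gene.strand, start, end, gene.gene_id)
            exonic_cycle += 1
        elif p.circ_class in ("sub_exonic_sense", "sub_exonic_antisense", "sub_exonic_rrna"):
            pool = rrna if p.circ_class == "sub_exonic_rrna" else genes
            host = None
            for g in pool:
                if g.biotype == "rRNA" and p.circ_class != "sub_exonic_rrna":
                    continue
                for t in g.transcripts.values():
                    for e in t.exons:
                        if e.length >= min_size + 10:
                            host = (g, e)
                            break
                    if host:
                        break
                if host:
                    break
            if host is None:
                raise RuntimeError("no exon long enough for a sub-exonic plant")
            g, e = host
            for _ in range(100):
                size = p.size or int(rng.integers(min_size, min(e.length - 2, min_size + 80) + 1))
                start = e.start + int(rng.integers(1, e.length - size))
                end = start + size - 1
                strand = g.strand
                if p.circ_class == "sub_exonic_antisense":
                    strand = "-" if g.strand == "+" else "+"
                if e.start < start and end < e.end and (g.chrom, strand, start, end) not in used:
                    break
            register(p, g.chrom, strand, start, end, g.gene_id)
        elif p.circ_class == "intronic":
            host = None
            for gid, ilist in gene_introns.items():
                for intron in ilist:
                    if intron.length - p.acceptor_offset >= min_size:
                        key_try = None
                        if intron.strand == "+":
                            s, t = intron.start, intron.end - p.acceptor_offset
                        else:
                            s, t = intron.start + p.acceptor_offset, intron.end
                        if (intron.chrom, intron.strand, s, t) not in used:
                            host = (intron, s, t)
                            break
                if host:
                    break
            if host is None:
                raise RuntimeError("no intron long enough for an intronic plant")
            intron, start, end = host
            register(p, intron.chrom, intron.strand, start, end, intron.gene_id)
        elif p.circ_class in ("intergenic", "size_excluded"):
            size = p.size or int(rng.integers(min_size + 5, min_size + 150))
            if p.circ_class == "size_excluded" and size >= min_size:
                raise ValueError("size_excluded plant needs size below the annotatable minimum")
            placed = False
            for chrom, lo, hi in genome.intergenic:
                if hi - lo + 1 >= size + 2:
                    start = lo + 1
                    strand = "+" if rng.random() < 0.5 else "-"
                    while (chrom, strand, start, start + size - 1) in used and start + size <= hi:
                        start += size + 3
                    end = start + size - 1
                    if end <= hi and (chrom, strand, start, end) not in used:
                        register(p, chrom, strand, start, end, None)
                        placed = True
                        break
            if not placed:
                raise RuntimeError("no intergenic space left for a plant")
        elif p.circ_class == "multi_gene":
            host = None
            by_cs: dict[tuple[str, str], list[Gene]] = {}
            for g in genes:
                if g.biotype == "rRNA":
                    continue
                by_cs.setdefault((g.chrom, g.strand), []).append(g)
            for (chrom, strand), gs in by_cs.items():
                if len(gs) >= 2:
                    gs = sorted(gs, key=lambda g: g.span[0])
                    host = (gs[0], gs[1])
                    break
            if host is None:
                raise RuntimeError("multi_gene plant needs two same-strand genes on one chromosome")
            g_a, g_b = host
            exon_a = next(iter(g_a.transcripts.values())).exons[0]
            exon_b = next(iter(g_b.transcripts.values())).exons[-1]
            register(p, g_a.chrom, g_a.strand, exon_a.start, exon_b.end, None)
        else:
            raise ValueError(f"unknown planted class {p.circ_class!r}")

    return pd.DataFrame(rows)


def _ccr_line(rng: np.random.Generator, chrom: str, strand: str, start: int,
              end: int, read_id: str, read_length: int, min_segment: int) -> str:
    """One STAR-style chimeric line for a read crossing the (start, end)
    back-splice junction; segments stay within the circle, remainders are
    soft-clipped."""
    size = end - start + 1
    # a segment spanning the whole circle would start where the other starts,
    # breaking strict inversion; keep spans <= size - 1
    hi = min(read_length - min_segment, size - 1)
    len1 = int(rng.integers(min_segment, hi + 1)) if hi > min_segment else min_segment
    len2 = min(read_length - len1, size - 1)
    rest = read_length - len1 - len2
    tail = f"{rest}S" if rest else ""
    if strand == "+":
        seg1_start = end - len1 + 1               # read prefix ends at the circle's 3' edge
        seg2_start = start
        cig1 = f"{len1}M{read_length - len1}S"
        cig2 = f"{len1}S{len2}M{tail}"
    else:
        seg1_start = start                         # mirrored geometry on the minus strand
        seg2_start = end - len2 + 1
        cig1 = f"{read_length - len1}S{len1}M"
        cig2 = f"{tail}{len2}M{len1}S" if tail else f"{len2}M{len1}S"
    return "\t".join(map(str, [
        chrom, end + 1, strand, chrom, start - 1, strand, 1, 0, 0,
        read_id, seg1_start, cig1, seg2_start, cig2,
    ]))


def plant_chimeric_file(spec: SimulationSpec, genome: SyntheticGenome,
                        path: str | Path | None = None,
                        ) -> tuple[str, pd.DataFrame, pd.DataFrame]:
    """Emit a chimeric.out.junction file with the spec's planted circles and
    decoys. Returns (file text, truth table, low-support table); the truth
    table is a bijection with ``spec.planted_circs``. Line order is shuffled
    so detection cannot depend on emission order.
    """
    rng = np.random.default_rng(spec.seed + 1)
    truth = _place_circles(spec, genome, rng)
    lines: list[str] = []
    for row in truth.itertuples(index=False):
        for k in range(row.ccr_count):
            lines.append(_ccr_line(rng, row.chrom, row.strand, row.start, row.end,
                                   f"read_{row.circ_id}_{k}", spec.read_length,
                                   spec.min_segment))

    chroms = list(genome.sequences)
    used = {(r.chrom, r.strand, r.start, r.end) for r in truth.itertuples(index=False)}

    def random_locus(size_lo: int = 200, size_hi: int = 600) -> tuple[str, str, int, int]:
        while True:
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            limit = len(genome.sequences[chrom]) - size_hi - 1
            start = int(rng.integers(1, limit))
            end = start + int(rng.integers(size_lo, size_hi))
            strand = "+" if rng.random() < 0.5 else "-"
            if (chrom, strand, start, end) not in used:
                used.add((chrom, strand, start, end))
                return chrom, strand, start, end

    d = spec.decoys
    n = 0
    for _ in range(d.linear):  # normal-order split read (linear splice)
        chrom, strand, start, end = random_locus()
        # normal order is strand-aware: the read prefix maps upstream on "+",
        # downstream on "-"
        s1, s2 = (start, end) if strand == "+" else (end, start)
        lines.append("\t".join(map(str, [
            chrom, start, strand, chrom, end, strand, 1, 0, 0,
            f"decoy_linear_{n}", s1, "40M60S", s2, "40S60M"])))
        n += 1
    for _ in range(d.trans_chrom):
        c1, strand, start, end = random_locus()
        c2 = chroms[(chroms.index(c1) + 1) % len(chroms)]
        lines.append("\t".join(map(str, [
            c1, end, strand, c2, start, strand, -1, 0, 0,
            f"decoy_trans_{n}", end - 39, "40M60S", start, "40S60M"])))
        n += 1
    for _ in range(d.strand_mismatch):
        chrom, _, start, end = random_locus()
        lines.append("\t".join(map(str, [
            chrom, end, "+", chrom, start, "-", -1, 0, 0,
            f"decoy_strand_{n}", end - 39, "40M60S", start, "40S60M"])))
        n += 1
    for _ in range(d.short_segment):  # inverted order but a 14 bp segment
        chrom, _, start, end = random_locus()
        lines.append("\t".join(map(str, [
            chrom, end + 1, "+", chrom, start - 1, "+", 1, 0, 0,
            f"decoy_short_{n}", end - 13, "14M86S", start, "14S86M"])))
        n += 1

    low_rows = []
    for i in range(d.low_support):
        chrom, strand, start, end = random_locus(size_lo=80, size_hi=300)
        count = int(rng.integers(1, 5))  # below the 5-CCR retention threshold
        for k in range(count):
            lines.append(_ccr_line(rng, chrom, strand, start, end,
                                   f"lowsupport_{i}_{k}", spec.read_length,
                                   spec.min_segment))
        low_rows.append({"circ_id": circ_id(chrom, strand, start, end),
                         "chrom": chrom, "strand": strand, "start": start,
                         "end": end, "ccr_count": count})

    rng.shuffle(lines)
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text, truth, pd.DataFrame(low_rows)


# ---------------------------------------------------------------------------
# Diverged ortholog genome
# ---------------------------------------------------------------------------

def _mutate(seq: str, divergence: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(arr.size) < divergence
    idx = np.flatnonzero(hit)
    if idx.size:
        # substitute with a different base: shift 1-3 positions in ACGT order
        base_idx = np.searchsorted(_BASES, arr[idx])
        shift = rng.integers(1, 4, size=idx.size)
        arr[idx] = _BASES[(base_idx + shift) % 4]
    return arr.tobytes().decode()


def make_ortholog_genome(genome: SyntheticGenome, truth: pd.DataFrame,
                         divergence: float, seed: int,
                         drop_genes: Sequence[str] = (),
                         ) -> tuple[SyntheticGenome, list[tuple[str, str]], pd.DataFrame]:
    """Diverged copy of a genome with lifted annotation.

    Applies i.i.d. substitutions at ``divergence`` (no indels), renames each
    gene G to G_b (dropping ``drop_genes``), and returns the second genome,
    the one-to-one gene ortholog map, and the circRNA ortholog truth pairs
    (circles whose parent gene was dropped, or that lie on a dropped gene's
    chromosome-free copy, keep their coordinates but leave the truth table).
    """
    if not 0 <= divergence <= 0.3:
        raise ValueError("divergence must be in [0, 0.3]")
    rng = np.random.default_rng(seed)
    sequences_b = {c: _mutate(s, divergence, rng) for c, s in genome.sequences.items()}
    models_b = GeneModelSet()
    gene_map = []
    for gene in genome.models.genes.values():
        if gene.gene_id in drop_genes:
            continue
        gid_b = gene.gene_id + "_b"
        gene_b = Gene(gid_b, gene.biotype, gene.chrom, gene.strand)
        for tx in gene.transcripts.values():
            tx_b = Transcript(tx.transcript_id + "_b",
                              [replace(e, exon_id=e.exon_id + "_b") for e in tx.exons])
            gene_b.transcripts[tx_b.transcript_id] = tx_b
        models_b.genes[gid_b] = gene_b
        gene_map.append((gene.gene_id, gid_b))
    genome_b = SyntheticGenome(sequences_b, models_b,
                               {g: genome.gene_chrom[a] for a, g in gene_map},
                               genome.intergenic)
    rows = []
    dropped = set(drop_genes)
    for row in truth.itertuples(index=False):
        if row.parent_gene and row.parent_gene in dropped:
            continue
        rows.append({"circ_a": row.circ_id, "circ_b": row.circ_id,
                     "gene_a": row.parent_gene or "",
                     "gene_b": row.parent_gene + "_b" if row.parent_gene else ""})
    return genome_b, gene_map, pd.DataFrame(rows)


def make_rbh_fixture(n_pairs: int = 50, n_decoys_a: int = 50, n_decoys_b: int = 50,
                     divergence: float = 0.05, seed: int = 0,
                     circ_size: tuple[int, int] = (150, 400),
                     ) -> tuple[dict[str, str], dict[str, str],
                                list[CircRNACandidate], list[CircRNACandidate],
                                list[tuple[str, str]]]:
    """Two diverged single-chromosome genomes with ``n_pairs`` orthologous
    circles at shared loci plus species-specific decoy circles at loci that
    host no circle in the other species. Returns (genome_a, genome_b,
    catalog_a, catalog_b, truth_pairs)."""
    rng = np.random.default_rng(seed)
    spacing = circ_size[1] + 200
    total = (n_pairs + n_decoys_a + n_decoys_b) * spacing + 2_000
    seq_a = _random_seq(rng, total)
    seq_b = _mutate(seq_a, divergence, rng)
    genome_a = {"chr1": seq_a}
    genome_b = {"chr1": seq_b}

    loci = []
    pos = 1_000
    for _ in range(n_pairs + n_decoys_a + n_decoys_b):
        size = int(rng.integers(*circ_size))
        strand = "+" if rng.random() < 0.5 else "-"
        loci.append(("chr1", strand, pos, pos + size - 1))
        pos += spacing
    order = rng.permutation(len(loci))
    shared = [loci[i] for i in order[:n_pairs]]
    only_a = [loci[i] for i in order[n_pairs:n_pairs + n_decoys_a]]
    only_b = [loci[i] for i in order[n_pairs + n_decoys_a:]]

    def cand(locus, dataset):
        chrom, strand, start, end = locus
        return CircRNACandidate(chrom, strand, start, end, 5, dataset)

    catalog_a = [cand(l, "A") for l in shared + only_a]
    catalog_b = [cand(l, "B") for l in shared + only_b]
    truth = [(circ_id(*l[:2], l[2], l[3]), circ_id(*l[:2], l[2], l[3])) for l in shared]
    return genome_a, genome_b, catalog_a, catalog_b, truth


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

def simulate_count_matrix(circ_ids: Sequence[str],
                          batch_plan: Mapping[str, Sequence[str]],
                          depth_range: tuple[float, float] = (0.5, 2.0),
                          base_library: int = 20_000_000,
                          mean_log: float = 3.0, sigma_log: float = 1.0,
                          dispersion: float = 0.1,
                          seed: int = 0) -> ExpressionTable:
    """Negative-binomial counts per circRNA x dataset with batch structure.

    ``batch_plan`` maps batch_id -> dataset ids. Per-circ means are
    log-normal; each dataset gets a depth factor drawn from ``depth_range``
    that scales both its counts and its library size, so per-million plus
    TMM normalization should recover equal expression across datasets.
    """
    if not batch_plan or any(len(v) < 1 for v in batch_plan.values()):
        raise ValueError("every batch needs at least one dataset")
    rng = np.random.default_rng(seed)
    datasets = [d for ds in batch_plan.values() for d in ds]
    if len(set(datasets)) != len(datasets):
        raise ValueError("dataset ids must be unique across batches")
    means = rng.lognormal(mean_log, sigma_log, size=len(circ_ids))
    depth = rng.uniform(*depth_range, size=len(datasets))
    if (depth <= 0).any():
        raise ValueError("depth factors must be positive")
    r = 1.0 / dispersion
    counts = {}
    for j, ds in enumerate(datasets):
        mu = means * depth[j]
        p = r / (r + mu)
        counts[ds] = rng.negative_binomial(r, p)
    counts_df = pd.DataFrame(counts, index=list(circ_ids))
    lib = pd.Series({ds: float(base_library) * depth[j] for j, ds in enumerate(datasets)})
    batch_rows = []
    for batch_id, ds_list in batch_plan.items():
        for ds in ds_list:
            batch_rows.append({"dataset_id": ds, "species": "syn", "tissue": "syn",
                               "batch_id": batch_id})
    batch_map = pd.DataFrame(batch_rows).set_index("dataset_id")
    return ExpressionTable(counts_df, lib, batch_map)
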