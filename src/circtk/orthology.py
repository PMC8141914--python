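"""Cross-species orthologous circRNA detection.

Each circRNA is represented by the nucleotide sequence crossing its circular
junction (2 x ``flank`` nt, default 100 nt on each side, in transcript
orientation). Junction sequences of the two species are aligned all-against-
all with a local pairwise aligner; reciprocal best hits define orthologous
circRNA pairs, which can then be checked for concordance with one-to-one
gene-level orthologs.

Circles smaller than the flank are handled by wrapping around the circle —
the sequence a read actually traverses — rather than truncating.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from .circ_catalog import CircRNACandidate, circ_id

__all__ = [
    "JunctionSequence",
    "BestHit",
    "OrthologPair",
    "AlignmentScoring",
    "load_genome",
    "junction_sequence",
    "junction_sequences",
    "write_junction_fasta",
    "best_hits",
    "reciprocal_best_hits",
    "gene_concordance",
    "read_ortholog_table",
]


@dataclass(frozen=True)
class JunctionSequence:
    circ_id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BestHit:
    query: str
    subject: str
    score: float
    tied: bool  # another subject reached the same top score


@dataclass(frozen=True)
class OrthologPair:
    circ_a: str
    circ_b: str
    score_ab: float
    score_ba: float
    gene_a: str | None = None
    gene_b: str | None = None
    gene_concordant: bool | None = None


@dataclass(frozen=True)
class AlignmentScoring:
    """Local alignment scoring (megablast-like defaults) and the minimum
    score below which a query reports no hit."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    min_score: float = 80.0

    def aligner(self) -> PairwiseAligner:
        al = PairwiseAligner()
        al.mode = "local"
        al.match_score = self.match
        al.mismatch_score = self.mismatch
        al.open_gap_score = self.gap_open
        al.extend_gap_score = self.gap_extend
        return al


def load_genome(path: str | Path) -> dict[str, str]:
    """Read a FASTA genome into a chrom -> sequence dict (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Junction sequences
# ---------------------------------------------------------------------------

def junction_sequence(circ: CircRNACandidate, genome: Mapping[str, str],
                      flank: int = 100) -> JunctionSequence:
    """2 x ``flank`` nt sequence centered on the back-splice junction.

    On the plus strand the junction joins the circle's last base (``end``)
    back to its first (``start``); the emitted sequence is the ``flank``
    transcribed bases ending at ``end`` followed by the ``flank`` bases
    starting at ``start``. For circles smaller than ``flank`` the sequence
    wraps around the circle. Minus-strand circles yield the reverse
    complement of the plus-strand construction.
    """
    if circ.chrom not in genome:
        raise KeyError(f"chromosome {circ.chrom!r} missing from genome")
    chrom_seq = genome[circ.chrom]
    if circ.end > len(chrom_seq):
        raise ValueError(f"{circ.chrom}:{circ.start}-{circ.end} exceeds chromosome length")
    circle = chrom_seq[circ.start - 1:circ.end]  # plus-strand circle sequence
    reps = math.ceil(flank / len(circle)) + 1
    tiled = circle * reps
    upstream = tiled[-flank:]       # ends at the circle's last base
    downstream = tiled[:flank]      # starts at the circle's first base
    seq = upstream + downstream
    if circ.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return JunctionSequence(circ_id(circ.chrom, circ.strand, circ.start, circ.end), seq)


def junction_sequences(catalog: Iterable[CircRNACandidate],
                       genome: Mapping[str, str], flank: int = 100
                       ) -> list[JunctionSequence]:
    return [junction_sequence(c, genome, flank) for c in catalog]


def write_junction_fasta(seqs: Iterable[JunctionSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.circ_id}\n{s.sequence}\n")


# ---------------------------------------------------------------------------
# Best hits and reciprocal best hits
# ---------------------------------------------------------------------------

def best_hits(queries: Sequence[JunctionSequence],
              subjects: Sequence[JunctionSequence],
              scoring: AlignmentScoring | None = None) -> dict[str, BestHit]:
    """Single top-scoring local-alignment subject per query.

    Queries whose best score falls below ``scoring.min_score`` report no
    hit; ties for the top score are flagged (they later invalidate
    reciprocity)."""
    if not queries or not subjects:
        raise ValueError("both sequence sets must be nonempty")
    scoring = scoring or AlignmentScoring()
    aligner = scoring.aligner()
    hits: dict[str, BestHit] = {}
    for q in queries:
        best_subject, best_score, tied = None, -math.inf, False
        for s in subjects:
            score = aligner.score(q.sequence, s.sequence)
            if score > best_score:
                best_subject, best_score, tied = s.circ_id, score, False
            elif score == best_score:
                tied = True
        if best_subject is not None and best_score >= scoring.min_score:
            hits[q.circ_id] = BestHit(q.circ_id, best_subject, best_score, tied)
    return hits


def reciprocal_best_hits(hits_ab: Mapping[str, BestHit],
                         hits_ba: Mapping[str, BestHit],
                         parents_a: Mapping[str, str] | None = None,
                         parents_b: Mapping[str, str] | None = None,
                         ) -> list[OrthologPair]:
    """Pairs (a, b) where b is a's best hit and a is b's best hit.

    Ties on either side drop the pair (ambiguous orthology). Parent-gene
    maps, when given, are recorded on the pairs for concordance analysis.
    """
    pairs = []
    for a, hit_ab in hits_ab.items():
        if hit_ab.tied:
            continue
        b = hit_ab.subject
        hit_ba = hits_ba.get(b)
        if hit_ba is None or hit_ba.tied or hit_ba.subject != a:
            continue
        pairs.append(OrthologPair(
            a, b, hit_ab.score, hit_ba.score,
            gene_a=parents_a.get(a) if parents_a else None,
            gene_b=parents_b.get(b) if parents_b else None,
        ))
    pairs.sort(key=lambda p: (p.circ_a, p.circ_b))
    return pairs


# ---------------------------------------------------------------------------
# Gene-level concordance
# ---------------------------------------------------------------------------

def read_ortholog_table(path: str | Path) -> set[tuple[str, str]]:
    """One-to-one gene ortholog TSV (columns gene_a, gene_b; header optional)."""
    pairs: set[tuple[str, str]] = set()
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2 or fields[0] in ("gene_a", ""):
                continue
            pairs.add((fields[0], fields[1]))
    return pairs


def gene_concordance(pairs: Sequence[OrthologPair],
                     ortholog_table: set[tuple[str, str]]
                     ) -> tuple[int, int, float]:
    """How many circRNA ortholog pairs have parents that are one-to-one gene
    orthologs. Pairs with an unannotated parent on either side are excluded
    from the denominator. Returns (n_pairs_with_parents, n_concordant,
    fraction); fraction is NaN when no pair has both parents."""
    with_parents = [p for p in pairs if p.gene_a and p.gene_b]
    n_conc = sum((p.gene_a, p.gene_b) in ortholog_table for p in with_parents)
    n = len(with_parents)
    return n, n_conc, (n_conc / n if n else math.nan)


def write_pairs_table(pairs: Sequence[OrthologPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("circ_a\tcirc_b\tscore_ab\tscore_ba\tgene_a\tgene_b\n")
        for p in pairs:
            fh.write(f"{p.circ_a}\t{p.circ_b}\t{p.score_ab}\t{p.score_ba}\t"
                     f"{p.gene_a or ''}\t{p.gene_b or ''}\n")
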