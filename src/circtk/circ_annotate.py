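"""Classification of circRNA candidates against gene models.

Classes:

* ``exonic`` — both junctions coincide exactly with exon boundaries of the
  same gene, on the gene's strand (the circle is one or several exons).
* ``sub_exonic`` — both junctions fall strictly inside a single exon; the
  call is ``sense`` or ``antisense`` relative to the host gene. Circles
  inside exons of excluded biotypes (ribosomal RNA by default) are never
  called sub-exonic.
* ``intronic`` — the circle lies within one intron, its 5' junction at the
  intron donor site exactly and its 3' junction at most ``acceptor_tolerance``
  (default 60 bp) inside the intron from the acceptor site — the geometry of
  lariat-derived circles and intron circles.
* ``unannotated`` — none of the above (includes candidates whose boundaries
  match exons of two different genes, flagged "multi_gene").
* ``size_excluded`` — below the minimum annotatable genomic size; never
  classified.

When several classes match, the primary class follows the precedence
exonic > intronic > sub_exonic(sense) > sub_exonic(antisense); every
alternative match is retained in ``all_matches`` so the choice is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .circ_catalog import CircRNACandidate, circ_id
from .gene_models import FeatureIndex, GeneModelSet, IntronRecord

logger = logging.getLogger("circtk")

__all__ = [
    "ClassifierConfig",
    "ClassMatch",
    "AnnotatedCircRNA",
    "classify_exonic",
    "classify_subexonic",
    "classify_intronic",
    "annotate_catalog",
    "gene_subexonic_profile",
    "find_unannotated_clusters",
    "write_annotated_table",
    "CLASS_NAMES",
]

CLASS_NAMES = ("exonic", "sub_exonic", "intronic", "unannotated", "size_excluded")

# small non-coding biotype groups used in per-gene profiles
_SNC_BIOTYPES = {"snoRNA", "snRNA", "misc_RNA", "ribozyme", "scaRNA", "Y_RNA",
                 "miRNA", "sRNA", "scRNA", "vault_RNA"}


@dataclass
class ClassifierConfig:
    acceptor_tolerance: int = 60
    exclude_biotypes_subexonic: frozenset[str] = frozenset({"rRNA"})
    allow_antisense_subexonic: bool = True

    def __post_init__(self) -> None:
        if self.acceptor_tolerance < 0:
            raise ValueError("acceptor_tolerance must be >= 0")
        self.exclude_biotypes_subexonic = frozenset(self.exclude_biotypes_subexonic)


@dataclass(frozen=True)
class ClassMatch:
    """One way a candidate matches the annotation."""

    circ_class: str                 # exonic / sub_exonic / intronic / multi_gene
    gene_id: str | None = None
    biotype: str | None = None
    sense: str = "n/a"              # sense / antisense / n/a
    exon_ids: tuple[str, ...] = ()
    intron: tuple[int, int] | None = None  # (start, end) of the matched intron
    acceptor_offset: int | None = None


@dataclass
class AnnotatedCircRNA:
    candidate: CircRNACandidate
    circ_class: str
    parent_gene_id: str | None = None
    parent_biotype: str | None = None
    sense: str = "n/a"
    matched_exon_ids: tuple[str, ...] = ()
    matched_intron: tuple[int, int] | None = None
    acceptor_offset: int | None = None
    all_matches: list[ClassMatch] = field(default_factory=list)

    @property
    def circ_id(self) -> str:
        c = self.candidate
        return circ_id(c.chrom, c.strand, c.start, c.end)


# ---------------------------------------------------------------------------
# Single-class matchers
# ---------------------------------------------------------------------------

def classify_exonic(candidate: CircRNACandidate, index: FeatureIndex
                    ) -> ClassMatch | None:
    """Exonic: candidate.start equals an exon start and candidate.end an exon
    end of the *same* gene on the candidate's strand (possibly the same exon).
    """
    starts = index.exons_starting_at(candidate.chrom, candidate.strand, candidate.start)
    ends = index.exons_ending_at(candidate.chrom, candidate.strand, candidate.end)
    if not starts or not ends:
        return None
    by_gene_start = {g.gene_id: (g, e) for g, e in starts}
    for gene, exon_end in ends:
        if gene.gene_id in by_gene_start:
            g, exon_start = by_gene_start[gene.gene_id]
            return ClassMatch("exonic", gene_id=g.gene_id, biotype=g.biotype,
                              sense="sense", exon_ids=(exon_start.exon_id, exon_end.exon_id))
    return None


def classify_multigene(candidate: CircRNACandidate, index: FeatureIndex
                       ) -> ClassMatch | None:
    """Boundaries match exon boundaries of two *different* genes — the
    exceptional exon-fusion geometry; flagged, never a standard class."""
    starts = index.exons_starting_at(candidate.chrom, candidate.strand, candidate.start)
    ends = index.exons_ending_at(candidate.chrom, candidate.strand, candidate.end)
    if not starts or not ends:
        return None
    start_genes = {g.gene_id for g, _ in starts}
    end_genes = {g.gene_id for g, _ in ends}
    if start_genes & end_genes:
        return None  # that's a plain exonic match
    g_a = sorted(start_genes)[0]
    g_b = sorted(end_genes)[0]
    return ClassMatch("multi_gene", gene_id=f"{g_a}|{g_b}")


def classify_subexonic(candidate: CircRNACandidate, index: FeatureIndex,
                       config: ClassifierConfig) -> ClassMatch | None:
    """Sub-exonic: both junctions strictly inside a single exon.

    Boundary-touching candidates are not sub-exonic. Sense calls are
    preferred over antisense when both host exons exist.
    """
    best: ClassMatch | None = None
    for gene, exon in index.exons_overlapping(candidate.chrom, candidate.start, candidate.end):
        if not (exon.start < candidate.start and candidate.end < exon.end):
            continue
        if gene.biotype in config.exclude_biotypes_subexonic:
            continue
        sense = "sense" if gene.strand == candidate.strand else "antisense"
        if sense == "antisense" and not config.allow_antisense_subexonic:
            continue
        match = ClassMatch("sub_exonic", gene_id=gene.gene_id, biotype=gene.biotype,
                           sense=sense, exon_ids=(exon.exon_id,))
        if sense == "sense":
            return match
        best = best or match
    return best


def classify_intronic(candidate: CircRNACandidate, index: FeatureIndex,
                      config: ClassifierConfig) -> ClassMatch | None:
    """Intronic: candidate within one intron on the same strand, 5' junction
    exactly at the intron donor, 3' junction within ``acceptor_tolerance`` bp
    of the intron acceptor (measured into the intron)."""
    for intron in index.introns_overlapping(candidate.chrom, candidate.start, candidate.end):
        if intron.strand != candidate.strand:
            continue
        if not (intron.start <= candidate.start and candidate.end <= intron.end):
            continue
        five_prime = candidate.start if candidate.strand == "+" else candidate.end
        if five_prime != intron.donor_pos:
            continue
        if candidate.strand == "+":
            offset = intron.end - candidate.end
        else:
            offset = candidate.start - intron.start
        if 0 <= offset <= config.acceptor_tolerance:
            return ClassMatch("intronic", gene_id=intron.gene_id,
                              biotype=_gene_biotype(index, intron.gene_id),
                              sense="sense", intron=(intron.start, intron.end),
                              acceptor_offset=offset)
    return None


def _gene_biotype(index: FeatureIndex, gene_id: str) -> str | None:
    gene = index.models.genes.get(gene_id)
    return gene.biotype if gene else None


# ---------------------------------------------------------------------------
# Catalog annotation
# ---------------------------------------------------------------------------

def annotate_catalog(annotatable: Sequence[CircRNACandidate],
                     index: FeatureIndex,
                     config: ClassifierConfig | None = None,
                     size_excluded: Sequence[CircRNACandidate] = (),
                     ) -> tuple[list[AnnotatedCircRNA], dict[str, int]]:
    """Assign one primary class to every candidate and tally the classes.

    Returns the annotated catalog (annotatable candidates followed by the
    size-excluded ones) and a per-class summary suitable for per-million
    scaling.
    """
    config = config or ClassifierConfig()
    out: list[AnnotatedCircRNA] = []
    missing_chroms: set[str] = set()

    for cand in annotatable:
        matches: list[ClassMatch] = []
        if not index.has_chromosome(cand.chrom):
            if cand.chrom not in missing_chroms:
                missing_chroms.add(cand.chrom)
                logger.warning("chromosome %s absent from annotation", cand.chrom)
        else:
            for fn in (classify_exonic,
                       lambda c, i: classify_intronic(c, i, config),
                       lambda c, i: classify_subexonic(c, i, config),
                       classify_multigene):
                m = fn(cand, index)
                if m is not None:
                    matches.append(m)

        primary = _pick_primary(matches)
        if primary is None:
            out.append(AnnotatedCircRNA(cand, "unannotated", all_matches=matches))
        else:
            out.append(AnnotatedCircRNA(
                cand, primary.circ_class,
                parent_gene_id=primary.gene_id,
                parent_biotype=primary.biotype,
                sense=primary.sense,
                matched_exon_ids=primary.exon_ids,
                matched_intron=primary.intron,
                acceptor_offset=primary.acceptor_offset,
                all_matches=matches,
            ))

    for cand in size_excluded:
        out.append(AnnotatedCircRNA(cand, "size_excluded"))

    summary = {name: 0 for name in CLASS_NAMES}
    for a in out:
        summary[a.circ_class] += 1
    return out, summary


_PRECEDENCE = {"exonic": 0, "intronic": 1, "sub_exonic": 2}


def _pick_primary(matches: list[ClassMatch]) -> ClassMatch | None:
    ranked = []
    for m in matches:
        if m.circ_class not in _PRECEDENCE:
            continue  # multi_gene stays a flag inside unannotated
        rank = _PRECEDENCE[m.circ_class]
        if m.circ_class == "sub_exonic" and m.sense == "antisense":
            rank += 1
        ranked.append((rank, m))
    if not ranked:
        return None
    ranked.sort(key=lambda t: t[0])
    return ranked[0][1]


# ---------------------------------------------------------------------------
# Downstream summaries
# ---------------------------------------------------------------------------

def _biotype_group(biotype: str | None) -> str:
    if biotype == "protein_coding":
        return "protein_coding"
    if biotype == "lncRNA":
        return "lncRNA"
    if biotype is not None and "pseudogene" in biotype:
        return "pseudogene"
    if biotype in _SNC_BIOTYPES:
        return "snc"
    return "other"


def gene_subexonic_profile(annotated: Iterable[AnnotatedCircRNA]) -> pd.DataFrame:
    """Per-gene summary of sub-exonic production: how many distinct exons of
    each parent gene host sub-exonic circles, how many circles, total CCRs.
    Columns: gene, biotype, biotype_group, n_exons_involved, n_subexonic,
    ccr_total."""
    rows: dict[str, dict] = {}
    for a in annotated:
        if a.circ_class != "sub_exonic" or a.parent_gene_id is None:
            continue
        entry = rows.setdefault(a.parent_gene_id, {
            "gene": a.parent_gene_id,
            "biotype": a.parent_biotype,
            "biotype_group": _biotype_group(a.parent_biotype),
            "exons": set(), "n_subexonic": 0, "ccr_total": 0,
        })
        entry["exons"].update(a.matched_exon_ids)
        entry["n_subexonic"] += 1
        entry["ccr_total"] += a.candidate.ccr_count
    records = [{"gene": e["gene"], "biotype": e["biotype"],
                "biotype_group": e["biotype_group"],
                "n_exons_involved": len(e["exons"]),
                "n_subexonic": e["n_subexonic"], "ccr_total": e["ccr_total"]}
               for e in rows.values()]
    df = pd.DataFrame(records, columns=["gene", "biotype", "biotype_group",
                                        "n_exons_involved", "n_subexonic", "ccr_total"])
    return df.sort_values("gene").reset_index(drop=True) if len(df) else df


def find_unannotated_clusters(annotated: Sequence[AnnotatedCircRNA],
                              window: int = 10_000,
                              min_count: int = 10,
                              ) -> list[tuple[str, int, int, int, float]]:
    """Scan chromosomes for clusters of unannotated circRNAs.

    Unannotated circles (including size-excluded ones, which the catalog
    keeps as non-annotated) whose junction intervals lie within ``window`` bp
    of each other are merged by a sort-then-sweep; clusters with at least
    ``min_count`` members are reported as (chrom, start, end, n_circ,
    fraction_of_unannotated) where the fraction is relative to all
    unannotated circles in the catalog.
    """
    unann = [a.candidate for a in annotated
             if a.circ_class in ("unannotated", "size_excluded")]
    total = len(unann)
    if total == 0:
        return []
    unann.sort(key=lambda c: (c.chrom, c.start, c.end))
    clusters: list[tuple[str, int, int, int, float]] = []
    cur_chrom, cur_start, cur_end, n = None, 0, 0, 0
    for c in unann:
        if c.chrom == cur_chrom and c.start - cur_end <= window:
            cur_end = max(cur_end, c.end)
            n += 1
        else:
            if cur_chrom is not None and n >= min_count:
                clusters.append((cur_chrom, cur_start, cur_end, n, n / total))
            cur_chrom, cur_start, cur_end, n = c.chrom, c.start, c.end, 1
    if cur_chrom is not None and n >= min_count:
        clusters.append((cur_chrom, cur_start, cur_end, n, n / total))
    return clusters


def write_annotated_table(annotated: Iterable[AnnotatedCircRNA], path: str | Path) -> None:
    """Annotated catalog TSV."""
    cols = ["chrom", "start", "end", "strand", "ccr_count", "class", "sense",
            "parent_gene", "biotype", "features", "acceptor_offset"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for a in annotated:
            c = a.candidate
            feats = (",".join(a.matched_exon_ids) if a.matched_exon_ids
                     else (f"intron:{a.matched_intron[0]}-{a.matched_intron[1]}"
                           if a.matched_intron else ""))
            fh.write("\t".join(map(str, [
                c.chrom, c.start, c.end, c.strand, c.ccr_count, a.circ_class,
                a.sense, a.parent_gene_id or "", a.parent_biotype or "", feats,
                a.acceptor_offset if a.acceptor_offset is not None else "",
            ])) + "\n")
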