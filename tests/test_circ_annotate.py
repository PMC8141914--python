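"""circRNA classification: exonic / sub-exonic / intronic / unannotated."""

import numpy as np
import pytest

from circtk.circ_annotate import (
    ClassifierConfig,
    annotate_catalog,
    classify_exonic,
    classify_intronic,
    classify_subexonic,
    find_unannotated_clusters,
    gene_subexonic_profile,
)
from circtk.circ_catalog import CircRNACandidate, FilterConfig, size_partition
from circtk.gene_models import (
    Exon,
    Gene,
    GeneModelSet,
    Transcript,
    build_feature_index,
)


def build_index(genes):
    """genes: list of (gene_id, biotype, chrom, strand, [(start, end), ...])."""
    models = GeneModelSet()
    for gid, biotype, chrom, strand, exons in genes:
        gene = Gene(gid, biotype, chrom, strand)
        tx = Transcript(f"{gid}.t1", [Exon(chrom, s, e, f"{gid}.e{k + 1}")
                                      for k, (s, e) in enumerate(exons)])
        tx.sort_exons()
        gene.transcripts[tx.transcript_id] = tx
        models.genes[gid] = gene
    return build_feature_index(models)


@pytest.fixture()
def index():
    return build_index([
        ("GA", "protein_coding", "chr1", "+",
         [(101, 200), (301, 400), (501, 700), (901, 1400)]),
        ("GB", "protein_coding", "chr1", "+", [(2001, 2300), (2601, 2900)]),
        ("GR", "rRNA", "chr1", "+", [(5001, 5500)]),
        ("GM", "misc_RNA", "chr1", "-", [(7001, 7400)]),
    ])


def cand(start, end, strand="+", chrom="chr1", count=5):
    return CircRNACandidate(chrom, strand, start, end, count)


class TestExonic:
    def test_two_exon_circle(self, index):
        m = classify_exonic(cand(301, 700), index)
        assert m is not None and m.gene_id == "GA"
        assert m.exon_ids == ("GA.e2", "GA.e3")

    def test_single_exon_circle(self, index):
        m = classify_exonic(cand(301, 400), index)
        assert m is not None and m.exon_ids == ("GA.e2", "GA.e2")

    def test_boundaries_of_two_genes_not_exonic(self, index):
        assert classify_exonic(cand(101, 2900), index) is None

    def test_strand_must_match_gene(self, index):
        assert classify_exonic(cand(301, 700, strand="-"), index) is None


class TestSubExonic:
    def test_sense_inside_exon(self, index):
        m = classify_subexonic(cand(520, 680), index, ClassifierConfig())
        assert m is not None and (m.gene_id, m.sense) == ("GA", "sense")

    def test_antisense_inside_exon(self, index):
        m = classify_subexonic(cand(520, 680, strand="-"), index, ClassifierConfig())
        assert m is not None and m.sense == "antisense"

    def test_rrna_exon_excluded(self, index):
        assert classify_subexonic(cand(5100, 5300), index, ClassifierConfig()) is None

    @pytest.mark.parametrize("start,end", [(501, 680), (520, 700), (501, 700)])
    def test_boundary_touching_is_not_subexonic(self, index, start, end):
        # "strictly within": junctions on an exon boundary do not qualify
        assert classify_subexonic(cand(start, end), index, ClassifierConfig()) is None


class TestIntronic:
    # GA introns on +: [201-300], [401-500], [701-900]
    def test_donor_anchored_with_offset(self, index):
        m = classify_intronic(cand(201, 295), index, ClassifierConfig())
        assert m is not None
        assert m.acceptor_offset == 5
        assert m.intron == (201, 300)

    def test_offset_sweep_accepts_up_to_60(self, index):
        accepted = [off for off in range(0, 101)
                    if classify_intronic(cand(701, 900 - off), index, ClassifierConfig())]
        assert max(accepted) == 60
        assert accepted == list(range(0, 61))

    def test_five_prime_must_equal_donor(self, index):
        assert classify_intronic(cand(205, 300), index, ClassifierConfig()) is None

    def test_minus_strand_donor_is_interval_end(self):
        index = build_index([("GN", "protein_coding", "chr1", "-",
                              [(101, 200), (301, 400)])])
        # intron 201-300 on "-": donor at 300, acceptor at 201
        m = classify_intronic(cand(206, 300, strand="-"), index, ClassifierConfig())
        assert m is not None and m.acceptor_offset == 5
        assert classify_intronic(cand(201, 295, strand="-"), index,
                                 ClassifierConfig()) is None

    def test_tolerance_monotonicity(self, index):
        counts = []
        for tol in (0, 30, 60, 100):
            cfg = ClassifierConfig(acceptor_tolerance=tol)
            n = sum(bool(classify_intronic(cand(701, 900 - off), index, cfg))
                    for off in range(0, 101))
            counts.append(n)
        assert counts == sorted(counts)


class TestAnnotateCatalog:
    def test_planted_mixture_summary(self, index):
        candidates = (
            [cand(101, 400), cand(301, 700), cand(101, 1400),
             cand(301, 400), cand(2001, 2900),
             cand(101, 700), cand(501, 1400), cand(301, 1400),
             cand(2001, 2300), cand(2601, 2900)]          # 10 exonic
            + [cand(520, 680), cand(530, 690), cand(940, 1100),
               cand(2050, 2200), cand(7100, 7300, strand="-")]  # 5 sub-exonic
            + [cand(201, 300), cand(401, 495), cand(701, 850)]  # 3 intronic
            + [cand(9000 + i * 500, 9100 + i * 500) for i in range(4)]  # 4 intergenic
        )
        annotated, summary = annotate_catalog(candidates, index)
        assert summary == {"exonic": 10, "sub_exonic": 5, "intronic": 3,
                           "unannotated": 4, "size_excluded": 0}

    def test_classification_is_a_partition(self, index):
        candidates = [cand(101, 400), cand(520, 680), cand(201, 300),
                      cand(9000, 9100)]
        annotated, summary = annotate_catalog(candidates, index)
        assert len(annotated) == len(candidates)
        assert sum(summary.values()) == len(candidates)
        assert all(sum(a.circ_class == c for c in
                       ("exonic", "sub_exonic", "intronic", "unannotated",
                        "size_excluded")) == 1 for a in annotated)

    def test_exonic_precedes_subexonic(self):
        # GB's exon engulfs GA's single exon; the candidate matches GA's
        # boundaries exactly and lies strictly inside GB's exon
        index = build_index([
            ("GA", "protein_coding", "chr1", "+", [(201, 300)]),
            ("GB", "protein_coding", "chr1", "+", [(101, 400)]),
        ])
        annotated, _ = annotate_catalog([cand(201, 300)], index)
        assert annotated[0].circ_class == "exonic"
        assert annotated[0].parent_gene_id == "GA"
        assert any(m.circ_class == "sub_exonic" for m in annotated[0].all_matches)

    def test_multi_gene_flagged_within_unannotated(self, index):
        annotated, _ = annotate_catalog([cand(101, 2900)], index)
        assert annotated[0].circ_class == "unannotated"
        assert any(m.circ_class == "multi_gene" for m in annotated[0].all_matches)

    def test_unknown_chromosome_is_unannotated(self, index):
        annotated, summary = annotate_catalog([cand(100, 200, chrom="chrUn")], index)
        assert summary["unannotated"] == 1

    def test_size_excluded_passthrough(self, index):
        small = cand(520, 560)
        annotatable, excluded = size_partition([small], FilterConfig(read_length=100))
        annotated, summary = annotate_catalog(annotatable, index, size_excluded=excluded)
        assert summary["size_excluded"] == 1
        assert annotated[-1].circ_class == "size_excluded"

    def test_end_to_end_planted_truth(self, sim_bundle, sim_index):
        """Detection plus annotation reproduces every planted class,
        coordinate and support count; decoys yield nothing."""
        from circtk import (apply_ccr_threshold, cluster_ccrs,
                            parse_chimeric_records, select_ccrs)
        _, _, _, chimeric, truth, low = sim_bundle
        ccrs = select_ccrs(parse_chimeric_records(chimeric))
        retained = apply_ccr_threshold(cluster_ccrs(ccrs, "ds1"), 5)
        annotatable, excluded = size_partition(retained, FilterConfig(read_length=100))
        annotated, _ = annotate_catalog(annotatable, sim_index, size_excluded=excluded)
        got = {a.circ_id: (a.circ_class, a.candidate.ccr_count) for a in annotated}
        want = {r.circ_id: (r.expected_class, r.ccr_count)
                for r in truth.itertuples(index=False)}
        assert got == want


class TestSubExonicProfile:
    def test_exons_involved_counted_once(self, index):
        annotated, _ = annotate_catalog(
            [cand(520, 680), cand(530, 690),              # both in GA.e3
             cand(940, 1100), cand(950, 1200),            # GA.e4
             cand(2050, 2200)], index)                    # GB.e1
        profile = gene_subexonic_profile(annotated)
        ga = profile.set_index("gene").loc["GA"]
        assert ga["n_exons_involved"] == 2
        assert ga["n_subexonic"] == 4
        assert ga["ccr_total"] == 20

    def test_empty_when_no_subexonic(self, index):
        annotated, _ = annotate_catalog([cand(101, 400)], index)
        assert len(gene_subexonic_profile(annotated)) == 0


class TestUnannotatedClusters:
    @staticmethod
    def annotate_intergenic(positions, index):
        cands = [CircRNACandidate("chr9", "+", p, p + 80, 5) for p in positions]
        annotated, _ = annotate_catalog(cands, index)
        return annotated

    def test_planted_cluster_fraction(self, index):
        """450 of 1,125 unannotated circles packed in one 200 kb region form
        one cluster holding 40% of the unannotated catalog."""
        rng = np.random.default_rng(5)
        inside = sorted(rng.choice(np.arange(1_000_000, 1_200_000, 100), 450,
                                   replace=False))
        outside = [3_000_000 + i * 50_000 for i in range(675)]
        annotated = self.annotate_intergenic(list(inside) + outside, index)
        clusters = find_unannotated_clusters(annotated, window=10_000, min_count=10)
        assert len(clusters) == 1
        chrom, start, end, n, frac = clusters[0]
        assert n == 450
        assert frac == pytest.approx(0.40)

    def test_scattered_singletons_no_cluster(self, index):
        annotated = self.annotate_intergenic([i * 100_000 for i in range(50)], index)
        assert find_unannotated_clusters(annotated, window=10_000, min_count=10) == []

    def test_merge_order_invariance_against_sweep_oracle(self, index):
        rng = np.random.default_rng(11)
        positions = rng.integers(1, 5_000_000, size=400)
        annotated = self.annotate_intergenic(list(positions), index)
        shuffled = list(annotated)
        rng.shuffle(shuffled)
        got = find_unannotated_clusters(shuffled, window=20_000, min_count=3)

        # independent oracle: repeated pairwise merging to a fixed point
        intervals = [(a.candidate.chrom, a.candidate.start, a.candidate.end, 1)
                     for a in annotated]
        changed = True
        while changed:
            changed = False
            merged = []
            for iv in sorted(intervals):
                if merged and iv[0] == merged[-1][0] and iv[1] - merged[-1][2] <= 20_000:
                    c, s, e, n = merged[-1]
                    merged[-1] = (c, s, max(e, iv[2]), n + iv[3])
                    changed = True
                else:
                    merged.append(iv)
            intervals = merged
        total = len(annotated)
        want = [(c, s, e, n, n / total) for c, s, e, n in intervals if n >= 3]
        assert got == want
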