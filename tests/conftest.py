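"""Shared fixtures: a deterministic synthetic study built once per session."""

from __future__ import annotations

import pytest

from circtk.gene_models import build_feature_index, derive_introns, load_gene_models
from circtk.synthetic_data import default_spec, make_genome, plant_chimeric_file

SEED = 20210510


@pytest.fixture(scope="session")
def sim_spec():
    return default_spec(SEED)


@pytest.fixture(scope="session")
def sim_bundle(sim_spec, tmp_path_factory):
    """(genome, fasta path, gtf path, chimeric path, truth df, low-support df)."""
    outdir = tmp_path_factory.mktemp("sim")
    genome = make_genome(sim_spec)
    fasta, gtf = genome.write(outdir)
    chimeric = outdir / "chimeric.out.junction"
    _, truth, low = plant_chimeric_file(sim_spec, genome, chimeric)
    return genome, fasta, gtf, chimeric, truth, low


@pytest.fixture(scope="session")
def sim_models(sim_bundle):
    _, _, gtf, _, _, _ = sim_bundle
    return load_gene_models(gtf)


@pytest.fixture(scope="session")
def sim_index(sim_models):
    return build_feature_index(sim_models, derive_introns(sim_models))


TOY_GTF = """\
chr1\ttest\tgene\t101\t1400\t.\t+\t.\tgene_id "GA"; gene_biotype "protein_coding";
chr1\ttest\texon\t101\t200\t.\t+\t.\tgene_id "GA"; gene_biotype "protein_coding"; transcript_id "GA.t1"; exon_id "GA.e1";
chr1\ttest\texon\t301\t400\t.\t+\t.\tgene_id "GA"; gene_biotype "protein_coding"; transcript_id "GA.t1"; exon_id "GA.e2";
chr1\ttest\texon\t901\t1400\t.\t+\t.\tgene_id "GA"; gene_biotype "protein_coding"; transcript_id "GA.t1"; exon_id "GA.e3";
chr1\ttest\texon\t101\t200\t.\t+\t.\tgene_id "GA"; gene_biotype "protein_coding"; transcript_id "GA.t2"; exon_id "GA.e1";
chr1\ttest\texon\t901\t1400\t.\t+\t.\tgene_id "GA"; gene_biotype "protein_coding"; transcript_id "GA.t2"; exon_id "GA.e3";
chr1\ttest\texon\t2001\t2100\t.\t-\t.\tgene_id "GB"; gene_biotype "rRNA"; transcript_id "GB.t1"; exon_id "GB.e1";
chr2\ttest\texon\t501\t700\t.\t-\t.\tgene_id "GC"; gene_biotype "lncRNA"; transcript_id "GC.t1"; exon_id "GC.e1";
chr2\ttest\texon\t901\t1000\t.\t-\t.\tgene_id "GC"; gene_biotype "lncRNA"; transcript_id "GC.t1"; exon_id "GC.e2";
"""


@pytest.fixture()
def toy_gtf(tmp_path):
    path = tmp_path / "toy.gtf"
    path.write_text(TOY_GTF)
    return path
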