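"""Genome bundle I/O: coordinate conventions, translation, round trips."""

import pytest

from synloss.genomeio import (GeneModel, GenomeBundle, read_genome_bundle,
                              revcomp, translate_cds, write_genome_bundle)
from synloss.simulate import SimConfig, simulate_genome_pair


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return str(p)


def test_gff3_coordinates_convert_to_zero_based_half_open(tmp_path):
    """A gene at GFF3 5..13 (1-based inclusive) is internally [4, 13)."""
    fasta = _write(tmp_path, "g.fa", ">chr1\n" + "ACGT" * 10 + "\n")
    gff = _write(tmp_path, "g.gff3", "\n".join([
        "##gff-version 3",
        "chr1\t.\tgene\t5\t13\t.\t+\t.\tID=g1",
        "chr1\t.\tmRNA\t5\t13\t.\t+\t.\tID=g1.t1;Parent=g1",
        "chr1\t.\tCDS\t5\t13\t.\t+\t0\tID=g1.t1.cds;Parent=g1.t1",
    ]) + "\n")
    bundle = read_genome_bundle(fasta, gff)
    gene = bundle.gene("g1")
    assert (gene.start, gene.end) == (4, 13)
    assert gene.exons == ((4, 13),)
    assert gene.rank == 0


def test_minus_strand_protein_is_translation_of_revcomp_spliced_cds(tmp_path):
    """Protein of a minus-strand 2-CDS gene = translate(revcomp(splice))."""
    seq = "TTTCATTTTTTGGGCATTTTTTTT"
    # minus-strand gene with exons [3,9) and [12,18): the stored protein
    # must equal the translation of the reverse-complemented splice
    fasta = _write(tmp_path, "m.fa", f">chr1\n{seq}\n")
    gff = _write(tmp_path, "m.gff3", "\n".join([
        "##gff-version 3",
        "chr1\t.\tgene\t4\t18\t.\t-\t.\tID=g1",
        "chr1\t.\tmRNA\t4\t18\t.\t-\t.\tID=g1.t1;Parent=g1",
        "chr1\t.\tCDS\t4\t9\t.\t-\t0\tID=g1.t1.cds;Parent=g1.t1",
        "chr1\t.\tCDS\t13\t18\t.\t-\t0\tID=g1.t1.cds;Parent=g1.t1",
    ]) + "\n")
    bundle = read_genome_bundle(fasta, gff)
    spliced = seq[3:9] + seq[12:18]
    assert bundle.gene("g1").protein == translate_cds(revcomp(spliced))
    assert bundle.cds("g1") == revcomp(spliced)


def test_missing_sequence_id_is_hard_error(tmp_path):
    fasta = _write(tmp_path, "g.fa", ">chr1\nACGTACGTACGT\n")
    gff = _write(tmp_path, "g.gff3", "\n".join([
        "##gff-version 3",
        "chrX\t.\tgene\t1\t9\t.\t+\t.\tID=g1",
        "chrX\t.\tCDS\t1\t9\t.\t+\t0\tID=g1.cds;Parent=g1",
    ]) + "\n")
    with pytest.raises(ValueError, match="chrX"):
        read_genome_bundle(fasta, gff)


def test_cds_not_divisible_by_three_warns_and_truncates(tmp_path):
    fasta = _write(tmp_path, "g.fa", ">chr1\nATGAAAGGGT\n")
    gff = _write(tmp_path, "g.gff3", "\n".join([
        "##gff-version 3",
        "chr1\t.\tgene\t1\t10\t.\t+\t.\tID=g1",
        "chr1\t.\tCDS\t1\t10\t.\t+\t0\tID=g1.cds;Parent=g1",
    ]) + "\n")
    with pytest.warns(UserWarning, match="not divisible"):
        bundle = read_genome_bundle(fasta, gff)
    assert bundle.gene("g1").protein == "MKG"


def test_te_input_dialects(tmp_path):
    """BED is consumed 0-based half-open, GFF3 1-based inclusive."""
    fasta = _write(tmp_path, "g.fa", ">chr1\n" + "A" * 100 + "\n")
    gff = _write(tmp_path, "g.gff3", "##gff-version 3\n")
    bed = _write(tmp_path, "te.bed", "chr1\t10\t20\n")
    tegff = _write(tmp_path, "te.gff3", "chr1\trep\tTE\t11\t20\t.\t+\t.\tx\n")
    b1 = read_genome_bundle(fasta, gff, te_path=bed)
    b2 = read_genome_bundle(fasta, gff, te_path=tegff)
    assert b1.te_intervals == b2.te_intervals == [("chr1", 10, 20)]


def test_empty_bundle_writes_header_only_files(tmp_path):
    bundle = GenomeBundle(genome_id="empty")
    paths = write_genome_bundle(bundle, str(tmp_path))
    assert (tmp_path / "empty.fa").read_text() == ""
    assert (tmp_path / "empty.gff3").read_text() == "##gff-version 3\n"
    assert (tmp_path / "empty.te.bed").read_text() == ""
    assert set(paths) == {"fasta", "gff3", "proteins", "te"}


def test_written_gff3_start_is_internal_plus_one(tmp_path):
    chrom = "ATGAAATGA" + "C" * 20 + "ATGCCCTGA" + "C" * 10
    genes = {"chr1": [
        GeneModel("g1", "chr1", 0, 9, "+", ((0, 9),), "MK"),
        GeneModel("g2", "chr1", 29, 38, "+", ((29, 38),), "MP"),
    ]}
    bundle = GenomeBundle(genome_id="two", chromosomes={"chr1": chrom},
                          genes=genes)
    paths = write_genome_bundle(bundle, str(tmp_path))
    lines = [ln.rstrip("\n").split("\t") for ln in
             open(paths["gff3"]) if not ln.startswith("#")]
    starts = {f[8].split(";")[0][3:]: int(f[3])
              for f in lines if f[2] == "gene"}
    assert starts == {"g1": 1, "g2": 30}
    # every emitted interval obeys 1 <= start <= end <= seqlen
    for f in lines:
        assert 1 <= int(f[3]) <= int(f[4]) <= len(chrom)


@pytest.mark.parametrize("seed", [1, 5])
def test_round_trip_is_identity_on_simulated_bundles(tmp_path, seed):
    """read(write(bundle)) == bundle, for both genomes of a small world."""
    cfg = SimConfig(seed=seed, n_chromosomes=1, genes_per_chromosome=12,
                    n_deletions=1, n_hidden_intact_copies=1,
                    n_pseudogenes_per_class=(1, 1, 1), n_inversions=0,
                    te_density=10.0)
    bundle_a, bundle_b, _ = simulate_genome_pair(cfg)
    for bundle in (bundle_a, bundle_b):
        out = tmp_path / bundle.genome_id
        paths = write_genome_bundle(bundle, str(out))
        back = read_genome_bundle(paths["fasta"], paths["gff3"],
                                  te_path=paths["te"],
                                  genome_id=bundle.genome_id)
        assert back == bundle
        # byte stability: writing again reproduces identical files
        paths2 = write_genome_bundle(bundle, str(tmp_path / "again"))
        for key in paths:
            assert open(paths[key], "rb").read() == \
                open(paths2[key], "rb").read()


def test_intergenic_segments_complement_gene_spans():
    chrom = "A" * 100
    genes = {"chr1": [
        GeneModel("g1", "chr1", 10, 20, "+", ((10, 20),), "MKV"),
        GeneModel("g2", "chr1", 50, 70, "+", ((50, 70),), "MKV"),
    ]}
    bundle = GenomeBundle(genome_id="x", chromosomes={"chr1": chrom},
                          genes=genes)
    assert bundle.intergenic_segments("chr1") == \
        [(0, 10), (20, 50), (70, 100)]
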