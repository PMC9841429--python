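import pytest
from Bio.Seq import Seq
from Bio.SeqFeature import BeforePosition, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from ambistart.genome import (
    GenomeParseError,
    WindowError,
    mrna_context,
    parse_genbank,
    write_genbank,
)
from ambistart.sequence import revcomp_dna


def _write(record, path):
    record.annotations.setdefault("molecule_type", "DNA")
    record.annotations.setdefault("date", "01-JAN-1980")
    with open(path, "w") as fh:
        from Bio import SeqIO

        SeqIO.write([record], fh, "genbank")
    return path


def _two_gene_record():
    seq = ["C"] * 500
    seq[100:106] = list("ATGAAA")  # forward gene start
    seq[357:360] = list("CAT")  # reverse gene start codon (revcomp ATG)
    seq[360:390] = list("AGCTTGCAGGCATAAGCAGGCTTACAGCTA")  # reverse gene upstream span
    rec = SeqRecord(Seq("".join(seq)), id="mini1", name="mini1", description="")
    rec.annotations["topology"] = "linear"
    rec.features = [
        SeqFeature(SimpleLocation(100, 160, strand=1), type="CDS",
                   qualifiers={"gene": ["fwd1"], "locus_tag": ["fwd1"]}),
        SeqFeature(SimpleLocation(300, 360, strand=-1), type="CDS",
                   qualifiers={"gene": ["rev1"], "locus_tag": ["rev1"]}),
    ]
    return rec


def test_two_gene_genbank_yields_mrna_sense_records(tmp_path):
    path = _write(_two_gene_record(), tmp_path / "mini.gbk")
    genome = parse_genbank(path)
    assert [g.gene_id for g in genome.genes] == ["fwd1", "rev1"]
    assert all(g.annotated_start_codon == "ATG" for g in genome.genes)
    rev = genome.genes[1]
    # the upstream window of a reverse gene is the reverse complement of the
    # forward-strand span just 3' of its CDS, read 5'->3' in mRNA sense
    assert rev.upstream_seq == revcomp_dna(genome.sequence[360:390])
    assert rev.strand == "-" and rev.start_anchor == 359


def test_pseudo_qualifier_is_flagged_not_dropped(tmp_path):
    rec = _two_gene_record()
    rec.features[0].qualifiers["pseudo"] = [""]
    genome = parse_genbank(_write(rec, tmp_path / "p.gbk"))
    assert [g.is_pseudo for g in genome.genes] == [True, False]


def test_fuzzy_location_is_skipped_with_report(tmp_path):
    rec = _two_gene_record()
    rec.features.append(
        SeqFeature(SimpleLocation(BeforePosition(400), 430, strand=1), type="CDS",
                   qualifiers={"locus_tag": ["fuzzy1"]})
    )
    genome = parse_genbank(_write(rec, tmp_path / "f.gbk"))
    assert len(genome.genes) == 2
    assert ("fuzzy1", "fuzzy location") in genome.skipped


def test_unreadable_and_missing_files_raise_parse_errors(tmp_path):
    with pytest.raises(GenomeParseError):
        parse_genbank(tmp_path / "nope.gbk")
    bad = tmp_path / "bad.gbk"
    bad.write_text("this is not a genbank file\n")
    with pytest.raises(GenomeParseError):
        parse_genbank(bad)


def test_mrna_context_definitions(suite_genome):
    genome = suite_genome.genome
    for gene in genome.genes:
        assert mrna_context(genome, gene, 0, 3) == gene.annotated_start_codon
        assert mrna_context(genome, gene, 30, 0) == gene.upstream_seq
        # reporter-style fusion window: 20 nt of 5' UTR + 15 nt of CDS
        fusion = mrna_context(genome, gene, 20, 15)
        assert fusion == gene.upstream_seq[-20:] + mrna_context(genome, gene, 0, 15)


def test_circular_upstream_window_wraps_origin(suite_genome):
    genome = suite_genome.genome
    rep10 = next(g for g in genome.genes if g.gene_id == "rep10")
    assert rep10.start_anchor < 30  # its 30-nt window spans the origin
    assert len(rep10.upstream_seq) == 30
    assert "UAAGGAGG".replace("U", "T") in rep10.upstream_seq


def test_window_longer_than_circular_replicon_errors(suite_genome):
    genome = suite_genome.genome
    with pytest.raises(WindowError):
        mrna_context(genome, genome.genes[0], genome.length, 3)


def test_linear_replicon_truncates_never_pads(tmp_path):
    rec = _two_gene_record()
    rec.features.append(
        SeqFeature(SimpleLocation(0, 30, strand=1), type="CDS",
                   qualifiers={"locus_tag": ["edge1"]})
    )
    rec.seq = Seq("ATG" + str(rec.seq)[3:])
    genome = parse_genbank(_write(rec, tmp_path / "e.gbk"))
    edge = next(g for g in genome.genes if g.gene_id == "edge1")
    assert edge.upstream_seq == ""
    assert edge.context_start == 0  # no -2..-1 available


def test_genbank_round_trip_reproduces_records(suite_genome, tmp_path):
    genome = suite_genome.genome
    path = write_genbank(genome, tmp_path / "rt.gbk")
    reparsed = parse_genbank(path)
    key = lambda g: (
        g.gene_id, g.strand, g.cds_interval, g.start_anchor,
        g.annotated_start_codon, g.upstream_seq, g.context_seq, g.is_pseudo,
    )
    assert [key(g) for g in genome.genes] == [key(g) for g in reparsed.genes]
    assert reparsed.topology == genome.topology


def test_strand_symmetry_under_full_reverse_complement(suite_genome, tmp_path):
    """Scanning the reverse-complemented genome with re-coordinated features
    yields identical mRNA-sense records."""
    genome = suite_genome.genome
    L = genome.length
    rc = SeqRecord(Seq(revcomp_dna(genome.sequence)), id=genome.replicon_id,
                   name="rc", description="")
    rc.annotations["topology"] = genome.topology
    for g in genome.genes:
        s, e = g.cds_interval
        strand = -1 if g.strand == "+" else 1
        quals = {"gene": [g.name], "locus_tag": [g.locus_tag]}
        if g.is_pseudo:
            quals["pseudo"] = [""]
        rc.features.append(
            SeqFeature(SimpleLocation(L - e, L - s, strand=strand), type="CDS",
                       qualifiers=quals)
        )
    mirrored = parse_genbank(_write(rc, tmp_path / "rc.gbk"))
    orig = {g.gene_id: g for g in genome.genes}
    assert set(orig) == {g.gene_id for g in mirrored.genes}
    for g in mirrored.genes:
        o = orig[g.gene_id]
        assert (g.annotated_start_codon, g.upstream_seq, g.context_seq) == (
            o.annotated_start_codon, o.upstream_seq, o.context_seq,
        )
        assert g.strand != o.strand


def test_fasta_gff_mode_matches_genbank_parse(tmp_path):
    from ambistart.genome import parse_fasta_gff

    rec = _two_gene_record()
    gbk = parse_genbank(_write(rec, tmp_path / "m.gbk"))
    fasta = tmp_path / "m.fa"
    fasta.write_text(f">mini1\n{rec.seq}\n")
    gff = tmp_path / "m.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "mini1\ttest\tCDS\t101\t160\t.\t+\t0\tID=fwd1;locus_tag=fwd1;gene=fwd1\n"
        "mini1\ttest\tCDS\t301\t360\t.\t-\t0\tID=rev1;locus_tag=rev1;gene=rev1\n"
    )
    genome = parse_fasta_gff(fasta, gff)
    key = lambda g: (g.gene_id, g.strand, g.cds_interval, g.annotated_start_codon,
                     g.upstream_seq, g.context_seq)
    assert [key(g) for g in genome.genes] == [key(g) for g in gbk.genes]


def test_duplicate_gene_names_get_unique_ids(tmp_path):
    rec = _two_gene_record()
    for f in rec.features:
        f.qualifiers["locus_tag"] = ["dup"]
        f.qualifiers["gene"] = ["dup"]
    genome = parse_genbank(_write(rec, tmp_path / "d.gbk"))
    ids = [g.gene_id for g in genome.genes]
    assert len(set(ids)) == 2
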