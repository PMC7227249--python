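import string

import pytest
from hypothesis import given
from hypothesis import strategies as st

from plastomarker.errors import FormatError
from plastomarker.seqio import (
    Alignment,
    GeneFeature,
    GenotypeTable,
    SequenceRecord,
    read_alignment,
    read_fasta,
    read_genbank_features,
    read_genotype_table,
    read_gff3_features,
    revcomp,
    write_alignment,
    write_fasta,
    write_genotype_table,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=80)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def test_read_fasta_minimal(tmp_path):
    p = tmp_path / "a.fasta"
    p.write_text(">a\nacgt\n")
    (rec,) = read_fasta(p)
    assert rec.id == "a" and rec.sequence == "ACGT"


def test_read_fasta_maps_u_to_t(tmp_path):
    p = tmp_path / "a.fasta"
    p.write_text(">a\nACGU\n")
    assert read_fasta(p)[0].sequence == "ACGT"


@pytest.mark.parametrize(
    "content,match",
    [
        (">a\nACGT\n>a\nACGT\n", "duplicate"),
        (">a\nACRT\n", "position 3"),
        ("", "no FASTA records"),
    ],
)
def test_read_fasta_errors(tmp_path, content, match):
    p = tmp_path / "bad.fasta"
    p.write_text(content)
    with pytest.raises(FormatError, match=match):
        read_fasta(p)


@given(st.lists(dna, min_size=1, max_size=5, unique=True))
def test_fasta_round_trip(seqs):
    import tempfile, os

    records = [SequenceRecord(f"s{i}", s) for i, s in enumerate(seqs)]
    fd, path = tempfile.mkstemp(suffix=".fasta")
    os.close(fd)
    try:
        write_fasta(records, path)
        back = read_fasta(path)
        assert [(r.id, r.sequence) for r in back] == [
            (r.id, r.sequence) for r in records
        ]
    finally:
        os.unlink(path)


def test_sequence_record_rejects_gap_and_empty():
    with pytest.raises(FormatError):
        SequenceRecord("a", "AC-GT")
    with pytest.raises(FormatError):
        SequenceRecord("a", "")


def test_circular_subseq_wraps():
    rec = SequenceRecord("a", "ACGTACGT", circular=True)
    assert rec.subseq(7, 2) == "GTAC"
    linear = SequenceRecord("a", "ACGTACGT")
    with pytest.raises(ValueError):
        linear.subseq(7, 2)


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------


def test_read_alignment_basic(tmp_path):
    p = tmp_path / "aln.fasta"
    p.write_text(">g1\nACGTACGTAA\n>g2\nACGTACGTAA\n>g3\nAC-TACGTAA\n>g4\nACGTACGTAA\n")
    aln = read_alignment(p)
    assert aln.length == 10 and aln.ids == ["g1", "g2", "g3", "g4"]
    assert aln.ungapped("g3") == "ACTACGTAA"


def test_read_alignment_ragged(tmp_path):
    p = tmp_path / "aln.fasta"
    p.write_text(">g1\nACGTACGTAC\n>g2\nACGTACGTA\n")
    with pytest.raises(FormatError, match="ragged"):
        read_alignment(p)


def test_alignment_all_gap_column_rejected():
    with pytest.raises(FormatError, match="column 3"):
        Alignment(["a", "b"], ["AC-T", "AC-T"])


def test_alignment_round_trip(tmp_path, small_scenario):
    p = tmp_path / "aln.fasta"
    write_alignment(small_scenario.alignment, p)
    assert read_alignment(p) == small_scenario.alignment


# ---------------------------------------------------------------------------
# GenBank / GFF3
# ---------------------------------------------------------------------------


def _genbank_text(tmp_path):
    """Small annotated genome built with Biopython's own writer."""
    from Bio.Seq import Seq
    from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO
    import numpy as np

    rng = np.random.default_rng(3)
    seq = "".join(rng.choice(list("ACGT"), size=900))
    rec = SeqRecord(Seq(seq), id="mini", annotations={"molecule_type": "DNA"})
    rec.features = [
        SeqFeature(FeatureLocation(100, 200, strand=1), type="gene",
                   qualifiers={"gene": ["plain"]}),
        SeqFeature(
            CompoundLocation([FeatureLocation(300, 350, 1), FeatureLocation(400, 450, 1)]),
            type="gene", qualifiers={"gene": ["one_intron"]}),
        SeqFeature(
            CompoundLocation(
                [FeatureLocation(500, 530, 1), FeatureLocation(560, 590, 1),
                 FeatureLocation(620, 650, 1)]),
            type="gene", qualifiers={"gene": ["two_introns"]}),
        SeqFeature(FeatureLocation(700, 780, strand=-1), type="tRNA",
                   qualifiers={"gene": ["trnX"]}),
        SeqFeature(FeatureLocation(700, 780, strand=-1), type="gene",
                   qualifiers={"gene": ["trnX"]}),
    ]
    path = tmp_path / "mini.gb"
    SeqIO.write(rec, str(path), "genbank")
    return path


def test_read_genbank_features(tmp_path):
    path = _genbank_text(tmp_path)
    record, features = read_genbank_features(path)
    byname = {f.name: f for f in features}
    assert len(record) == 900
    assert byname["plain"].exons == ((101, 200),)
    assert byname["one_intron"].exons == ((301, 350), (401, 450))
    assert byname["one_intron"].introns == ((351, 400),)
    # a two-intron gene has three exons
    assert len(byname["two_introns"].exons) == 3
    assert byname["trnX"].kind == "tRNA" and byname["trnX"].strand == "-"


def test_read_genbank_missing_origin(tmp_path):
    p = tmp_path / "noseq.gb"
    p.write_text(
        "LOCUS       test 100 bp DNA linear PLN 01-JAN-2000\n"
        "FEATURES             Location/Qualifiers\n"
        "     gene            1..50\n"
        "                     /gene=\"g\"\n"
        "//\n"
    )
    with pytest.raises(FormatError):
        read_genbank_features(p)


def test_read_gff3_features(tmp_path):
    p = tmp_path / "mini.gff3"
    p.write_text(
        "##gff-version 3\n"
        "chr1\t.\tgene\t101\t200\t.\t+\t.\tID=g1;Name=plain\n"
        "chr1\t.\tgene\t301\t450\t.\t+\t.\tID=g2;Name=one_intron\n"
        "chr1\t.\texon\t301\t350\t.\t+\t.\tID=g2e1;Parent=g2\n"
        "chr1\t.\texon\t401\t450\t.\t+\t.\tID=g2e2;Parent=g2\n"
        "chr1\t.\ttRNA\t700\t780\t.\t-\t.\tID=t1;Name=trnX\n"
    )
    features = read_gff3_features(p)
    byname = {f.name: f for f in features}
    assert byname["plain"].exons == ((101, 200),)
    assert byname["one_intron"].exons == ((301, 350), (401, 450))
    assert byname["trnX"].kind == "tRNA"


def test_gene_feature_invariants():
    with pytest.raises(FormatError):
        GeneFeature("g", "gene", "+", ((10, 5),))
    with pytest.raises(FormatError):
        GeneFeature("g", "gene", "+", ((10, 50), (40, 80)))


# ---------------------------------------------------------------------------
# genotype CSV
# ---------------------------------------------------------------------------


def test_read_genotype_table(tmp_path):
    p = tmp_path / "g.csv"
    p.write_text("id,L1,L2\ns1,231/235,110/110\ns2,231/231,NA\n")
    t = read_genotype_table(p, ploidy=2)
    assert t.call("s1", "L1") == (231, 235)
    assert t.call("s2", "L1") == (231, 231)
    assert t.call("s2", "L2") is None


def test_read_genotype_table_wrong_count(tmp_path):
    p = tmp_path / "g.csv"
    p.write_text("id,L1\ns1,231\n")
    with pytest.raises(FormatError, match="'s1', 'L1'"):
        read_genotype_table(p, ploidy=2)


def test_genotype_round_trip(tmp_path):
    t = GenotypeTable(
        ["s1", "s2"],
        ["L1", "L2"],
        {("s1", "L1"): (1, 2), ("s2", "L1"): (2, 2), ("s1", "L2"): (5, 9)},
        ploidy=2,
    )
    p = tmp_path / "g.csv"
    write_genotype_table(t, p)
    back = read_genotype_table(p, ploidy=2)
    assert back.calls == t.calls and back.individuals == t.individuals


def test_revcomp():
    assert revcomp("ACGTN") == "NACGT"
    assert revcomp(revcomp("GATTACA")) == "GATTACA"
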