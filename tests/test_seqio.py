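"""FASTA/GFF3 round trips, coordinate conventions, translation, stop profiles."""

import numpy as np
import pytest

from hrp import seqio
from hrp.seqio import GeneModel, SeqRecord, SeqIOError

from conftest import random_dna


def test_fasta_read_concatenates_wrapped_lines_and_uppercases(tmp_path):
    p = tmp_path / "a.fa"
    p.write_text(">s1\nAC\ngt\n>s2\nACGTN\n")
    recs = seqio.read_fasta(p, "dna")
    assert [(r.id, r.seq) for r in recs] == [("s1", "ACGT"), ("s2", "ACGTN")]


def test_fasta_duplicate_id_raises_with_id(tmp_path):
    p = tmp_path / "a.fa"
    p.write_text(">a\nAC\n>a\nGT\n")
    with pytest.raises(SeqIOError, match="'a'"):
        seqio.read_fasta(p, "dna")


def test_fasta_illegal_character_reports_position(tmp_path):
    p = tmp_path / "a.fa"
    p.write_text(">a\nACQT\n")
    with pytest.raises(SeqIOError, match="position 2"):
        seqio.read_fasta(p, "dna")


def test_fasta_round_trip_wraps_at_60(tmp_path):
    rng = np.random.default_rng(0)
    recs = [SeqRecord(id=f"s{i}", seq=random_dna(137, rng), kind="dna") for i in range(3)]
    p = tmp_path / "out.fa"
    seqio.write_fasta(recs, p)
    lines = p.read_text().splitlines()
    assert max(len(l) for l in lines if not l.startswith(">")) == 60
    back = seqio.read_fasta(p, "dna")
    assert [(r.id, r.seq) for r in back] == [(r.id, r.seq) for r in recs]


GFF = """##gff-version 3
chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=g1
chr1\tsrc\tmRNA\t101\t200\t.\t+\t.\tID=m1;Parent=g1
chr1\tsrc\tCDS\t101\t200\t.\t+\t0\tParent=m1
"""


def test_gff3_one_based_inclusive_converts_to_half_open(tmp_path):
    p = tmp_path / "a.gff3"
    p.write_text(GFF)
    models = seqio.read_gff3(p)
    assert len(models) == 1
    assert models[0].exons == [(100, 200)]
    assert models[0].cds_length == 100


def test_gff3_cds_without_parent_errors(tmp_path):
    p = tmp_path / "a.gff3"
    p.write_text("chr1\ts\tCDS\t1\t9\t.\t+\t0\tID=x\n")
    with pytest.raises(SeqIOError, match="Parent"):
        seqio.read_gff3(p)


def test_gff3_end_before_start_errors(tmp_path):
    p = tmp_path / "a.gff3"
    p.write_text("chr1\ts\tgene\t20\t10\t.\t+\t.\tID=g\n")
    with pytest.raises(SeqIOError, match="end"):
        seqio.read_gff3(p)


def test_minus_strand_two_exon_translation_matches_hand_oracle(tmp_path):
    # 60-nt fixture: gene on '-' strand, transcript = revcomp(exon2)+revcomp(exon1)
    # hand translation below was worked out from the genetic code directly
    exon1 = "TTACATGGCGGC"  # genomic [10, 22)
    exon2 = "CATCGCCAT"  # genomic [40, 49)
    rng = np.random.default_rng(3)
    genome_seq = random_dna(10, rng) + exon1 + random_dna(18, rng) + exon2 + random_dna(11, rng)
    genome = SeqRecord(id="chr1", seq=genome_seq, kind="dna")
    model = GeneModel(id="m", seqid="chr1", strand="-", exons=[(10, 22), (40, 49)])
    protein, stops = seqio.extract_and_translate(model, genome)
    # transcript = revcomp("TTACATGGCGGC"+"CATCGCCAT") = ATGGCGATGGCCGCCATGTAA
    assert protein == "MAMAAM"
    assert stops == 0
    assert not model.pseudogene


def test_gff3_round_trip_preserves_models(tmp_path, small_truth):
    models = small_truth.truth_models
    p = tmp_path / "round.gff3"
    seqio.write_gff3(models, p)
    back = seqio.read_gff3(p)
    assert len(back) == len(models)
    orig = {m.id: m for m in models}
    for m in back:
        o = orig[m.id]
        assert (m.seqid, m.strand, m.exons) == (o.seqid, o.strand, o.exons)
        assert m.pseudogene == o.pseudogene


@pytest.mark.parametrize(
    "cds,strand,protein,stops",
    [
        ("ATGGCATAA", "+", "MA", 0),
        ("TTACGCCAT", "-", "MA", 0),  # revcomp = ATGGCGTAA
        ("ATGTAAGCATAA", "+", "M*A", 1),
    ],
)
def test_translation_examples(cds, strand, protein, stops):
    genome = SeqRecord(id="g", seq=cds, kind="dna")
    model = GeneModel(id="m", seqid="g", strand=strand, exons=[(0, len(cds))])
    got, n = seqio.extract_and_translate(model, genome)
    assert got == protein
    assert n == stops
    assert model.pseudogene == (stops > 0)


def test_frameshift_sets_flag_instead_of_raising():
    genome = SeqRecord(id="g", seq="ATGGCATA", kind="dna")  # 8 nt
    model = GeneModel(id="m", seqid="g", strand="+", exons=[(0, 8)])
    protein, _ = seqio.extract_and_translate(model, genome)
    assert model.frameshift and model.pseudogene
    assert protein == "MA"


def test_truth_models_satisfy_cds_length_identity(small_truth):
    # exon lengths == 3 * len(protein) + 3 (stop codon) when clean
    for m in small_truth.truth_models:
        if not m.frameshift and m.internal_stop_count == 0:
            assert m.cds_length == 3 * len(m.protein) + 3


def _brute_stop_counts(dna):
    from hrp.seqio import STOP_CODONS, revcomp

    out = []
    for s in (dna, revcomp(dna)):
        for off in range(3):
            out.append(
                sum(
                    1
                    for i in range(off, len(s) - 2, 3)
                    if s[i : i + 3] in STOP_CODONS
                )
            )
    return tuple(out[:3] + out[3:])


@pytest.mark.parametrize("dna", ["TAA", "ATGTAGATGTGAATGTAAGGG", "ACGT"])
def test_six_frame_stop_profile_matches_exhaustive_scan(dna):
    assert seqio.six_frame_stop_profile(dna) == _brute_stop_counts(dna)


def test_six_frame_profile_of_revcomp_is_frame_swapped():
    rng = np.random.default_rng(11)
    for _ in range(20):
        dna = random_dna(int(rng.integers(3, 120)), rng)
        p = seqio.six_frame_stop_profile(dna)
        q = seqio.six_frame_stop_profile(seqio.revcomp(dna))
        assert q == p[3:] + p[:3]


def test_six_frame_rejects_non_dna():
    with pytest.raises(SeqIOError):
        seqio.six_frame_stop_profile("ACGU")


def test_bed6_export(tmp_path, small_truth):
    p = tmp_path / "m.bed"
    seqio.write_bed6(small_truth.truth_models[:3], p)
    rows = [l.split("\t") for l in p.read_text().splitlines()]
    assert all(len(r) == 6 for r in rows)
    m = small_truth.truth_models[0]
    assert rows[0][0] == m.seqid and int(rows[0][1]) == m.start and int(rows[0][2]) == m.end
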