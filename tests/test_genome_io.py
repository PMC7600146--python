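"""Genome reading, CDS/tRNA extraction and genome summaries."""

import pytest
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO
from hypothesis import given
from hypothesis import strategies as st

from phagetools import (
    AnnotatedGenome,
    CodonBiasSpec,
    CompletenessPolicy,
    ConsistencyError,
    Feature,
    InputError,
    ValidationError,
    extract_cds,
    extract_trna,
    gc_percent,
    generate_genome,
    read_genome,
    reverse_complement,
    summarize_genome,
    write_genbank,
)
from phagetools.genome import GENETIC_CODE, STOP_CODONS
from phagetools.codons import CODONS

dna = st.text(alphabet="ACGT", min_size=1, max_size=300)


def _write_record(tmp_path, record, name="g.gbk"):
    path = tmp_path / name
    with open(path, "w") as fh:
        SeqIO.write([record], fh, "genbank")
    return path


def test_read_genbank_preserves_feature_counts(tmp_path):
    """A record with 3 CDS and 1 tRNA yields exactly those features."""
    rec = SeqRecord(
        Seq("ATGAAATAA" * 20), id="mini", name="mini",
        annotations={"molecule_type": "DNA"},
    )
    for i in range(3):
        rec.features.append(
            SeqFeature(SimpleLocation(9 * i, 9 * i + 9, strand=1), type="CDS")
        )
    rec.features.append(
        SeqFeature(
            SimpleLocation(100, 177, strand=1), type="tRNA",
            qualifiers={"anticodon": ["tgg"]},
        )
    )
    rec.features.append(SeqFeature(SimpleLocation(0, 180, strand=1), type="misc_feature"))
    g = read_genome(_write_record(tmp_path, rec))
    assert len(g.features_of_kind("CDS")) == 3
    assert len(g.features_of_kind("tRNA")) == 1
    assert len(g.features_of_kind("other")) == 1


def test_multi_record_genbank_is_pooled(tmp_path):
    recs = []
    for i, seq in enumerate(["ATGAAATAA", "ATGCCCTAA"]):
        r = SeqRecord(Seq(seq), id=f"ctg{i}", name=f"ctg{i}",
                      annotations={"molecule_type": "DNA"})
        r.features.append(SeqFeature(SimpleLocation(0, 9, strand=1), type="CDS"))
        recs.append(r)
    path = tmp_path / "draft.gbk"
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "genbank")
    g = read_genome(path, genome_id="draft")
    assert g.length == 18
    cds = extract_cds(g)
    assert [c.nt for c in cds] == ["ATGAAATAA", "ATGCCCTAA"]


def test_fasta_gff3_reader_and_bounds(tmp_path):
    fasta = tmp_path / "g.fa"
    fasta.write_text(">chr1\nATGAAATAAG\n")
    gff = tmp_path / "g.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr1\t.\tCDS\t1\t9\t.\t+\t0\tID=cds1;product=hypothetical protein\n"
    )
    g = read_genome(fasta, format="fasta+gff3", gff=gff)
    assert extract_cds(g)[0].nt == "ATGAAATAA"

    bad = tmp_path / "bad.gff3"
    bad.write_text("##gff-version 3\nchr1\t.\tCDS\t11\t16\t.\t+\t0\tID=cds2\n")
    with pytest.raises(ValidationError, match="cds2"):
        read_genome(fasta, format="fasta+gff3", gff=bad)


def test_fasta_gff3_id_mismatch(tmp_path):
    fasta = tmp_path / "g.fa"
    fasta.write_text(">chr1\nATGAAATAA\n")
    gff = tmp_path / "g.gff3"
    gff.write_text("##gff-version 3\nchrX\t.\tCDS\t1\t9\t.\t+\t0\tID=c\n")
    with pytest.raises(ConsistencyError):
        read_genome(fasta, format="fasta+gff3", gff=gff)


def test_missing_file_and_unknown_format(tmp_path):
    with pytest.raises(InputError):
        read_genome(tmp_path / "absent.gbk")
    (tmp_path / "x.gbk").write_text("not genbank at all\n")
    with pytest.raises(InputError):
        read_genome(tmp_path / "x.gbk")
    with pytest.raises(InputError):
        read_genome(tmp_path / "x.gbk", format="embl")


def test_minus_strand_cds_is_reverse_complemented():
    g = AnnotatedGenome(
        "g", "ATGCATGGGGGG",
        [Feature(kind="CDS", start=1, end=6, strand="-", feature_id="c1")],
    )
    # ATGCAT is its own reverse complement
    assert extract_cds(g)[0].nt == "ATGCAT"


@pytest.mark.parametrize(
    "nt,reason",
    [
        ("ATGAAATT", "length not multiple of 3"),
        ("ATGAAATAA", None),
    ],
)
def test_frame_completeness_check(nt, reason):
    g = AnnotatedGenome(
        "g", nt + "A" * 10,
        [Feature(kind="CDS", start=1, end=len(nt), strand="+", feature_id="c")],
    )
    (cds,) = extract_cds(g)
    assert cds.exclusion_reason == reason
    assert cds.is_complete is (reason is None)


def test_partial_flag_counts_as_incomplete():
    spec = CodonBiasSpec(n_cds=23, cds_length_codons=(5, 15), seed=3, n_partial_cds=3)
    g = generate_genome(spec, genome_id="px")
    cds = extract_cds(g)
    assert len(cds) == 23
    assert sum(c.is_complete for c in cds) == 20


def test_optional_start_and_internal_stop_checks():
    seq = "CCCAAATAA" + "ATGTAAAAATAA"
    g = AnnotatedGenome(
        "g", seq,
        [
            Feature(kind="CDS", start=1, end=9, strand="+", feature_id="nostart"),
            Feature(kind="CDS", start=10, end=21, strand="+", feature_id="istop"),
        ],
    )
    strict = CompletenessPolicy(require_start=True, check_internal_stop=True)
    c1, c2 = extract_cds(g, strict)
    assert "start codon" in c1.exclusion_reason
    assert "internal stop" in c2.exclusion_reason
    assert all(c.is_complete for c in extract_cds(g))  # default policy accepts both


def test_complete_cds_have_no_internal_stop_under_strict_policy(small_genome):
    policy = CompletenessPolicy(check_internal_stop=True, require_start=True)
    for cds in extract_cds(small_genome, policy):
        assert cds.is_complete, cds.exclusion_reason
        body = [cds.nt[i : i + 3] for i in range(0, len(cds.nt) - 3, 3)]
        assert not any(c in STOP_CODONS for c in body)


@pytest.mark.parametrize(
    "seq,expected",
    [("GGCC", 100.0), ("GATTACA", 28.6), ("ATAT", 0.0), ("GCNNNN", 100.0)],
)
def test_gc_percent(seq, expected):
    assert gc_percent(seq) == expected


def test_gc_percent_all_ambiguous_raises():
    with pytest.raises(ValidationError):
        gc_percent("NNNN")


def test_summary_functional_percentage():
    feats = [
        Feature(
            kind="CDS", start=10 * i + 1, end=10 * i + 9, strand="+",
            qualifiers={"product": "DNA helicase" if i < 15 else "hypothetical protein"},
            feature_id=f"c{i}",
        )
        for i in range(68)
    ]
    g = AnnotatedGenome("g", "ACGT" * 200, feats)
    s = summarize_genome(g)
    assert (s.n_cds, s.n_functional, s.functional_percent) == (68, 15, 22.1)


def test_trna_extraction(small_genome):
    (trna,) = extract_trna(small_genome)
    assert trna.anticodon == "TGG"
    assert trna.decoded_codon == "CCA"
    assert trna.amino_acid == "Pro"
    assert trna.length_bp == 77


def test_trna_anticodon_cat_decodes_atg_met():
    g = AnnotatedGenome(
        "g", "A" * 100,
        [Feature(kind="tRNA", start=1, end=77, strand="+",
                 qualifiers={"anticodon": "CAT"}, feature_id="t1")],
    )
    (t,) = extract_trna(g)
    assert (t.decoded_codon, t.amino_acid) == ("ATG", "Met")


def test_trna_genbank_style_anticodon_qualifier():
    g = AnnotatedGenome(
        "g", "A" * 100,
        [Feature(kind="tRNA", start=1, end=77, strand="+",
                 qualifiers={"anticodon": "(pos:34..36,aa:Pro,seq:tgg)"},
                 feature_id="t1")],
    )
    assert extract_trna(g)[0].decoded_codon == "CCA"


def test_trna_missing_anticodon_skipped_with_warning():
    g = AnnotatedGenome(
        "g", "A" * 100,
        [Feature(kind="tRNA", start=1, end=77, strand="+", feature_id="t1")],
    )
    with pytest.warns(UserWarning, match="anticodon"):
        assert extract_trna(g) == []


def test_no_trna_features_gives_empty_list():
    g = AnnotatedGenome("g", "ACGT")
    assert extract_trna(g) == []


def test_feature_validation():
    with pytest.raises(ValidationError):
        Feature(kind="CDS", start=5, end=2, strand="+")
    with pytest.raises(ValidationError):
        Feature(kind="CDS", start=1, end=3, strand="x")
    with pytest.raises(ValidationError):
        AnnotatedGenome("g", "ACGT", [Feature(kind="CDS", start=1, end=10, strand="+")])
    with pytest.raises(ValidationError):
        AnnotatedGenome("g", "")


def test_genbank_round_trip(tmp_path, small_genome):
    """Write->read preserves sequence and CDS/tRNA coordinate sets."""
    path = tmp_path / "rt.gbk"
    write_genbank(small_genome, path)
    g2 = read_genome(path, genome_id=small_genome.genome_id)
    assert g2.sequence == small_genome.sequence
    for kind in ("CDS", "tRNA"):
        orig = {(f.start, f.end, f.strand) for f in small_genome.features_of_kind(kind)}
        back = {(f.start, f.end, f.strand) for f in g2.features_of_kind(kind)}
        assert back == orig


@pytest.mark.parametrize("codon", CODONS)
def test_anticodon_decoding_is_an_involution(codon):
    assert reverse_complement(reverse_complement(codon)) == codon


@given(dna)
def test_gc_of_purine_swapped_sequence_is_complementary(seq):
    """Swapping A<->G and T<->C turns GC% into 100-GC%."""
    swapped = seq.translate(str.maketrans("AGTC", "GACT"))
    assert gc_percent(seq, None) == pytest.approx(100 - gc_percent(swapped, None))


def test_genetic_code_is_complete():
    assert set(GENETIC_CODE) == set(CODONS)
    assert sum(aa == "*" for aa in GENETIC_CODE.values()) == 3
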