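import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given
from hypothesis import strategies as st

from genevidence import seqio
from genevidence.simulate import NeighborhoodSpec, simulate_neighborhood

from _oracles import brute_n50

dna_st = st.text(alphabet="ACGTacgt", min_size=1, max_size=200)


class TestFasta:
    def test_basic_record(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">s1\nACgtN\n")
        (sc,) = seqio.read_fasta(p)
        assert sc.id == "s1" and sc.length == 5 and sc.sequence == "ACgtN"

    def test_round_trip_preserves_case(self, tmp_path, default_sim):
        record, _ = default_sim
        p = tmp_path / "sim.fa"
        seqio.write_fasta(record.scaffolds, p)
        back = seqio.read_fasta(p)
        assert back == record.scaffolds
        # writing again gives identical bytes (normalized wrapping)
        p2 = tmp_path / "sim2.fa"
        seqio.write_fasta(back, p2)
        assert p.read_bytes() == p2.read_bytes()

    def test_blank_interleaved_lines(self, tmp_path):
        p = tmp_path / "b.fa"
        p.write_text(">x\nACGT\n\nACG\n>y\n\nGG\n")
        recs = seqio.read_fasta(p)
        assert [(r.id, r.length) for r in recs] == [("x", 7), ("y", 2)]

    def test_malformed_header_raises(self, tmp_path):
        p = tmp_path / "bad.fa"
        p.write_text("ACGT\n>s1\nAC\n")
        with pytest.raises(ValueError, match="line 1"):
            seqio.read_fasta(p)

    def test_empty_record_raises(self, tmp_path):
        p = tmp_path / "bad2.fa"
        p.write_text(">s1\n>s2\nAC\n")
        with pytest.raises(ValueError, match="empty record"):
            seqio.read_fasta(p)


class TestGff:
    def test_coordinate_convention(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(
            "##gff-version 3\n"
            "sc1\t.\tgene\t101\t200\t.\t+\t.\tID=g1\n"
        )
        (ann,) = seqio.read_gff(p)
        assert ann.exons == ((100, 200),) and ann.strand == "+"

    def test_two_exon_gene(self, tmp_path):
        p = tmp_path / "b.gff3"
        p.write_text(
            "##gff-version 3\n"
            "sc1\t.\tgene\t1\t90\t.\t+\t.\tID=g1\n"
            "sc1\t.\tmRNA\t1\t90\t.\t+\t.\tID=g1.t1;Parent=g1\n"
            "sc1\t.\texon\t1\t30\t.\t+\t.\tID=e1;Parent=g1.t1\n"
            "sc1\t.\texon\t61\t90\t.\t+\t.\tID=e2;Parent=g1.t1\n"
        )
        (ann,) = seqio.read_gff(p)
        assert ann.exons == ((0, 30), (60, 90))

    def test_round_trip_on_simulator_output(self, tmp_path, default_sim):
        record, _ = default_sim
        p = tmp_path / "sim.gff3"
        seqio.write_gff(record.annotations, p)
        back = seqio.read_gff(p)
        assert sorted(back, key=lambda a: a.gene_id) == sorted(
            record.annotations, key=lambda a: a.gene_id
        )

    def test_orphan_exon_raises(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text(
            "##gff-version 3\n"
            "sc1\t.\tgene\t1\t90\t.\t+\t.\tID=g1\n"
            "sc1\t.\texon\t1\t30\t.\t+\t.\tID=lost\n"
        )
        with pytest.raises(ValueError, match="lost"):
            seqio.read_gff(p)


class TestSequenceOps:
    @pytest.mark.parametrize(
        "dna,expected",
        [
            ("TTGTGCAGGCTCAGGTTG", "CAACCTGAGCCTGCACAA"),
            ("ACGT", "ACGT"),
            ("acgtN", "Nacgt"),
        ],
    )
    def test_revcomp_examples(self, dna, expected):
        # oracle: base-by-base complement, then reversal
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
        oracle = "".join(comp.get(c, comp[c.upper()].lower()) for c in reversed(dna))
        assert seqio.revcomp(dna) == expected == oracle

    @given(dna_st)
    def test_revcomp_involution(self, s):
        assert seqio.revcomp(seqio.revcomp(s)) == s

    @pytest.mark.parametrize(
        "dna,frame,expected",
        [
            ("CAACCTGAGCCTGCACAA", 1, "NLSLH"),
            ("ATG", 0, "M"),
            ("TAA", 0, "*"),
            ("ATNGGG", 0, "XG"),
        ],
    )
    def test_translate_examples(self, dna, frame, expected):
        assert seqio.translate(dna, frame) == expected

    @given(st.text(alphabet="ACGT", min_size=3, max_size=120),
           st.integers(0, 2))
    def test_reverse_strand_translation_matches_biopython(self, s, frame):
        ours = seqio.translate(seqio.revcomp(s), frame)
        rc = Seq(s).reverse_complement()[frame:]
        ref = str(rc[: 3 * (len(rc) // 3)].translate())
        assert ours == ref

    def test_translate_length_contract(self):
        for frame in (0, 1, 2):
            assert len(seqio.translate("ACGTACGTAC", frame)) == (10 - frame) // 3

    def test_non_iupac_rejected(self):
        with pytest.raises(ValueError):
            seqio.revcomp("ACGU")
        with pytest.raises(ValueError):
            seqio.translate("AC-")

    @pytest.mark.parametrize(
        "seq,expected", [("GGCC", 1.0), ("ATAT", 0.0), ("GCNNAT", 0.5)]
    )
    def test_gc_fraction_examples(self, seq, expected):
        assert seqio.gc_fraction(seq) == expected

    def test_gc_all_n_is_undefined(self):
        assert seqio.gc_fraction("NNN") is None

    def test_gc_empty_region_raises(self):
        with pytest.raises(ValueError):
            seqio.gc_fraction("ACGT", (2, 2))

    @given(st.text(alphabet="ACGTacgt", min_size=1, max_size=100))
    def test_gc_plus_at_is_one(self, s):
        gc = seqio.gc_fraction(s)
        at = sum(s.count(c) for c in "ATat") / len(s)
        assert gc + at == pytest.approx(1.0)

    def test_masked_and_gaps(self):
        assert seqio.masked_fraction("acgtACGT") == 0.5
        assert seqio.gap_runs("AANNNAA") == [(2, 5)]
        assert seqio.masked_fraction("ACGT") == 0.0
        assert seqio.gap_runs("ACGT") == []
        assert seqio.gap_runs("NNayNcNN") == [(0, 2), (4, 5), (6, 8)]


class TestN50:
    @pytest.mark.parametrize(
        "lengths,expected", [([10], 10), ([1, 2, 3, 4, 10], 10), ([5, 5, 5, 5], 5)]
    )
    def test_examples(self, lengths, expected):
        assert seqio.n50(lengths) == expected == brute_n50(lengths)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            seqio.n50([])

    def test_matches_brute_force_on_random_lists(self, rng):
        for _ in range(1000):
            lengths = rng.integers(1, 500, size=rng.integers(1, 40)).tolist()
            assert seqio.n50(lengths) == brute_n50(lengths)

    def test_bounded_by_min_and_max(self, rng):
        for _ in range(50):
            lengths = rng.integers(1, 10_000, size=20).tolist()
            v = seqio.n50(lengths)
            assert min(lengths) <= v <= max(lengths)


class TestRecordsAndStats:
    def test_assembly_stats(self):
        scaffolds = [
            seqio.Scaffold("a", "GGGGcccc"),
            seqio.Scaffold("b", "ATNNNNAT"),
        ]
        stats = seqio.assembly_stats(scaffolds)
        assert stats.n50 == 8 and stats.total_length == 16
        assert stats.gc_fraction == pytest.approx(8 / 12)
        assert stats.masked_fraction == pytest.approx(4 / 16)
        assert stats.gap_fraction == pytest.approx(4 / 16)

    def test_record_validation(self):
        sc = seqio.Scaffold("s", "ACGTACGT")
        with pytest.raises(ValueError, match="unknown scaffold"):
            seqio.AssemblyRecord(
                genome_id="g",
                scaffolds=[sc],
                annotations=[seqio.GeneAnnotation("x", "other", "+", ((0, 4),))],
            )
        with pytest.raises(ValueError, match="bounds"):
            seqio.AssemblyRecord(
                genome_id="g",
                scaffolds=[sc],
                annotations=[seqio.GeneAnnotation("x", "s", "+", ((0, 99),))],
            )

    def test_annotation_invariants(self):
        with pytest.raises(ValueError, match="overlap"):
            seqio.GeneAnnotation("x", "s", "+", ((0, 10), (5, 15)))
        with pytest.raises(ValueError, match="strand"):
            seqio.GeneAnnotation("x", "s", "*", ((0, 10),))

    def test_metadata_tsv_round_trip(self, tmp_path):
        metas = [
            seqio.AssemblyMetadata("g1", 46.0, 67526, 931132),
            seqio.AssemblyMetadata("g2", None, None, None),
        ]
        p = tmp_path / "meta.tsv"
        seqio.write_metadata_tsv(metas, p)
        assert seqio.read_metadata_tsv(p) == metas

    def test_reverse_complement_record_round_trip(self, default_sim):
        record, _ = default_sim
        back = seqio.reverse_complement_record(
            seqio.reverse_complement_record(record)
        )
        assert back.scaffolds == record.scaffolds
        assert sorted(back.annotations, key=lambda a: a.gene_id) == sorted(
            record.annotations, key=lambda a: a.gene_id
        )
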