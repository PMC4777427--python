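import numpy as np
import pytest

from genevidence.seqio import revcomp
from genevidence.simulate import back_translate
from genevidence.splice import (
    ExonHit,
    ScoringScheme,
    curate_boundaries,
    exon_report,
    spliced_align,
)

from _oracles import local_codon_score, oracle_spliced_score

SMALL = ScoringScheme(min_intron=8)


def _perfect_score(protein, scheme=None):
    mat = (scheme or ScoringScheme()).matrix
    return sum(mat[aa, aa] for aa in protein)


class TestSingleExon:
    def test_exact_backtranslation_single_exon(self):
        protein = "MKTAYIDQLE"
        dna = back_translate(protein)
        aln = spliced_align(protein, dna)
        assert aln.strand == "+"
        assert len(aln.exons) == 1 and aln.n_introns == 0
        assert aln.exons[0].genomic == (0, 30)
        assert aln.exons[0].protein == (0, 10)
        assert aln.coverage == 1.0
        assert aln.score == _perfect_score(protein)

    def test_strand_symmetry(self):
        protein = "MKTAYIDQLE"
        dna = back_translate(protein)
        fwd = spliced_align(protein, dna)
        rev = spliced_align(protein, revcomp(dna))
        assert rev.score == fwd.score
        assert rev.strand == "-"
        assert rev.exons[0].genomic == (0, 30)

    def test_empty_inputs_raise(self):
        with pytest.raises(ValueError):
            spliced_align("", "ACGT")
        with pytest.raises(ValueError):
            spliced_align("MKTAYIDQLE", "")
        with pytest.raises(ValueError):
            spliced_align("MKT", "ATGAAAACC")


class TestPlantedGene:
    def test_recovers_simulated_exons_exactly(self, small_sim):
        record, truth = small_sim
        seq = record.scaffolds[0].sequence
        lo, hi = truth.region
        aln = spliced_align(truth.target_protein, seq[lo:hi])
        expected = [(s - lo, e - lo) for s, e, _ in truth.target_exons]
        assert [e.genomic for e in aln.exons] == expected
        assert aln.n_introns == len(expected) - 1
        assert aln.coverage == 1.0

    def test_locality_n_flanks_leave_score_unchanged(self, small_sim):
        record, truth = small_sim
        seq = record.scaffolds[0].sequence
        lo, hi = truth.region
        base = spliced_align(truth.target_protein, seq[lo:hi])
        padded = spliced_align(
            truth.target_protein, "N" * 500 + seq[lo:hi] + "N" * 500
        )
        assert padded.score == base.score
        assert len(padded.exons) == len(base.exons)

    def test_unrelated_flanks_never_reduce_score(self, small_sim, rng):
        record, truth = small_sim
        seq = record.scaffolds[0].sequence
        lo, hi = truth.region
        base = spliced_align(truth.target_protein, seq[lo:hi])
        flank = "".join(rng.choice(list("ACGT"), size=300))
        padded = spliced_align(truth.target_protein, flank + seq[lo:hi] + flank)
        assert padded.score >= base.score

    def test_gap_run_inside_exon_blocks_it(self, small_sim):
        """N runs are impassable in exons: masking one exon loses only it."""
        record, truth = small_sim
        seq = list(record.scaffolds[0].sequence)
        lo, hi = truth.region
        s, e, _ = truth.target_exons[1]
        for i in range(s, e):
            seq[i] = "N"
        aln = spliced_align(truth.target_protein, "".join(seq)[lo:hi])
        kept = [(s2 - lo, e2 - lo) for s2, e2, _ in truth.target_exons]
        recovered = [x.genomic for x in aln.exons]
        assert kept[1] not in recovered
        assert kept[0] in recovered and kept[2] in recovered


class TestOracleAgreement:
    def _random_instance(self, rng):
        """Small instance with a planted homology and few splice sites."""
        aas = list("ARNDCQEGHILKMFPSTWYV")
        while True:
            protein = "".join(rng.choice(aas, size=rng.integers(5, 8)))
            core = back_translate(protein)
            n_extra = int(rng.integers(0, 12))
            extra = "".join(rng.choice(list("ACGT"), size=n_extra))
            pos = int(rng.integers(0, n_extra + 1))
            dna = extra[:pos] + core + extra[pos:]
            if len(dna) > 42:
                continue
            # scramble a little so gaps/introns can pay off
            chars = list(dna)
            for i in range(len(chars)):
                if rng.random() < 0.15:
                    chars[i] = rng.choice(list("ACGT"))
            if rng.random() < 0.3:  # occasionally plant an N run
                p = int(rng.integers(0, len(chars) - 3))
                for i in range(p, min(p + 3, len(chars))):
                    chars[i] = "N"
            dna = "".join(chars)
            donors = sum(
                1 for j in range(len(dna) - 1) if dna[j : j + 2] == "GT"
            )
            acceptors = sum(
                1 for j in range(2, len(dna) + 1) if dna[j - 2 : j] == "AG"
            )
            if donors <= 5 and acceptors <= 5:
                return protein, dna

    def test_dp_matches_exhaustive_enumeration(self, rng):
        for _ in range(60):
            protein, dna = self._random_instance(rng)
            expected = oracle_spliced_score(protein, dna, SMALL)
            got = spliced_align(protein, dna, SMALL).score
            assert got == int(round(expected)), (protein, dna)

    def test_infinite_intron_penalty_reduces_to_local_codon_alignment(self, rng):
        no_introns = ScoringScheme(min_intron=8, intron_penalty=-(10**6))
        for _ in range(25):
            protein, dna = self._random_instance(rng)
            expected = max(
                local_codon_score(protein, dna, no_introns),
                local_codon_score(protein, revcomp(dna), no_introns),
            )
            got = spliced_align(protein, dna, no_introns).score
            assert got == int(round(expected)), (protein, dna)


class TestCuration:
    def _two_exon_case(self):
        """A 2-exon gene whose junction placement is score-ambiguous.

        The VQ codons (GTGCAG) are duplicated on both sides of a 30-nt
        intron whose interior also carries a shifted AG acceptor, so the
        intron can legally sit after residue 6 or after residue 8 with
        identical score.
        """
        protein = "MKTAYIVQDQLE"
        dna = (
            back_translate("MKTAYI")      # [0, 18)
            + "GTGCAG"                     # VQ, [18, 24)
            + "GT" + "C" * 20 + "AGGTGC" + "AG"  # intron A [24, 54)
            + "GTGCAG"                     # VQ again, [54, 60)
            + back_translate("DQLE")       # [60, 72)
        )
        return protein, dna

    def test_fixed_point_when_on_reference(self, small_sim):
        record, truth = small_sim
        seq = record.scaffolds[0].sequence
        lo, hi = truth.region
        aln = spliced_align(truth.target_protein, seq[lo:hi])
        ref = [tuple(e.protein) for e in aln.exons]
        curated = curate_boundaries(aln, ref, seq[lo:hi], truth.target_protein)
        assert [e.genomic for e in curated.exons] == [e.genomic for e in aln.exons]
        assert curated.score == aln.score

    def test_snaps_ambiguous_junction(self):
        protein, dna = self._two_exon_case()
        aln = spliced_align(protein, dna)
        assert len(aln.exons) == 2
        bp = aln.exons[0].protein[1]
        assert bp in (6, 8)
        # ask for the other consistent placement, two codons away
        ref = [(0, 8), (8, 12)] if bp == 6 else [(0, 6), (6, 12)]
        curated = curate_boundaries(aln, ref, dna, protein)
        assert curated.exons[0].protein[1] == ref[0][1]
        assert curated.score == aln.score  # duplicated codons: score neutral
        assert curated.coverage == aln.coverage

    def test_no_valid_site_leaves_alignment_flagged(self, small_sim):
        record, truth = small_sim
        seq = record.scaffolds[0].sequence
        lo, hi = truth.region
        aln = spliced_align(truth.target_protein, seq[lo:hi])
        bp = aln.exons[0].protein[1]
        ref = [(0, bp + 1), (bp + 1, len(truth.target_protein))]
        curated = curate_boundaries(aln, ref, seq[lo:hi], truth.target_protein)
        if curated.exons[0].protein[1] == bp:  # not snapped: must be flagged
            assert any("no_valid_splice_site" in f or "blocked" in f
                       for f in curated.flags)

    def test_overlapping_reference_raises(self, small_sim):
        record, truth = small_sim
        seq = record.scaffolds[0].sequence
        lo, hi = truth.region
        aln = spliced_align(truth.target_protein, seq[lo:hi])
        with pytest.raises(ValueError, match="overlap"):
            curate_boundaries(
                aln, [(0, 30), (20, 60)], seq[lo:hi], truth.target_protein
            )


class TestExonReport:
    def test_domain_overlap_rows(self):
        aln_exons = (
            ExonHit(genomic=(0, 30), protein=(0, 10)),
            ExonHit(genomic=(60, 90), protein=(10, 20)),
        )
        from genevidence.splice import SplicedAlignment

        aln = SplicedAlignment(
            exons=aln_exons, strand="+", score=100, coverage=1.0, n_introns=1
        )
        table = exon_report(aln, {"FRK": (12, 20), "LZ": (0, 5)})
        assert list(table["domains"]) == ["LZ", "FRK"]
        assert list(table["aligned_aa"]) == [10, 10]

    def test_empty_alignment_empty_table(self):
        from genevidence.splice import SplicedAlignment

        aln = SplicedAlignment(exons=(), strand="+", score=0, coverage=0.0)
        assert exon_report(aln, {"FRK": (0, 10)}).empty
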