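import warnings

import numpy as np
import pytest

from genevidence import scenarios
from genevidence.seqio import (
    AssemblyMetadata,
    AssemblyRecord,
    GeneAnnotation,
    Scaffold,
    reverse_complement_record,
)
from genevidence.simulate import (
    FragmentationModel,
    NeighborhoodSpec,
    fragment_assembly,
    simulate_neighborhood,
)
from genevidence.synteny import (
    STATUSES,
    classify_locus,
    co_annotation_contingency,
    quality_stratify,
)


def _toy_record(genes, seq_len=4000, genome_id="toy"):
    """genes: list of (gene_id, scaffold_id, strand, (start, end))."""
    scaffold_ids = {g[1] for g in genes}
    scaffolds = [
        Scaffold(sid, "ACGT" * (seq_len // 4)) for sid in sorted(scaffold_ids)
    ]
    annotations = [
        GeneAnnotation(g, sid, strand, ((s, e),)) for g, sid, strand, (s, e) in genes
    ]
    return AssemblyRecord(genome_id=genome_id, scaffolds=scaffolds,
                          annotations=annotations)


class TestClassifyLocus:
    def test_annotated_between_flanks(self):
        rec = _toy_record([
            ("ppp1r3f", "s1", "-", (100, 400)),
            ("foxp3", "s1", "+", (600, 900)),
            ("ccdc22", "s1", "-", (1100, 1400)),
        ])
        a = classify_locus(rec, "foxp3", "ppp1r3f", "ccdc22")
        assert a.status == "ANNOTATED"
        assert a.intergenic_interval == (400, 1100)

    def test_spanned_unannotated(self):
        rec = _toy_record([
            ("naa10", "s1", "+", (100, 400)),
            ("cacna1f", "s1", "+", (1100, 1400)),
        ])
        a = classify_locus(rec, "foxp3", "naa10", "cacna1f")
        assert a.status == "SPANNED_UNANNOTATED"
        assert a.gap_total == 0 and a.region_gc is not None

    def test_crow_like_gap_in_region(self):
        rec = scenarios.crow_like(0)
        a = classify_locus(rec, "foxp3", "naa10", "cacna1f",
                           fallback_flanks=("hsd17b10",))
        assert a.status == "GAP_IN_REGION"
        assert a.upstream.used_fallback and a.upstream.gene_id == "hsd17b10"
        span = a.intergenic_interval[1] - a.intergenic_interval[0]
        assert span == 36_546
        assert a.gap_largest == 23_713

    def test_flanks_split(self):
        rec = _toy_record([
            ("naa10", "s1", "+", (100, 400)),
            ("cacna1f", "s2", "+", (100, 400)),
        ])
        assert classify_locus(rec, "foxp3", "naa10", "cacna1f").status == "FLANKS_SPLIT"

    def test_flank_missing(self):
        rec = _toy_record([("naa10", "s1", "+", (100, 400))])
        assert classify_locus(rec, "foxp3", "naa10", "cacna1f").status == "FLANK_MISSING"

    def test_target_colliding_with_flank_raises(self):
        rec = _toy_record([("naa10", "s1", "+", (100, 400))])
        with pytest.raises(ValueError, match="collides"):
            classify_locus(rec, "naa10", "naa10", "cacna1f")

    def test_split_fixture_from_midpoint(self, default_sim):
        """Splitting the simulated scaffold at the intergenic midpoint
        separates the flanks."""
        record, truth = default_sim
        mid = sum(truth.region) // 2
        seq = record.scaffolds[0].sequence
        pieces = [Scaffold("p1", seq[:mid]), Scaffold("p2", seq[mid:])]
        annotations = []
        for ann in record.annotations:
            s, e = ann.span
            if e <= mid:
                annotations.append(
                    GeneAnnotation(ann.gene_id, "p1", ann.strand, ann.exons)
                )
            elif s >= mid:
                exons = tuple((es - mid, ee - mid) for es, ee in ann.exons)
                annotations.append(
                    GeneAnnotation(ann.gene_id, "p2", ann.strand, exons)
                )
        rec = AssemblyRecord(genome_id="split", scaffolds=pieces,
                             annotations=annotations)
        assert classify_locus(rec, "foxp3", "naa10", "cacna1f").status == "FLANKS_SPLIT"

    def test_unfragmented_simulations_always_annotated(self):
        for seed in range(25):
            record, _ = simulate_neighborhood(NeighborhoodSpec(seed=seed))
            a = classify_locus(record, "foxp3", "naa10", "cacna1f")
            assert a.status == "ANNOTATED"

    def test_status_invariant_under_reverse_complement(self):
        for seed in range(6):
            record, truth = simulate_neighborhood(NeighborhoodSpec(seed=seed))
            frag = fragment_assembly(
                record, truth,
                FragmentationModel(base_break_rate=0.15, gc_break_multiplier=20,
                                   seed=seed),
            )
            fwd = classify_locus(frag, "foxp3", "naa10", "cacna1f")
            rev = classify_locus(
                reverse_complement_record(frag), "foxp3", "naa10", "cacna1f"
            )
            assert fwd.status == rev.status
            assert fwd.gap_largest == rev.gap_largest

    def test_statuses_exhaustive_on_fuzzed_assemblies(self):
        seen = set()
        for seed in range(40):
            record, truth = simulate_neighborhood(NeighborhoodSpec(seed=seed))
            frag = fragment_assembly(
                record, truth,
                FragmentationModel(
                    base_break_rate=0.05 + 0.1 * (seed % 5),
                    gc_break_multiplier=1 + 10 * (seed % 7),
                    gap_probability=(seed % 3) / 2.0,
                    seed=seed * 13 + 1,
                ),
            )
            a = classify_locus(frag, "foxp3", "naa10", "cacna1f")
            assert a.status in STATUSES
            seen.add(a.status)
        assert len(seen) >= 3  # the fuzz exercises several failure modes

    def test_nearest_pair_used_for_duplicated_flank(self):
        rec = _toy_record([
            ("naa10", "s1", "+", (100, 200)),
            ("naa10", "s1", "+", (2500, 2600)),
            ("cacna1f", "s1", "+", (3000, 3100)),
        ])
        a = classify_locus(rec, "foxp3", "naa10", "cacna1f")
        assert a.intergenic_interval == (2600, 3000)


class TestContingency:
    def test_all_present_diagonal(self):
        records = [
            _toy_record(
                [("foxp3", "s1", "+", (100, 200)),
                 ("cacna1f", "s1", "+", (300, 400)),
                 ("ccdc22", "s1", "-", (500, 600))],
                genome_id=f"g{i}",
            )
            for i in range(3)
        ]
        s = co_annotation_contingency(records, "foxp3", "cacna1f", "ccdc22")
        assert s.gene_counts == {"foxp3": 3, "cacna1f": 3, "ccdc22": 3}
        assert all(v == 0 for v in s.discordance.values())

    def test_removal_creates_discordance(self):
        records = [
            _toy_record([("foxp3", "s1", "+", (0, 10)),
                         ("cacna1f", "s1", "+", (20, 30))], genome_id="a"),
            _toy_record([("cacna1f", "s1", "+", (20, 30))], genome_id="b"),
        ]
        s = co_annotation_contingency(records, "foxp3", "cacna1f", "ccdc22")
        assert s.discordance["cacna1f_without_foxp3"] == 1
        assert s.discordance["foxp3_without_ccdc22"] == 1

    def test_synthetic_mammal_panel_reproduces_survey_row(self):
        panel = scenarios.mammal_panel_synthetic()
        s = co_annotation_contingency(panel, "foxp3", "cacna1f", "ccdc22")
        assert s.n_genomes == 105
        assert s.gene_counts == {"foxp3": 88, "cacna1f": 87, "ccdc22": 86}
        assert s.discordance == {
            "foxp3_without_cacna1f": 1,
            "foxp3_without_ccdc22": 2,
            "cacna1f_without_foxp3": 0,
            "ccdc22_without_foxp3": 0,
        }

    def test_empty_record_list_raises(self):
        with pytest.raises(ValueError):
            co_annotation_contingency([], "foxp3", "cacna1f", "ccdc22")


class TestQualityStratify:
    def test_multi_gene_group(self):
        rec = _toy_record([("naa10", "s1", "+", (0, 10)),
                           ("cacna1f", "s1", "+", (20, 30))])
        rec.metadata = AssemblyMetadata("toy", 50.0, 1, 4000)
        s = quality_stratify([rec], scenarios.NEIGHBORHOOD_GENES)
        assert s.group_sizes["multi_gene"] == 1

    def test_mean_coverage(self):
        records = []
        for k, cov in enumerate((40.0, 50.0, 60.0)):
            rec = _toy_record([("cacna1f", "s1", "+", (0, 10))],
                              genome_id=f"g{k}")
            rec.metadata = AssemblyMetadata(f"g{k}", cov, 1, 1000)
            records.append(rec)
        s = quality_stratify(records, scenarios.NEIGHBORHOOD_GENES)
        assert s.group_means["single_gene_only"]["coverage_x"] == 50.0

    def test_missing_metadata_excluded_with_warning(self):
        rec = _toy_record([("cacna1f", "s1", "+", (0, 10))])
        with pytest.warns(UserWarning, match="lacks metadata"):
            s = quality_stratify([rec], scenarios.NEIGHBORHOOD_GENES)
        assert s.excluded == ["toy"] and s.n_genomes == 0

    def test_synthetic_avian_panel_reproduces_survey(self):
        panel = scenarios.avian_quality_panel_synthetic()
        s = quality_stratify(panel, scenarios.NEIGHBORHOOD_GENES)
        assert s.group_sizes == {
            "zero_annotated": 31, "single_gene_only": 15, "multi_gene": 14
        }
        means = s.group_means
        assert [means[g]["coverage_x_rounded"] for g in
                ("zero_annotated", "single_gene_only", "multi_gene")] == [46, 59, 92]
        assert [round(means[g]["n50"]) for g in
                ("zero_annotated", "single_gene_only", "multi_gene")] == [
            931_132, 4_481_081, 7_011_777
        ]
        assert [round(means[g]["n_scaffolds"]) for g in
                ("zero_annotated", "single_gene_only", "multi_gene")] == [
            67_526, 47_461, 47_280
        ]
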