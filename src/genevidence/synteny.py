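"""Synteny-based locus classification and assembly-quality surveys.

A target locus is assessed from its annotated neighborhood: if the two
flanking genes sit on one scaffold in a consistent orientation, the
intergenic interval can be interrogated (annotated target? gap runs? GC?
repeats?); if they sit on different scaffolds, or a flank is missing, the
locus cannot be assessed and that fact is itself evidence about assembly
quality.  Survey compilers aggregate co-annotation contingencies and
quality stratifications over many genomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .seqio import AssemblyRecord, GeneAnnotation, gap_runs, gc_fraction, masked_fraction

__all__ = [
    "STATUSES",
    "FlankEvidence",
    "LocusAssessment",
    "SurveySummary",
    "classify_locus",
    "co_annotation_contingency",
    "quality_stratify",
    "REFERENCE_STRANDS",
]

STATUSES = (
    "ANNOTATED",
    "SPANNED_UNANNOTATED",
    "GAP_IN_REGION",
    "FLANKS_SPLIT",
    "FLANK_MISSING",
)

#: reference strands of the target's neighborhood, target-relative; genes on
#: the opposing strand tolerate inversions (they have been observed inverted
#: without disturbing the neighborhood)
REFERENCE_STRANDS = {
    "naa10": "+",
    "hsd17b10": "+",
    "tspyl2": "+",
    "ppp1r3f": "-",
    "foxp3": "+",
    "ccdc22": "-",
    "cacna1f": "+",
}


@dataclass(frozen=True)
class FlankEvidence:
    gene_id: str | None
    present: bool
    scaffold_ids: tuple[str, ...] = ()
    single_gene_scaffold: bool = False
    used_fallback: bool = False


@dataclass(frozen=True)
class LocusAssessment:
    genome_id: str
    status: str
    intergenic_interval: tuple[int, int] | None = None
    scaffold_id: str | None = None
    gap_total: int = 0
    gap_largest: int = 0
    region_gc: float | None = None
    region_masked: float | None = None
    upstream: FlankEvidence | None = None
    downstream: FlankEvidence | None = None


@dataclass
class SurveySummary:
    """Aggregate survey over genomes (contingency and/or quality parts)."""

    n_genomes: int = 0
    gene_counts: dict = field(default_factory=dict)
    discordance: dict = field(default_factory=dict)
    group_sizes: dict = field(default_factory=dict)
    group_means: dict = field(default_factory=dict)
    excluded: list = field(default_factory=list)


def _annotations_by_gene(record: AssemblyRecord) -> dict:
    out: dict[str, list[GeneAnnotation]] = {}
    for ann in record.annotations:
        out.setdefault(ann.gene_id, []).append(ann)
    return out


def _single_gene_scaffolds(record: AssemblyRecord) -> set:
    genes_per_scaffold: dict[str, set] = {}
    for ann in record.annotations:
        genes_per_scaffold.setdefault(ann.scaffold_id, set()).add(ann.gene_id)
    return {sc for sc, genes in genes_per_scaffold.items() if len(genes) == 1}


def _resolve_flank(by_gene, primary, fallbacks, single_gene_scaffolds):
    for gene_id in (primary, *fallbacks):
        if gene_id in by_gene:
            scaffolds = tuple(sorted({a.scaffold_id for a in by_gene[gene_id]}))
            return FlankEvidence(
                gene_id=gene_id,
                present=True,
                scaffold_ids=scaffolds,
                single_gene_scaffold=all(
                    s in single_gene_scaffolds for s in scaffolds
                ),
                used_fallback=gene_id != primary,
            )
    return FlankEvidence(gene_id=None, present=False)


def classify_locus(
    record: AssemblyRecord,
    target_gene: str,
    upstream_flank: str,
    downstream_flank: str,
    fallback_flanks=(),
    gap_threshold: float = 0.20,
    reference_strands: dict | None = None,
) -> LocusAssessment:
    """Classify the target locus from the neighborhood annotation state.

    Cascade: ANNOTATED when the target is annotated between the flanks;
    SPANNED_UNANNOTATED when both flanks share a scaffold and the largest
    intergenic gap run stays below ``gap_threshold`` of the span;
    GAP_IN_REGION when spanned but gapped above the threshold; FLANKS_SPLIT
    when the flanks live on different scaffolds (or in a broken relative
    orientation); FLANK_MISSING otherwise.
    """
    if target_gene in (upstream_flank, downstream_flank) or target_gene in fallback_flanks:
        raise ValueError(f"target {target_gene!r} collides with a flank gene id")
    reference_strands = reference_strands or REFERENCE_STRANDS
    by_gene = _annotations_by_gene(record)
    singles = _single_gene_scaffolds(record)
    up = _resolve_flank(by_gene, upstream_flank, fallback_flanks, singles)
    down = _resolve_flank(by_gene, downstream_flank, fallback_flanks, singles)

    def assessment(status, **kw):
        return LocusAssessment(
            genome_id=record.genome_id, status=status, upstream=up, downstream=down, **kw
        )

    if not (up.present and down.present):
        return assessment("FLANK_MISSING")

    shared = set(up.scaffold_ids) & set(down.scaffold_ids)
    if not shared:
        return assessment("FLANKS_SPLIT")

    # nearest pair of flank copies on a shared scaffold
    best = None
    for scaffold_id in sorted(shared):
        for a in by_gene[up.gene_id]:
            if a.scaffold_id != scaffold_id:
                continue
            for b in by_gene[down.gene_id]:
                if b.scaffold_id != scaffold_id:
                    continue
                left, right = sorted((a, b), key=lambda x: x.span)
                gap = right.span[0] - left.span[1]
                if best is None or gap < best[0]:
                    best = (gap, scaffold_id, a, b, left, right)
    gap_len, scaffold_id, a, b, left, right = best

    # orientation consistency: flanks must show the reference relative
    # orientation unless one is an opposing-strand gene (inversion tolerated)
    exp_a = reference_strands.get(a.gene_id, "+")
    exp_b = reference_strands.get(b.gene_id, "+")
    tolerated = exp_a == "-" or exp_b == "-"
    if not tolerated and ((a.strand == b.strand) != (exp_a == exp_b)):
        return assessment("FLANKS_SPLIT")

    if gap_len <= 0:
        interval = (left.span[1], left.span[1])
    else:
        interval = (left.span[1], right.span[0])

    sc = record.scaffold_index().get(scaffold_id) if record.scaffolds else None
    gap_total = gap_largest = 0
    region_gc = region_masked = None
    span = interval[1] - interval[0]
    if sc is not None and span > 0:
        sub = sc.sequence[interval[0] : interval[1]]
        runs = gap_runs(sub)
        gap_total = sum(e - s for s, e in runs)
        gap_largest = max((e - s for s, e in runs), default=0)
        region_gc = gc_fraction(sub)
        region_masked = masked_fraction(sub)

    kwargs = dict(
        intergenic_interval=interval,
        scaffold_id=scaffold_id,
        gap_total=gap_total,
        gap_largest=gap_largest,
        region_gc=region_gc,
        region_masked=region_masked,
    )

    target_between = any(
        ann.scaffold_id == scaffold_id
        and ann.span[0] >= left.span[0]
        and ann.span[1] <= right.span[1]
        for ann in by_gene.get(target_gene, [])
    )
    if target_between:
        return assessment("ANNOTATED", **kwargs)
    if span > 0 and gap_largest >= gap_threshold * span:
        return assessment("GAP_IN_REGION", **kwargs)
    return assessment("SPANNED_UNANNOTATED", **kwargs)


def co_annotation_contingency(records, target: str, flank_a: str, flank_b: str) -> SurveySummary:
    """Co-annotation counts of the target with two flanks (contingency part)."""
    records = list(records)
    if not records:
        raise ValueError("need at least one record")
    counts = {target: 0, flank_a: 0, flank_b: 0}
    disc = {
        f"{target}_without_{flank_a}": 0,
        f"{target}_without_{flank_b}": 0,
        f"{flank_a}_without_{target}": 0,
        f"{flank_b}_without_{target}": 0,
    }
    for record in records:
        present = {ann.gene_id for ann in record.annotations}
        for gene in counts:
            if gene in present:
                counts[gene] += 1
        if target in present and flank_a not in present:
            disc[f"{target}_without_{flank_a}"] += 1
        if target in present and flank_b not in present:
            disc[f"{target}_without_{flank_b}"] += 1
        if flank_a in present and target not in present:
            disc[f"{flank_a}_without_{target}"] += 1
        if flank_b in present and target not in present:
            disc[f"{flank_b}_without_{target}"] += 1
    return SurveySummary(
        n_genomes=len(records), gene_counts=counts, discordance=disc
    )


QUALITY_GROUPS = ("zero_annotated", "single_gene_only", "multi_gene")


def quality_stratify(records, neighborhood_genes) -> SurveySummary:
    """Stratify genomes by how the neighborhood assembled (quality part).

    Groups: no scaffold annotates a neighborhood gene; scaffolds carry at
    most one neighborhood gene each; at least one scaffold carries two or
    more.  Arithmetic means of coverage, N50 and scaffold count are
    reported per group (mean coverage rounded to whole fold for display).
    """
    neighborhood = set(neighborhood_genes)
    group_members: dict[str, list] = {g: [] for g in QUALITY_GROUPS}
    excluded = []
    for record in records:
        meta = record.metadata
        if meta is None or meta.coverage_x is None or meta.n_scaffolds is None:
            warnings.warn(
                f"genome {record.genome_id} lacks metadata; excluded from stratification",
                stacklevel=2,
            )
            excluded.append(record.genome_id)
            continue
        per_scaffold: dict[str, set] = {}
        for ann in record.annotations:
            if ann.gene_id in neighborhood:
                per_scaffold.setdefault(ann.scaffold_id, set()).add(ann.gene_id)
        if not per_scaffold:
            group = "zero_annotated"
        elif max(len(genes) for genes in per_scaffold.values()) >= 2:
            group = "multi_gene"
        else:
            group = "single_gene_only"
        group_members[group].append(meta)

    group_sizes = {g: len(m) for g, m in group_members.items()}
    group_means = {}
    for g, members in group_members.items():
        if not members:
            group_means[g] = {}
            continue
        cov = [m.coverage_x for m in members]
        n50s = [m.declared_n50 for m in members if m.declared_n50 is not None]
        nsc = [m.n_scaffolds for m in members]
        group_means[g] = {
            "coverage_x": sum(cov) / len(cov),
            "coverage_x_rounded": round(sum(cov) / len(cov)),
            "n50": sum(n50s) / len(n50s) if n50s else None,
            "n_scaffolds": sum(nsc) / len(nsc),
        }
    return SurveySummary(
        n_genomes=sum(group_sizes.values()),
        group_sizes=group_sizes,
        group_means=group_means,
        excluded=excluded,
    )
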