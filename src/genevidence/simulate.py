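"""Synthetic archosaur-like *foxp3* gene neighborhoods with known ground truth.

The generator emulates the genomic configuration in which the avian *foxp3*
question arises: an ordered neighborhood (``naa10 -> foxp3 -> cacna1f`` on
one strand, ``ppp1r3f`` and ``ccdc22`` on the opposing strand), a
GC-elevated intergenic region between the outer flanks, repeat tracts, a
planted multi-exon target gene whose protein carries the FoxP domain
layout, and short reads from its CDS.  A stylized fragmentation model then
breaks assemblies preferentially in GC-rich windows, producing the
"missed" configurations (gap runs, split scaffolds, lost annotations) seen
in real avian assemblies.

All introns are canonical (GT...AG, >= 30 bp) and fall on codon boundaries
(phase 0).  Every operation is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data.CodonTable import standard_dna_table as _std

from . import domains
from .seqio import (
    AssemblyMetadata,
    AssemblyRecord,
    GeneAnnotation,
    Scaffold,
    gc_fraction,
    revcomp,
    translate,
)

__all__ = [
    "NeighborhoodSpec",
    "GroundTruth",
    "FragmentationModel",
    "simulate_neighborhood",
    "fragment_assembly",
    "simulate_reads",
    "back_translate",
    "plant_foxp_protein",
    "PREFERRED_CODONS",
]

DEFAULT_GENE_ORDER = (
    ("naa10", "+"),
    ("ppp1r3f", "-"),
    ("foxp3", "+"),
    ("ccdc22", "-"),
    ("cacna1f", "+"),
)

#: most-used vertebrate codon per amino acid (used for deterministic
#: back-translation; GC-biased synonymous choice is applied on top)
PREFERRED_CODONS = {
    "A": "GCC", "R": "CGG", "N": "AAC", "D": "GAC", "C": "TGC",
    "Q": "CAG", "E": "GAG", "G": "GGC", "H": "CAC", "I": "ATC",
    "L": "CTG", "K": "AAG", "M": "ATG", "F": "TTC", "P": "CCC",
    "S": "AGC", "T": "ACC", "W": "TGG", "Y": "TAC", "V": "GTG",
}

_BASES = np.array(list("ACGT"))


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    if length <= 0:
        return ""
    gc = min(max(gc, 0.02), 0.98)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def back_translate(protein: str, codons: dict | None = None) -> str:
    """Deterministic back-translation using one codon per amino acid."""
    table = codons or PREFERRED_CODONS
    try:
        return "".join(table[aa] for aa in protein)
    except KeyError as exc:
        raise ValueError(f"no codon for residue {exc.args[0]!r}") from exc


# ---------------------------------------------------------------------------
# planted FoxP-like proteins

def plant_foxp_protein(
    length: int = 298,
    seed: int = 0,
    zf_present: bool = True,
    pror_length: int | None = None,
    pror_prolines: int | None = None,
    lz_first_residue: str = "V",
    template_mutation_rate: float = 0.03,
    linker2_length: int | None = None,
    tail_length: int | None = None,
) -> tuple[str, dict]:
    """Build a FoxP3-like protein with known domain intervals.

    Layout (N to C): ProR, optional ZF, linker, LZ, linker, FRK, tail.
    Returns the sequence and a dict of planted truth intervals.
    """
    rng = np.random.default_rng(seed)
    zf_len = len(domains.ZF_CONSENSUS) if zf_present else 0
    lz_len = len(domains.LZ_EXEMPLAR)
    frk_len = len(domains.FRK_CONSENSUS)
    linker1 = 8 if zf_present else 0
    linker2 = 25 if linker2_length is None else linker2_length
    tail = 10 if tail_length is None else tail_length
    pror_len = pror_length if pror_length is not None else (
        length - zf_len - lz_len - frk_len - linker1 - linker2 - tail
    )
    total = pror_len + zf_len + linker1 + lz_len + linker2 + frk_len + tail
    if pror_len < 10 or total != length:
        raise ValueError(
            f"length {length} cannot host the requested domain layout "
            f"(computed ProR length {pror_len})"
        )
    non_p = [a for a in domains.AA20 if a not in "PVLIC"]
    n_p = pror_prolines if pror_prolines is not None else round(0.25 * pror_len)
    pror = list(rng.choice(non_p, size=pror_len))
    p_pos = rng.choice(pror_len, size=n_p, replace=False)
    for pos in p_pos:
        pror[pos] = "P"
    pror = "".join(pror)

    def mutated(template: str, keep: set) -> str:
        out = list(template)
        for i in range(len(out)):
            if i in keep:
                continue
            if rng.random() < template_mutation_rate:
                out[i] = rng.choice(list(domains.AA20.replace(out[i], "")))
        return "".join(out)

    zf = mutated(domains.ZF_CONSENSUS, set()) if zf_present else ""
    lz = list(domains.LZ_EXEMPLAR)
    lz[0] = lz_first_residue
    lz = mutated("".join(lz), set(domains.LZ_PATTERN.anchor_offsets))
    frk = mutated(domains.FRK_CONSENSUS, set())
    link1 = "".join(rng.choice(non_p, size=linker1))
    link2 = "".join(rng.choice(non_p, size=linker2))
    tail_seq = "".join(rng.choice(non_p, size=tail))
    seq = pror + zf + link1 + lz + link2 + frk + tail_seq
    cursor = pror_len
    truth = {"pror": (0, pror_len)}
    if zf_present:
        truth["zf"] = (cursor, cursor + zf_len)
        cursor += zf_len + linker1
    truth["lz"] = (cursor, cursor + lz_len)
    cursor += lz_len + linker2
    truth["frk"] = (cursor, cursor + frk_len)
    return seq, truth


# ---------------------------------------------------------------------------
# neighborhood simulation

@dataclass(frozen=True)
class NeighborhoodSpec:
    gene_order: tuple = DEFAULT_GENE_ORDER
    target_gene: str = "foxp3"
    target_exon_count: int = 11
    target_protein_length: int = 298
    intergenic_length: int = 1500
    target_region_gc: float = 0.66
    background_gc: float = 0.42
    repeat_density: float = 0.25
    seed: int = 0
    # protein layout knobs (forwarded to plant_foxp_protein)
    zf_present: bool = True
    pror_length: int | None = None
    pror_prolines: int | None = None
    lz_first_residue: str = "V"
    target_protein: str | None = None
    margin_length: int = 800
    flank_exon_length: int = 240
    flank_intron_length: int = 180
    min_intron: int = 60
    max_intron: int = 240

    def __post_init__(self) -> None:
        gene_ids = [g for g, _ in self.gene_order]
        if self.target_gene not in gene_ids:
            raise ValueError(f"target {self.target_gene!r} not in gene order")
        if len(set(gene_ids)) != len(gene_ids):
            raise ValueError("duplicate gene ids in gene order")
        for frac in (self.target_region_gc, self.background_gc, self.repeat_density):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.target_exon_count < 1:
            raise ValueError("target gene needs at least one exon")
        if self.target_protein_length < 5 * self.target_exon_count:
            raise ValueError("protein too short for the requested exon count")
        if self.intergenic_length < 200:
            raise ValueError(
                "intergenic length too short to host the requested gene structure"
            )


@dataclass
class GroundTruth:
    """Truth manifest for a simulated neighborhood."""

    target_protein: str
    target_cds: str
    target_exons: tuple  # (start, end, phase) on the scaffold, 0-based half-open
    target_strand: str
    gene_spans: dict  # gene_id -> (start, end, strand)
    region: tuple  # interval between upstream-flank 3' end and downstream 5' start
    domain_truth: dict  # planted protein-domain intervals
    seed: int


def _target_gene_block(spec: NeighborhoodSpec, rng: np.random.Generator):
    """CDS split into phase-0 exons joined by GT..AG introns.

    Returns (gene_sequence, local exon intervals, protein, cds, domain truth).
    """
    if spec.target_protein is not None:
        protein = spec.target_protein
        domain_truth = {}
    else:
        try:
            protein, domain_truth = plant_foxp_protein(
                length=spec.target_protein_length,
                seed=int(rng.integers(2**31 - 1)),
                zf_present=spec.zf_present,
                pror_length=spec.pror_length,
                pror_prolines=spec.pror_prolines,
                lz_first_residue=spec.lz_first_residue,
            )
        except ValueError:
            # too short for the FoxP layout: plain random protein
            protein = "M" + "".join(
                rng.choice(list(domains.AA20),
                           size=spec.target_protein_length - 1)
            )
            domain_truth = {}
    gc_rich = spec.target_region_gc >= 0.55

    def choose_codon(aa: str) -> str:
        if gc_rich:
            return PREFERRED_CODONS[aa]
        syn = [c for c, a in _SYNONYMS.items() if a == aa]
        return syn[rng.integers(len(syn))]

    cds = "".join(choose_codon(aa) for aa in protein)
    n_exons = spec.target_exon_count
    n_codons = len(protein)
    # split codons into n_exons parts, each at least 5 codons
    cuts = np.array([], int)
    if n_exons > 1:
        for _ in range(100):
            cuts = np.sort(rng.choice(np.arange(5, n_codons - 4),
                                      size=n_exons - 1, replace=False))
            if len(cuts) < 2 or np.min(np.diff(cuts)) >= 5:
                break
        else:  # tight layouts: fall back to even spacing
            cuts = np.linspace(0, n_codons, n_exons + 1)[1:-1].astype(int)
    bounds = [0, *[int(c) for c in cuts], n_codons]
    parts = [cds[3 * a : 3 * b] for a, b in zip(bounds, bounds[1:])]
    pieces = []
    exons_local = []
    cursor = 0
    for k, part in enumerate(parts):
        exons_local.append((cursor, cursor + len(part), 0))
        pieces.append(part)
        cursor += len(part)
        if k < len(parts) - 1:
            ilen = int(rng.integers(spec.min_intron, spec.max_intron + 1))
            intron = "GT" + _random_dna(rng, ilen - 4, spec.target_region_gc) + "AG"
            pieces.append(intron)
            cursor += ilen
    return "".join(pieces), exons_local, protein, cds, domain_truth


_SYNONYMS = {c.upper(): a for c, a in _std.forward_table.items()}


def simulate_neighborhood(spec: NeighborhoodSpec) -> tuple[AssemblyRecord, GroundTruth]:
    """Emit one contiguous scaffold holding the full gene neighborhood."""
    rng = np.random.default_rng(spec.seed)
    target_block, target_exons_local, protein, cds, domain_truth = _target_gene_block(
        spec, rng
    )
    flank_gene_len = 2 * spec.flank_exon_length + spec.flank_intron_length

    # assemble blocks left to right; record gene offsets
    blocks: list[str] = []
    gene_offsets: dict[str, int] = {}
    gene_lengths: dict[str, int] = {}
    gene_strands: dict[str, str] = dict(spec.gene_order)
    region_gene_ids = [g for g, _ in spec.gene_order][1:-1]

    def flank_block(length: int, gc: float) -> str:
        return _random_dna(rng, length, gc)

    cursor = 0

    def push(seq: str) -> int:
        nonlocal cursor
        blocks.append(seq)
        start = cursor
        cursor += len(seq)
        return start

    push(_random_dna(rng, spec.margin_length, spec.background_gc))
    # GC budget: the target CDS is fixed; solve the base probability for the
    # remaining random sequence inside the region so the region hits target GC
    region_random_len = (
        (len(spec.gene_order) - 1) * spec.intergenic_length
        + (len(region_gene_ids) - 1) * flank_gene_len
        + (len(target_block) - len(cds))
    )
    region_total = (
        (len(spec.gene_order) - 1) * spec.intergenic_length
        + (len(region_gene_ids) - 1) * flank_gene_len
        + len(target_block)
    )
    cds_gc = sum(cds.count(c) for c in "GC")
    inner_gc = (spec.target_region_gc * region_total - cds_gc) / max(region_random_len, 1)
    inner_gc = min(max(inner_gc, 0.05), 0.95)

    for idx, (gene_id, strand) in enumerate(spec.gene_order):
        inside_region = gene_id in region_gene_ids
        if gene_id == spec.target_gene:
            block = target_block if strand == "+" else revcomp(target_block)
            start = push(block)
        else:
            gc = inner_gc if inside_region else spec.background_gc
            block = flank_block(flank_gene_len, gc)
            start = push(block)
        gene_offsets[gene_id] = start
        gene_lengths[gene_id] = len(block)
        if idx < len(spec.gene_order) - 1:
            push(_random_dna(rng, spec.intergenic_length, inner_gc))

    push(_random_dna(rng, spec.margin_length, spec.background_gc))
    sequence = "".join(blocks)

    first_gene, last_gene = spec.gene_order[0][0], spec.gene_order[-1][0]
    region = (
        gene_offsets[first_gene] + gene_lengths[first_gene],
        gene_offsets[last_gene],
    )

    # soft-mask repeat tracts inside the intergenic spacers of the region
    if spec.repeat_density > 0:
        seq = list(sequence)
        mask_budget = spec.repeat_density * (region[1] - region[0])
        spacer_spans = []
        order_ids = [g for g, _ in spec.gene_order]
        for a, b in zip(order_ids, order_ids[1:]):
            s = gene_offsets[a] + gene_lengths[a]
            e = gene_offsets[b]
            spacer_spans.append((s, e))
        total_spacer = sum(e - s for s, e in spacer_spans)
        for s, e in spacer_spans:
            share = int(mask_budget * (e - s) / total_spacer)
            share = min(share, e - s - 50)
            if share <= 0:
                continue
            start = s + int(rng.integers(0, e - s - share))
            for i in range(start, start + share):
                seq[i] = seq[i].lower()
        sequence = "".join(seq)

    scaffold = Scaffold(id=f"sim_{spec.seed}_s1", sequence=sequence)

    annotations = []
    truth_exons = []
    for gene_id, strand in spec.gene_order:
        off = gene_offsets[gene_id]
        glen = gene_lengths[gene_id]
        if gene_id == spec.target_gene:
            if strand == "+":
                exons = tuple(
                    (off + s, off + e) for s, e, _ in target_exons_local
                )
                truth_exons = [(off + s, off + e, ph) for s, e, ph in target_exons_local]
            else:
                exons = tuple(
                    sorted((off + glen - e, off + glen - s) for s, e, _ in target_exons_local)
                )
                truth_exons = [
                    (s, e, 0) for s, e in exons
                ]
        else:
            e1 = (off, off + spec.flank_exon_length)
            e2 = (off + glen - spec.flank_exon_length, off + glen)
            exons = (e1, e2)
        annotations.append(
            GeneAnnotation(
                gene_id=gene_id, scaffold_id=scaffold.id, strand=strand, exons=exons
            )
        )

    record = AssemblyRecord(
        genome_id=f"sim_{spec.seed}",
        scaffolds=[scaffold],
        annotations=annotations,
        metadata=AssemblyMetadata(
            genome_id=f"sim_{spec.seed}", coverage_x=100.0, n_scaffolds=1
        ),
    )
    truth = GroundTruth(
        target_protein=protein,
        target_cds=cds,
        target_exons=tuple(truth_exons),
        target_strand=gene_strands[spec.target_gene],
        gene_spans={
            g: (gene_offsets[g], gene_offsets[g] + gene_lengths[g], s)
            for g, s in spec.gene_order
        },
        region=region,
        domain_truth=domain_truth,
        seed=spec.seed,
    )
    # self-check: spliced truth must translate back to the protein
    if gene_strands[spec.target_gene] == "+":
        spliced = "".join(sequence[s:e] for s, e, _ in truth.target_exons)
    else:
        spliced = revcomp("".join(sequence[s:e] for s, e, _ in truth.target_exons))
    assert translate(spliced.upper()) == protein
    return record, truth


# ---------------------------------------------------------------------------
# fragmentation

@dataclass(frozen=True)
class FragmentationModel:
    """Stylized GC-linked assembly failure.

    Breakpoints arrive at ``base_break_rate`` per kb, multiplied by
    ``gc_break_multiplier`` inside windows whose GC exceeds
    ``gc_threshold``.  A breakpoint becomes an internal N-gap run with
    probability ``gap_probability``, otherwise a scaffold split.  Genes that
    lose any exon to a gap or a split are dropped (or truncated when
    ``drop_damaged_genes`` is False), emulating annotation loss.
    """

    base_break_rate: float = 0.02
    gc_break_multiplier: float = 1.0
    gap_length_distribution: tuple = (200, 3000)
    seed: int = 0
    gc_threshold: float = 0.55
    window: int = 500
    gap_probability: float = 0.5
    drop_damaged_genes: bool = True

    def __post_init__(self) -> None:
        if self.base_break_rate < 0 or self.gc_break_multiplier < 1:
            raise ValueError("rates must be >= 0 and multiplier >= 1")
        lo, hi = self.gap_length_distribution
        if not (0 < lo <= hi):
            raise ValueError("bad gap length distribution")


def fragment_assembly(
    record: AssemblyRecord, truth: GroundTruth, model: FragmentationModel
) -> AssemblyRecord:
    """Break a simulated assembly; re-map, truncate or drop annotations."""
    rng = np.random.default_rng(model.seed)
    if model.base_break_rate == 0:
        return record
    new_scaffolds: list[Scaffold] = []
    new_annotations: list[GeneAnnotation] = []
    for scaffold in record.scaffolds:
        seq = scaffold.sequence
        n = len(seq)
        breaks: list[tuple[int, bool]] = []  # (position, is_gap)
        for wstart in range(0, n, model.window):
            wseq = seq[wstart : wstart + model.window]
            gc = gc_fraction(wseq) or 0.0
            rate = model.base_break_rate * len(wseq) / 1000.0
            if gc > model.gc_threshold:
                rate *= model.gc_break_multiplier
            k = rng.poisson(min(rate, 50.0))
            for _ in range(k):
                pos = wstart + int(rng.integers(len(wseq)))
                breaks.append((pos, bool(rng.random() < model.gap_probability)))
        breaks.sort()
        gap_spans: list[tuple[int, int]] = []
        split_points: list[int] = []
        chars = list(seq)
        for pos, is_gap in breaks:
            if is_gap:
                lo, hi = model.gap_length_distribution
                glen = int(rng.integers(lo, hi + 1))
                gend = min(pos + glen, n)
                for i in range(pos, gend):
                    chars[i] = "N"
                gap_spans.append((pos, gend))
            else:
                if 0 < pos < n:
                    split_points.append(pos)
        seq = "".join(chars)
        cut_points = sorted(set([0, *split_points, n]))
        pieces = list(zip(cut_points, cut_points[1:]))
        piece_ids = {}
        for k, (ps, pe) in enumerate(pieces):
            pid = scaffold.id if len(pieces) == 1 else f"{scaffold.id}_f{k + 1}"
            piece_ids[(ps, pe)] = pid
            new_scaffolds.append(Scaffold(id=pid, sequence=seq[ps:pe]))

        def exon_intact(s: int, e: int) -> bool:
            return not any(gs < e and s < ge for gs, ge in gap_spans)

        for ann in record.annotations:
            if ann.scaffold_id != scaffold.id:
                continue
            per_piece: dict[tuple[int, int], list[tuple[int, int]]] = {}
            lost = False
            for s, e in ann.exons:
                placed = False
                for ps, pe in pieces:
                    if ps <= s and e <= pe and exon_intact(s, e):
                        per_piece.setdefault((ps, pe), []).append((s - ps, e - ps))
                        placed = True
                        break
                if not placed:
                    lost = True
            if not per_piece:
                continue
            damaged = lost or len(per_piece) > 1
            if damaged and model.drop_damaged_genes:
                continue
            for (ps, pe), exons in per_piece.items():
                new_annotations.append(
                    GeneAnnotation(
                        gene_id=ann.gene_id,
                        scaffold_id=piece_ids[(ps, pe)],
                        strand=ann.strand,
                        exons=tuple(sorted(exons)),
                        biotype=ann.biotype,
                    )
                )
    meta = record.metadata
    if meta is not None:
        meta = AssemblyMetadata(
            genome_id=meta.genome_id,
            coverage_x=meta.coverage_x,
            n_scaffolds=len(new_scaffolds),
            declared_n50=meta.declared_n50,
        )
    return AssemblyRecord(
        genome_id=record.genome_id,
        scaffolds=new_scaffolds,
        annotations=new_annotations,
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# reads

def simulate_reads(
    cds: str,
    read_length: int = 90,
    n_reads: int = 100,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[str]:
    """Uniform reads from both strands of a CDS with per-base substitutions."""
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    if read_length > len(cds):
        raise ValueError("read_length exceeds CDS length")
    rng = np.random.default_rng(seed)
    reads = []
    cds = cds.upper()
    for _ in range(n_reads):
        start = int(rng.integers(0, len(cds) - read_length + 1))
        read = cds[start : start + read_length]
        if rng.random() < 0.5:
            read = revcomp(read)
        if error_rate > 0:
            chars = list(read)
            for i in range(len(chars)):
                if rng.random() < error_rate:
                    chars[i] = rng.choice([b for b in "ACGT" if b != chars[i]])
            read = "".join(chars)
        reads.append(read)
    return reads
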