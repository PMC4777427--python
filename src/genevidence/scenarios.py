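"""Synthetic study-condition stand-ins.

Each builder here emulates one of the genomic configurations at the heart
of the missed-vs-missing question, with every quantitative condition
planted so the pipeline can recompute it: a ground-tit-like genome (clean
GC-rich region, unannotated but intact 11-exon / 298-aa target with
transcript reads), a crow-like genome (a 23,713 bp assembly gap inside the
36,546 bp intergenic region, upstream flank replaced by hsd17b10), two
falcon-like genomes (partial exon sets over the forkhead domain), a
mammal co-annotation panel, an avian assembly-quality panel, squamate-like
low-proline proteins, and a forkhead-domain alignment with planted clade
signature residues.

Everything in this module is synthetic; it is constructed, not downloaded,
and is labelled as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import domains
from .fgenesh import format_prediction
from .seqio import (
    AssemblyMetadata,
    AssemblyRecord,
    GeneAnnotation,
    Scaffold,
)
from .simulate import (
    NeighborhoodSpec,
    _random_dna,
    plant_foxp_protein,
    simulate_neighborhood,
)

__all__ = [
    "GroundTitLike",
    "ground_tit_like",
    "crow_like",
    "falcon_like",
    "mammal_panel_synthetic",
    "avian_quality_panel_synthetic",
    "squamate_like_proteins",
    "signature_panel_synthetic",
    "NEIGHBORHOOD_GENES",
    "CHICKEN_PRIMER",
]

#: the neighborhood genes used for quality stratification (the target
#: itself is not part of the quality measure)
NEIGHBORHOOD_GENES = ("hsd17b10", "naa10", "tspyl2", "ppp1r3f", "ccdc22", "cacna1f")

#: the single chicken PCR primer that matches the target CDS perfectly
CHICKEN_PRIMER = "TTGTGCAGGCTCAGGTTG"


# ---------------------------------------------------------------------------
# ground-tit-like genome

@dataclass
class GroundTitLike:
    """Synthetic ground-tit-like bundle with planted truth."""

    record: AssemblyRecord  # target annotation removed, as in the public set
    annotated_record: AssemblyRecord
    truth: object
    protein: str
    cds: str
    domain_truth: dict
    lz_frk_span: tuple[int, int]  # codon interval: mid-LZ to FRK end minus 4 aa
    uncovered_codons: tuple[int, int]
    reads: list
    fgenesh_text: str


def ground_tit_like(seed: int = 0) -> GroundTitLike:
    """A clean, GC-rich neighborhood whose target gene is intact but
    unannotated: 298 aa over 11 exons, no ZF, isoleucine-first LZ, a
    proline-rich N-terminus at 31/123 prolines, and error-free muscle-like
    reads covering 144 of the 152 codons between mid-LZ and the end of the
    forkhead domain (minus its last four codons)."""
    protein, domain_truth = plant_foxp_protein(
        length=298,
        seed=seed,
        zf_present=False,
        pror_length=123,
        pror_prolines=31,
        lz_first_residue="I",
        template_mutation_rate=0.0,
        linker2_length=50,
        tail_length=8,
    )
    spec = NeighborhoodSpec(
        seed=seed,
        target_protein=protein,
        target_region_gc=0.66,
        repeat_density=0.07,
    )
    record, truth = simulate_neighborhood(spec)
    lz = domain_truth["lz"]
    frk = domain_truth["frk"]
    span = (lz[0] + (lz[1] - lz[0]) // 2, frk[1] - 4)
    assert span[1] - span[0] == 152

    # reads tiling the span except one fixed 8-codon window
    uncovered = (span[0] + 66, span[0] + 74)
    cds = truth.target_cds
    read_len, step = 60, 30
    reads = []
    for lo, hi in ((span[0] * 3, uncovered[0] * 3), (uncovered[1] * 3, span[1] * 3)):
        starts = list(range(lo, hi - read_len + 1, step))
        if not starts or starts[-1] != hi - read_len:
            starts.append(hi - read_len)
        for s in starts:
            reads.append(cds[s : s + read_len])

    unannotated = AssemblyRecord(
        genome_id=record.genome_id,
        scaffolds=record.scaffolds,
        annotations=[a for a in record.annotations if a.gene_id != spec.target_gene],
        metadata=record.metadata,
    )
    fgenesh_text = format_prediction(
        record.scaffolds[0].id,
        [(s, e) for s, e, _ in truth.target_exons],
        protein,
        strand=truth.target_strand,
    )
    return GroundTitLike(
        record=unannotated,
        annotated_record=record,
        truth=truth,
        protein=protein,
        cds=cds,
        domain_truth=domain_truth,
        lz_frk_span=span,
        uncovered_codons=uncovered,
        reads=reads,
        fgenesh_text=fgenesh_text,
    )


# ---------------------------------------------------------------------------
# crow-like genome

def crow_like(seed: int = 0) -> AssemblyRecord:
    """Flanks conserved but 23,713 of the 36,546 intergenic bases are one N
    run; the upstream flank is hsd17b10 because no naa10 was assembled."""
    rng = np.random.default_rng(seed)
    margin = 500
    gene_len = 800
    intergenic = 36_546
    gap_len = 23_713
    spacer_a = 5_000
    spacer_b = intergenic - spacer_a - gap_len

    parts = [
        _random_dna(rng, margin, 0.42),
        _random_dna(rng, gene_len, 0.45),          # hsd17b10
        _random_dna(rng, spacer_a, 0.55),
        "N" * gap_len,
        _random_dna(rng, spacer_b, 0.55),
        _random_dna(rng, gene_len, 0.45),          # cacna1f
        _random_dna(rng, margin, 0.42),
    ]
    # soft-mask repeat tracts in the assembled spacers
    masked_a = parts[2][:2000].lower() + parts[2][2000:]
    parts[2] = masked_a
    seq = "".join(parts)
    up_start = margin
    up_end = up_start + gene_len
    down_start = up_end + intergenic
    down_end = down_start + gene_len
    scaffold = Scaffold(id="crow_s1", sequence=seq)
    annotations = [
        GeneAnnotation("hsd17b10", scaffold.id, "+",
                       ((up_start, up_start + 300), (up_end - 300, up_end))),
        GeneAnnotation("cacna1f", scaffold.id, "+",
                       ((down_start, down_start + 300), (down_end - 300, down_end))),
    ]
    return AssemblyRecord(
        genome_id="crow_like",
        scaffolds=[scaffold],
        annotations=annotations,
        metadata=AssemblyMetadata(genome_id="crow_like", coverage_x=30.0, n_scaffolds=1),
    )


# ---------------------------------------------------------------------------
# falcon-like genomes

def falcon_like(seed: int = 0, keep_last_exons: int = 4):
    """Ground-tit-like gene structure whose region is unassembled (N runs)
    except for a window holding the last exons -- the ones spanning the
    forkhead domain -- as for the peregrine (4) and saker (3) falcons.

    Returns (record, truth, reference_protein, region_interval)."""
    gt = ground_tit_like(seed)
    record, truth = gt.annotated_record, gt.truth
    scaffold = record.scaffolds[0]
    chars = list(scaffold.sequence)
    exons = list(truth.target_exons)
    window = (exons[-keep_last_exons][0] - 40, exons[-1][1] + 40)
    for i in range(*truth.region):
        if not window[0] <= i < window[1]:
            chars[i] = "N"
    seq = "".join(chars)
    new_record = AssemblyRecord(
        genome_id=f"falcon_like_{keep_last_exons}",
        scaffolds=[Scaffold(id=scaffold.id, sequence=seq)],
        annotations=[a for a in record.annotations
                     if a.gene_id in ("naa10", "cacna1f")],
        metadata=record.metadata,
    )
    return new_record, truth, gt.protein, truth.region


# ---------------------------------------------------------------------------
# mammal co-annotation panel

def mammal_panel_synthetic() -> list[AssemblyRecord]:
    """105 annotation-only mammal-like genomes: 86 carry foxp3 with both
    downstream flanks, one lacks ccdc22, one carries foxp3 alone, and 17
    carry none of the three."""
    panel = []

    def make(genome_id, genes):
        annotations = [
            GeneAnnotation(g, "sc1", "+", ((100 * k, 100 * k + 50),))
            for k, g in enumerate(genes)
        ]
        return AssemblyRecord(genome_id=genome_id, annotations=annotations)

    for k in range(86):
        panel.append(make(f"mammal_{k:03d}", ["foxp3", "cacna1f", "ccdc22"]))
    panel.append(make("mammal_086", ["foxp3", "cacna1f"]))
    panel.append(make("mammal_087", ["foxp3"]))
    for k in range(88, 105):
        panel.append(make(f"mammal_{k:03d}", ["tspyl2"]))
    return panel


# ---------------------------------------------------------------------------
# avian quality panel

def _spread(mean: int, n: int, scale: int) -> list[int]:
    """n positive integers with exactly the requested mean."""
    offsets = [((k % 7) - 3) * scale for k in range(n - 1)]
    values = [mean + o for o in offsets]
    values.append(mean * n - sum(values))
    assert all(v > 0 for v in values) and sum(values) == mean * n
    return values


def avian_quality_panel_synthetic() -> list[AssemblyRecord]:
    """60 annotation-only avian-like genomes in three assembly-quality
    strata (31 with no neighborhood annotation, 15 with single-gene
    scaffolds only, 14 with a multi-gene scaffold), whose per-genome
    metadata average to the stratum-level coverage, N50 and scaffold-count
    summaries of the avian survey."""
    groups = [
        # (n, coverage mean, n50 mean, scaffold-count mean, gene placement)
        (31, 46, 931_132, 67_526, []),
        (15, 59, 4_481_081, 47_461, [("cacna1f", "sc1"), ("ccdc22", "sc2")]),
        (14, 92, 7_011_777, 47_280, [("cacna1f", "sc1"), ("ccdc22", "sc1"),
                                     ("naa10", "sc2")]),
    ]
    panel = []
    for gi, (n, cov_mean, n50_mean, nsc_mean, placement) in enumerate(groups):
        covs = _spread(cov_mean, n, 1)
        n50s = _spread(n50_mean, n, 10_000)
        nscs = _spread(nsc_mean, n, 100)
        for k in range(n):
            genome_id = f"avian_g{gi}_{k:02d}"
            annotations = [
                GeneAnnotation(gene, sc, "+", ((0, 50),))
                for gene, sc in placement
            ]
            panel.append(
                AssemblyRecord(
                    genome_id=genome_id,
                    annotations=annotations,
                    metadata=AssemblyMetadata(
                        genome_id=genome_id,
                        coverage_x=float(covs[k]),
                        n_scaffolds=nscs[k],
                        declared_n50=n50s[k],
                    ),
                )
            )
    return panel


# ---------------------------------------------------------------------------
# squamate-like proteins

def squamate_like_proteins(seed: int = 0) -> dict:
    """Squamate-like FoxP3 proteins lacking a discernible proline-rich
    region: anole-like at 13/120 prolines, python-like at 10/115."""
    anole, _ = plant_foxp_protein(
        length=272, seed=seed + 1, zf_present=False,
        pror_length=120, pror_prolines=13, template_mutation_rate=0.0,
    )
    python, _ = plant_foxp_protein(
        length=267, seed=seed + 2, zf_present=False,
        pror_length=115, pror_prolines=10, template_mutation_rate=0.0,
    )
    return {"anole_like": anole, "python_like": python}


# ---------------------------------------------------------------------------
# signature panel

AVIAN_SIGNATURE_COLUMNS = (5, 18, 33, 47, 62, 80)
MAMMAL_SIGNATURE_COLUMNS = (2, 9, 14, 25, 38, 44, 52, 58, 66, 71, 84, 90)
#: of the 12 mammal-signature columns, birds retain the first five
MAMMAL_COLUMNS_KEPT_IN_BIRDS = MAMMAL_SIGNATURE_COLUMNS[:5]
SAKER_MISSING = (30, 60)  # partial saker sequence: columns without data


def signature_panel_synthetic(seed: int = 0) -> dict:
    """A forkhead-domain panel with planted clade signatures.

    Ingroup: ground-tit-, peregrine- and (partial) saker-like sequences
    sharing six avian residues absent everywhere else.  Exclusions: mouse-
    and alligator-like FoxP3 plus mouse-like FoxP1/2/4 paralogues.  Birds
    retain five of the twelve mammal-signature residues.  Returns the raw
    sequences, group ids and the mammal reference signature list."""
    rng = np.random.default_rng(seed)
    base = list(domains.FRK_CONSENSUS)
    n = len(base)

    def mutate_at(seq, columns, forbidden=()):
        out = list(seq)
        for c in columns:
            choices = [a for a in domains.AA20
                       if a != out[c] and a not in forbidden and a not in
                       {row[c] for row in forbidden_rows}]
            out[c] = choices[int(rng.integers(len(choices)))]
        return out

    forbidden_rows: list[list[str]] = []

    # paralogues: diverged at a third of the columns
    paralogues = {}
    for name in ("foxp1", "foxp2", "foxp4"):
        cols = rng.choice(n, size=n // 3, replace=False)
        paralogues[f"mouse_{name}"] = mutate_at(base, [int(c) for c in cols])
        forbidden_rows.append(paralogues[f"mouse_{name}"])

    # alligator-like FoxP3: mildly diverged
    cols = rng.choice(n, size=8, replace=False)
    alligator = mutate_at(base, [int(c) for c in cols])
    forbidden_rows.append(alligator)
    forbidden_rows.append(base)

    # avian rows: start from baseline, lose 7 of the 12 mammal-signature
    # residues in the ground tit only (so the ingroup disagrees there), and
    # share 6 avian residues absent from baseline, alligator and paralogues
    groundtit = list(base)
    for c in MAMMAL_SIGNATURE_COLUMNS[5:]:
        choices = [a for a in domains.AA20 if a != base[c]]
        groundtit[c] = choices[int(rng.integers(len(choices)))]
    peregrine = list(base)
    saker = list(base)
    for c in AVIAN_SIGNATURE_COLUMNS:
        taken = {base[c], alligator[c]} | {p[c] for p in paralogues.values()}
        choices = [a for a in domains.AA20 if a not in taken]
        residue = choices[int(rng.integers(len(choices)))]
        groundtit[c] = peregrine[c] = saker[c] = residue
    for c in range(*SAKER_MISSING):
        saker[c] = "X"

    sequences = {
        "mouse_foxp3": "".join(base),
        "alligator_foxp3": "".join(alligator),
        "groundtit_foxp3": "".join(groundtit),
        "peregrine_foxp3": "".join(peregrine),
        "saker_foxp3": "".join(saker),
        **{k: "".join(v) for k, v in paralogues.items()},
    }
    reference_signature = [(c, base[c]) for c in MAMMAL_SIGNATURE_COLUMNS]
    return {
        "sequences": sequences,
        "baseline_id": "mouse_foxp3",
        "ingroup": ("groundtit_foxp3", "peregrine_foxp3", "saker_foxp3"),
        "exclusion_sets": (
            ("mouse_foxp3", "alligator_foxp3"),
            ("mouse_foxp1", "mouse_foxp2", "mouse_foxp4"),
        ),
        "reference_signature": reference_signature,
    }
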