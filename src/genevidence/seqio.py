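"""Sequence primitives, FASTA/GFF3 I/O and assembly-level statistics.

Coordinates are 0-based, half-open everywhere in memory; the GFF3 1-based
inclusive convention exists only at the I/O boundary.  Soft-masking
(lowercase) is the sole repeat representation: an ``N`` (any case) is an
assembly gap, never a hard-masked repeat.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import gffutils
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Scaffold",
    "GeneAnnotation",
    "AssemblyMetadata",
    "AssemblyRecord",
    "AssemblyStats",
    "read_fasta",
    "write_fasta",
    "read_gff",
    "write_gff",
    "read_metadata_tsv",
    "write_metadata_tsv",
    "revcomp",
    "translate",
    "gc_fraction",
    "masked_fraction",
    "gap_runs",
    "n50",
    "assembly_stats",
    "reverse_complement_record",
]

DNA_CHARS = frozenset("ACGTNacgtn")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_CODON_TABLE = {c.upper(): aa for c, aa in standard_dna_table.forward_table.items()}
_STOP_CODONS = frozenset(standard_dna_table.stop_codons)
FASTA_WRAP = 60


def _check_dna(seq: str) -> None:
    bad = set(seq) - DNA_CHARS
    if bad:
        raise ValueError(f"non-IUPAC DNA characters (only ACGTN allowed): {sorted(bad)!r}")


@dataclass(frozen=True)
class Scaffold:
    """A named assembly sequence; lowercase = repeat-masked, N = gap."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("scaffold id must be non-empty")
        if not self.sequence:
            raise ValueError(f"scaffold {self.id!r} has empty sequence")
        _check_dna(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneAnnotation:
    """Stranded, multi-exon gene annotation on a scaffold (0-based, half-open)."""

    gene_id: str
    scaffold_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    biotype: str = "gene"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.biotype not in ("gene", "pseudogene"):
            raise ValueError(f"unknown biotype {self.biotype!r}")
        exons = tuple(tuple(e) for e in self.exons)
        if not exons:
            raise ValueError(f"gene {self.gene_id!r} has no exons")
        for s, e in exons:
            if not (0 <= s < e):
                raise ValueError(f"gene {self.gene_id!r}: bad exon interval [{s},{e})")
        for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
            if s1 < e0:
                raise ValueError(f"gene {self.gene_id!r}: exons overlap or are unsorted")
        object.__setattr__(self, "exons", exons)

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])


@dataclass(frozen=True)
class AssemblyMetadata:
    genome_id: str
    coverage_x: float | None = None
    n_scaffolds: int | None = None
    declared_n50: int | None = None


@dataclass
class AssemblyRecord:
    """One genome: scaffolds (optional for annotation-only records), annotations, metadata."""

    genome_id: str
    scaffolds: list[Scaffold] = field(default_factory=list)
    annotations: list[GeneAnnotation] = field(default_factory=list)
    metadata: AssemblyMetadata | None = None

    def __post_init__(self) -> None:
        if self.scaffolds:
            by_id = self.scaffold_index()
            if len(by_id) != len(self.scaffolds):
                raise ValueError("duplicate scaffold ids")
            for ann in self.annotations:
                sc = by_id.get(ann.scaffold_id)
                if sc is None:
                    raise ValueError(
                        f"annotation {ann.gene_id!r} references unknown scaffold {ann.scaffold_id!r}"
                    )
                if ann.span[1] > sc.length:
                    raise ValueError(
                        f"annotation {ann.gene_id!r} exceeds scaffold {ann.scaffold_id!r} bounds"
                    )
            if self.metadata and self.metadata.n_scaffolds is not None:
                if self.metadata.n_scaffolds != len(self.scaffolds):
                    raise ValueError("metadata n_scaffolds disagrees with scaffold list")

    def scaffold_index(self) -> dict[str, Scaffold]:
        return {sc.id: sc for sc in self.scaffolds}


@dataclass(frozen=True)
class AssemblyStats:
    n50: int
    total_length: int
    n_scaffolds: int
    gc_fraction: float | None
    masked_fraction: float
    gap_fraction: float


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> list[Scaffold]:
    """Read a (case-preserving) multi-record FASTA into Scaffolds."""
    scaffolds = []
    try:
        with open(path) as handle:
            first = handle.readline()
            if first and not first.startswith(">"):
                raise ValueError(f"{path}: line 1 is not a FASTA header: {first.strip()!r}")
            handle.seek(0)
            for rec in SeqIO.parse(handle, "fasta"):
                if len(rec.seq) == 0:
                    raise ValueError(f"{path}: empty record {rec.id!r}")
                scaffolds.append(Scaffold(id=rec.id, sequence=str(rec.seq)))
    except ValueError as exc:
        raise ValueError(f"FASTA parse error in {path}: {exc}") from exc
    if not scaffolds:
        raise ValueError(f"FASTA parse error in {path}: no records found")
    return scaffolds


def write_fasta(scaffolds, path) -> None:
    records = [
        SeqRecord(Seq(sc.sequence), id=sc.id, description="") for sc in scaffolds
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=FASTA_WRAP)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3

def read_gff(path) -> list[GeneAnnotation]:
    """Read gene/mRNA/exon features from GFF3 into GeneAnnotations.

    Every exon must resolve (directly or through an mRNA) to a gene or
    pseudogene parent; 1-based inclusive coordinates become 0-based half-open.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    gene_types = ("gene", "pseudogene")
    annotations = []
    claimed_exons: set[str] = set()
    for gtype in gene_types:
        for gene in db.features_of_type(gtype, order_by="start"):
            exons = []
            for child in db.children(gene.id, featuretype="exon", order_by="start"):
                exons.append((child.start - 1, child.end))
                claimed_exons.add(child.id)
            if not exons:
                # a bare gene line: use the gene span as a single exon
                exons = [(gene.start - 1, gene.end)]
            annotations.append(
                GeneAnnotation(
                    gene_id=gene.id,
                    scaffold_id=gene.seqid,
                    strand=gene.strand,
                    exons=tuple(exons),
                    biotype=gtype,
                )
            )
    orphans = [
        feat.id
        for feat in db.features_of_type("exon")
        if feat.id not in claimed_exons
    ]
    if orphans:
        raise ValueError(f"exons without a resolvable gene parent: {orphans}")
    return annotations


def write_gff(annotations, path) -> None:
    """Write GeneAnnotations as GFF3 gene -> mRNA -> exon feature triples."""
    lines = ["##gff-version 3"]
    for ann in annotations:
        src = "genevidence"
        start, end = ann.span
        attrs = f"ID={ann.gene_id}"
        lines.append(
            "\t".join(
                [ann.scaffold_id, src, ann.biotype, str(start + 1), str(end),
                 ".", ann.strand, ".", attrs]
            )
        )
        mrna_id = f"{ann.gene_id}.t1"
        lines.append(
            "\t".join(
                [ann.scaffold_id, src, "mRNA", str(start + 1), str(end),
                 ".", ann.strand, ".", f"ID={mrna_id};Parent={ann.gene_id}"]
            )
        )
        for k, (es, ee) in enumerate(ann.exons, start=1):
            lines.append(
                "\t".join(
                    [ann.scaffold_id, src, "exon", str(es + 1), str(ee),
                     ".", ann.strand, ".", f"ID={mrna_id}.exon{k};Parent={mrna_id}"]
                )
            )
    with open(path, "w") as handle:
        handle.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# metadata TSV

METADATA_COLUMNS = ["genome_id", "coverage_x", "n_scaffolds", "n50"]


def read_metadata_tsv(path) -> list[AssemblyMetadata]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata table missing columns: {missing}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            AssemblyMetadata(
                genome_id=str(row.genome_id),
                coverage_x=None if pd.isna(row.coverage_x) else float(row.coverage_x),
                n_scaffolds=None if pd.isna(row.n_scaffolds) else int(row.n_scaffolds),
                declared_n50=None if pd.isna(row.n50) else int(row.n50),
            )
        )
    return out


def write_metadata_tsv(metadata, path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        [
            {
                "genome_id": m.genome_id,
                "coverage_x": m.coverage_x,
                "n_scaffolds": m.n_scaffolds,
                "n50": m.declared_n50,
            }
            for m in metadata
        ],
        columns=METADATA_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sequence primitives

def revcomp(dna: str) -> str:
    """Reverse complement, preserving soft-mask case."""
    _check_dna(dna)
    return dna.translate(_COMPLEMENT)[::-1]


def translate(dna: str, frame: int = 0) -> str:
    """Translate one reading frame with the standard code.

    Every codon containing an N yields ``X``; stops render as ``*``.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    _check_dna(dna)
    seq = dna.upper()
    aas = []
    for i in range(frame, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if "N" in codon:
            aas.append("X")
        elif codon in _STOP_CODONS:
            aas.append("*")
        else:
            aas.append(_CODON_TABLE[codon])
    return "".join(aas)


def _region_slice(seq: str, region: tuple[int, int] | None) -> str:
    if region is None:
        return seq
    s, e = region
    if not (0 <= s < e <= len(seq)):
        raise ValueError(f"region [{s},{e}) out of bounds or empty for length {len(seq)}")
    return seq[s:e]


def gc_fraction(seq: str, region: tuple[int, int] | None = None) -> float | None:
    """G+C over unambiguous bases in a region; None when the region is all N."""
    sub = _region_slice(seq, region)
    if not sub:
        raise ValueError("empty sequence")
    gc = sum(sub.count(c) for c in "GCgc")
    unambiguous = len(sub) - sub.count("N") - sub.count("n")
    if unambiguous == 0:
        return None
    return gc / unambiguous


def masked_fraction(seq: str, region: tuple[int, int] | None = None) -> float:
    """Lowercase (soft-masked) bases over region length."""
    sub = _region_slice(seq, region)
    if not sub:
        raise ValueError("empty sequence")
    return sum(1 for c in sub if c.islower()) / len(sub)


def gap_runs(seq: str) -> list[tuple[int, int]]:
    """Maximal runs of N/n as sorted, disjoint 0-based half-open intervals."""
    return [m.span() for m in re.finditer(r"[Nn]+", seq)]


def n50(lengths) -> int:
    """Smallest L such that scaffolds of length >= L total at least half the assembly."""
    lengths = list(lengths)
    if not lengths:
        raise ValueError("n50 of an empty length list is undefined")
    if any(l <= 0 for l in lengths):
        raise ValueError("all lengths must be positive")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    acc = 0
    for l in ordered:
        acc += l
        if acc >= half:
            return l
    raise AssertionError("unreachable")


def assembly_stats(scaffolds) -> AssemblyStats:
    lengths = [sc.length for sc in scaffolds]
    total = sum(lengths)
    gc = 0
    unamb = 0
    masked = 0
    gaps = 0
    for sc in scaffolds:
        s = sc.sequence
        gc += sum(s.count(c) for c in "GCgc")
        n_count = s.count("N") + s.count("n")
        unamb += len(s) - n_count
        gaps += n_count
        masked += sum(1 for c in s if c.islower())
    return AssemblyStats(
        n50=n50(lengths),
        total_length=total,
        n_scaffolds=len(lengths),
        gc_fraction=(gc / unamb) if unamb else None,
        masked_fraction=masked / total,
        gap_fraction=gaps / total,
    )


def reverse_complement_record(record: AssemblyRecord) -> AssemblyRecord:
    """Reverse-complement every scaffold and remap annotations accordingly."""
    new_scaffolds = [Scaffold(sc.id, revcomp(sc.sequence)) for sc in record.scaffolds]
    lengths = {sc.id: sc.length for sc in record.scaffolds}
    new_annotations = []
    for ann in record.annotations:
        n = lengths[ann.scaffold_id]
        exons = tuple(sorted((n - e, n - s) for s, e in ann.exons))
        new_annotations.append(
            replace(ann, exons=exons, strand="-" if ann.strand == "+" else "+")
        )
    return AssemblyRecord(
        genome_id=record.genome_id,
        scaffolds=new_scaffolds,
        annotations=new_annotations,
        metadata=record.metadata,
    )
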