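"""Transcript-read support, in-silico PCR and the missed-vs-missing verdict.

Read support is deliberately exact-match (substring equality on either
strand): the question is whether any read covers the predicted CDS
perfectly, not how abundantly the locus is expressed.  The integration
step turns the locus assessment, spliced-alignment exon evidence, domain
architecture and read coverage into one of five verdicts through a
deterministic rule cascade.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .domains import DomainArchitecture
from .seqio import revcomp, translate
from .splice import SplicedAlignment
from .synteny import LocusAssessment

__all__ = [
    "CoverageProfile",
    "PrimerCheck",
    "VerdictThresholds",
    "EvidenceReport",
    "VERDICTS",
    "exact_match_coverage",
    "covered_aa",
    "insilico_primer_match",
    "integrate",
]

VERDICTS = (
    "PRESENT_ANNOTATED",
    "PRESENT_UNANNOTATED",
    "LIKELY_MISSED",
    "INDETERMINATE",
    "LIKELY_ABSENT",
)


@dataclass
class CoverageProfile:
    """Per-codon exact-match read counts over a CDS."""

    counts: np.ndarray
    region_annotations: dict = field(default_factory=dict)

    @property
    def n_codons(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class PrimerCheck:
    primer: str
    best_identity: float
    orientation: str
    matched_peptide: str | None
    match_interval: tuple[int, int]


def exact_match_coverage(reads, cds: str, region_annotations: dict | None = None) -> CoverageProfile:
    """Count, per codon, the exact substring matches covering it.

    A read contributes to every codon fully contained in an exact match of
    the read (or its reverse complement) to the CDS; matches at multiple
    positions all accumulate.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    counts = np.zeros(len(cds) // 3, dtype=np.int64)
    for read in reads:
        read = read.upper()
        if len(read) < 3:
            continue
        seen = set()
        for query in (read, revcomp(read)):
            if query in seen:
                continue
            seen.add(query)
            start = cds.find(query)
            while start != -1:
                first = (start + 2) // 3
                last = (start + len(query)) // 3
                if last > first:
                    counts[first:last] += 1
                start = cds.find(query, start + 1)
    return CoverageProfile(
        counts=counts, region_annotations=dict(region_annotations or {})
    )


def covered_aa(profile: CoverageProfile, region: tuple[int, int] | None = None) -> int:
    """Number of codons in a region with at least one exact-match read."""
    counts = profile.counts
    if region is not None:
        s, e = region
        if not (0 <= s <= e <= len(counts)):
            raise ValueError(f"region [{s},{e}) outside profile of {len(counts)} codons")
        counts = counts[s:e]
    return int(np.count_nonzero(counts))


def insilico_primer_match(primer: str, dna: str) -> PrimerCheck:
    """Best ungapped match of a primer against a template, both orientations.

    Identity is scored over the primer length.  When the match is perfect
    the matched genomic segment is translated in the codon frame implied by
    its offset (exact for an in-frame CDS template), exposing the peptide a
    perfectly matching primer encodes.
    """
    if len(primer) < 10:
        raise ValueError("primer must be at least 10 nt")
    primer_u = primer.upper()
    dna_u = dna.upper()
    if len(dna_u) < len(primer_u):
        raise ValueError("template shorter than primer")
    p_arr = np.frombuffer(primer_u.encode(), dtype=np.uint8)
    d_arr = np.frombuffer(dna_u.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(d_arr, len(p_arr))
    best = (-1.0, "forward", 0)
    for orientation, query in (("forward", p_arr),
                               ("reverse", np.frombuffer(revcomp(primer_u).encode(), dtype=np.uint8))):
        identities = (windows == query).sum(axis=1) / len(p_arr)
        j = int(np.argmax(identities))
        if identities[j] > best[0]:
            best = (float(identities[j]), orientation, j)
    identity, orientation, start = best
    interval = (start, start + len(primer_u))
    peptide = None
    if identity == 1.0:
        segment = dna_u[interval[0] : interval[1]]
        frame = (3 - interval[0] % 3) % 3
        peptide = translate(segment, frame)
    return PrimerCheck(
        primer=primer,
        best_identity=identity,
        orientation=orientation,
        matched_peptide=peptide,
        match_interval=interval,
    )


# ---------------------------------------------------------------------------
# verdict integration

@dataclass(frozen=True)
class VerdictThresholds:
    """Rule thresholds for the evidence cascade.

    ``min_frk_exon_aa``: an exon chain counts as exon evidence when at
    least one exon overlaps the reference FRK domain by this many aligned
    aa.  ``min_covered_codons``: read support requires this many codons
    with exact-match coverage.
    """

    min_frk_exon_aa: int = 15
    min_covered_codons: int = 30
    frk_interval: tuple[int, int] | None = None


@dataclass
class EvidenceReport:
    locus: LocusAssessment
    exons: SplicedAlignment | None
    architecture: DomainArchitecture | None
    coverage: CoverageProfile | None
    verdict: str
    rationale: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "genome_id": self.locus.genome_id,
            "locus_status": self.locus.status,
            "gap_total": self.locus.gap_total,
            "gap_largest": self.locus.gap_largest,
            "region_gc": self.locus.region_gc,
            "n_exons": len(self.exons.exons) if self.exons else None,
            "exon_score": self.exons.score if self.exons else None,
            "covered_codons": (
                covered_aa(self.coverage) if self.coverage is not None else None
            ),
            "verdict": self.verdict,
            "rationale": list(self.rationale),
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)

    def to_text(self) -> str:
        d = self.to_dict()
        lines = [f"locus {d['genome_id']}: {d['verdict']}"]
        lines.append(f"  synteny status: {d['locus_status']}")
        if self.exons is not None:
            lines.append(
                f"  exon evidence: {d['n_exons']} exon(s), score {d['exon_score']}"
            )
        if self.coverage is not None:
            lines.append(f"  read support: {d['covered_codons']} codons covered")
        for r in self.rationale:
            lines.append(f"  - {r}")
        return "\n".join(lines)


def _exon_evidence(exons, arch, thresholds) -> bool:
    if exons is None or exons.is_empty:
        return False
    frk = thresholds.frk_interval
    if frk is None and arch is not None:
        frk = arch.frk_interval
    if frk is None:
        return any(e.protein[1] - e.protein[0] >= thresholds.min_frk_exon_aa
                   for e in exons.exons)
    fs, fe = frk
    return any(
        min(e.protein[1], fe) - max(e.protein[0], fs) >= thresholds.min_frk_exon_aa
        for e in exons.exons
    )


def integrate(
    locus: LocusAssessment,
    exons: SplicedAlignment | None = None,
    architecture: DomainArchitecture | None = None,
    coverage: CoverageProfile | None = None,
    thresholds: VerdictThresholds | None = None,
) -> EvidenceReport:
    """Deterministic rule cascade from evidence to verdict."""
    thresholds = thresholds or VerdictThresholds()
    rationale: list[str] = []
    exon_ev = _exon_evidence(exons, architecture, thresholds)
    read_ev = (
        coverage is not None
        and covered_aa(coverage) >= thresholds.min_covered_codons
    )
    flanks_conserved = (
        locus.upstream is not None and locus.upstream.present
        and locus.downstream is not None and locus.downstream.present
    )

    if locus.status == "ANNOTATED":
        verdict = "PRESENT_ANNOTATED"
        rationale.append("target annotated between conserved flanks")
    elif locus.status in ("SPANNED_UNANNOTATED", "GAP_IN_REGION") and exon_ev:
        verdict = "PRESENT_UNANNOTATED"
        rationale.append(
            "spliced-alignment exons over the forkhead domain inside the "
            "flank-spanned region"
        )
        if read_ev:
            rationale.append("corroborated by exact-match transcript reads")
    elif locus.status in ("GAP_IN_REGION", "FLANKS_SPLIT") and flanks_conserved and not exon_ev:
        verdict = "LIKELY_MISSED"
        rationale.append(
            "conserved flanks but the locus region is gapped or split; "
            "absence of exon evidence is uninformative"
        )
    elif locus.status == "SPANNED_UNANNOTATED" and not exon_ev and not read_ev:
        verdict = "LIKELY_ABSENT"
        rationale.append(
            "clean spanned region with neither exon evidence nor read support"
        )
    else:
        verdict = "INDETERMINATE"
        rationale.append("evidence insufficient or conflicting")
        if read_ev:
            rationale.append("read support present without locatable exons")

    return EvidenceReport(
        locus=locus,
        exons=exons,
        architecture=architecture,
        coverage=coverage,
        verdict=verdict,
        rationale=tuple(rationale),
    )
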