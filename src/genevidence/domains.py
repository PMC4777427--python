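"""FoxP domain architecture and clade signature-residue analysis.

FoxP3 is distinguished from its FoxP1/2/4 paralogues by a C-terminal
forkhead (FRK) domain, an adjacent leucine zipper (LZ), a zinc finger (ZF)
that is absent in some clades, and a disordered, proline-enriched
N-terminal region (ProR).  This module locates those features in a protein
sequence, measures proline enrichment, and discovers clade "signature"
residues in a baseline-anchored alignment: columns conserved within an
ingroup and absent from a set of comparator (e.g. paralogue) sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "MotifPattern",
    "LZ_PATTERN",
    "LZ_PATTERN_IV",
    "LZ_EXEMPLAR",
    "ZF_CONSENSUS",
    "FRK_CONSENSUS",
    "DomainTemplates",
    "DEFAULT_TEMPLATES",
    "DomainArchitecture",
    "AnchoredAlignment",
    "SignatureResult",
    "proline_fraction",
    "find_motif",
    "detect_architecture",
    "anchor_align",
    "signature_residues",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# motif patterns

@dataclass(frozen=True)
class MotifPattern:
    """Anchor residues separated by fixed-length spacers.

    ``anchors[i]`` is the set of residues allowed at the i-th anchor;
    ``spacers[i]`` is the number of unconstrained residues between anchor i
    and anchor i+1.
    """

    anchors: tuple[frozenset, ...]
    spacers: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.spacers) != len(self.anchors) - 1:
            raise ValueError("need exactly one spacer between consecutive anchors")
        if any(s < 0 for s in self.spacers):
            raise ValueError("spacers must be >= 0")

    @property
    def length(self) -> int:
        return len(self.anchors) + sum(self.spacers)

    @property
    def anchor_offsets(self) -> tuple[int, ...]:
        offsets = [0]
        for sp in self.spacers:
            offsets.append(offsets[-1] + 1 + sp)
        return tuple(offsets)


def _fs(chars: str) -> frozenset:
    return frozenset(chars)


#: leucine-zipper consensus V-x(6)-L-x(6)-L-x(6)-L
LZ_PATTERN = MotifPattern((_fs("V"), _fs("L"), _fs("L"), _fs("L")), (6, 6, 6))
#: variant admitting isoleucine at the first position (seen in e.g. ground tit)
LZ_PATTERN_IV = MotifPattern((_fs("VI"), _fs("L"), _fs("L"), _fs("L")), (6, 6, 6))

#: synthetic 22-aa exemplar satisfying the LZ consensus, used for planting
LZ_EXEMPLAR = "VEQLESRLKDVRSHLQMQTNEL"
assert len(LZ_EXEMPLAR) == LZ_PATTERN.length == 22

#: synthetic C2H2-like zinc-finger exemplar (28 aa); a stand-in consensus,
#: not any species' real ZF
ZF_CONSENSUS = "PKCTECGKGFARSDELTRHMRIHTGEKP"

#: synthetic forkhead-like exemplar (95 aa) carrying the NLSLH peptide that
#: the single matching chicken PCR primer encodes; a stand-in consensus
FRK_CONSENSUS = (
    "KPPYSYAQLIVQAITSAPDRQLTLNEIYQWIMDNLSLHKMSSSEWQNSIRHNLSANRCFVKVPR"
    "SQDDPGKGSYWTIDPASEAMFDNGSFLRRRK"
)
assert len(FRK_CONSENSUS) == 95 and "NLSLH" in FRK_CONSENSUS


@dataclass(frozen=True)
class DomainTemplates:
    """Curated reference material for architecture detection."""

    zf_consensus: str = ZF_CONSENSUS
    frk_consensus: str = FRK_CONSENSUS
    lz_pattern: MotifPattern = LZ_PATTERN_IV
    identity_floor: float = 0.35


DEFAULT_TEMPLATES = DomainTemplates()


@dataclass(frozen=True)
class DomainArchitecture:
    """Located FoxP features, N- to C-terminal: ProR <= ZF <= LZ <= FRK."""

    pror_interval: tuple[int, int]
    pror_proline_fraction: float | None
    zf_present: bool
    zf_interval: tuple[int, int] | None
    lz_interval: tuple[int, int] | None
    lz_first_residue: str | None
    frk_interval: tuple[int, int]
    n_terminal_region: tuple[int, int]


# ---------------------------------------------------------------------------
# elementary measures

def proline_fraction(protein: str, region: tuple[int, int] | None = None) -> float:
    """Fraction of prolines in a region; alignment gaps are excluded from the
    denominator, X counts toward it."""
    if region is not None:
        s, e = region
        if not (0 <= s < e <= len(protein)):
            raise ValueError(f"region [{s},{e}) out of bounds or empty")
        protein = protein[s:e]
    if not protein:
        raise ValueError("empty region")
    residues = [c for c in protein if c != "-"]
    if not residues:
        raise ValueError("region contains only gaps")
    return residues.count("P") / len(residues)


def find_motif(protein: str, pattern: MotifPattern) -> list[tuple[int, int]]:
    """All start positions where the anchored pattern matches exactly."""
    hits = []
    L = pattern.length
    offsets = pattern.anchor_offsets
    for start in range(0, len(protein) - L + 1):
        if all(protein[start + off] in allowed
               for off, allowed in zip(offsets, pattern.anchors)):
            hits.append((start, start + L))
    return hits


# ---------------------------------------------------------------------------
# pairwise alignment helpers

def _make_aligner(mode: str) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def _best_local_hit(template: str, protein: str) -> tuple[tuple[int, int], float]:
    """Locate a template in a protein by local alignment.

    Returns the protein interval covered and the identity over the template
    span (matches / template length).
    """
    aligner = _make_aligner("local")
    aln = aligner.align(protein, template)[0]
    blocks = aln.aligned
    matches = 0
    for (ts, te), (qs, qe) in zip(blocks[0], blocks[1]):
        matches += sum(
            1 for a, b in zip(protein[ts:te], template[qs:qe]) if a == b
        )
    interval = (int(blocks[0][0][0]), int(blocks[0][-1][1]))
    return interval, matches / len(template)


def detect_architecture(
    protein: str, templates: DomainTemplates = DEFAULT_TEMPLATES
) -> DomainArchitecture:
    """Locate ProR/ZF/LZ/FRK in a FoxP-family protein.

    The FRK domain must be locatable (identity over the template span at or
    above the floor), otherwise the sequence is not classifiable as
    FoxP-family and a ValueError is raised.  The ZF is marked absent below
    the floor.  The N-terminal region runs from the start of the protein to
    the ZF, or to the LZ in sequences lacking a ZF.
    """
    if not protein:
        raise ValueError("empty protein")
    if "-" in protein:
        raise ValueError("unaligned (gap-free) protein expected")
    frk_interval, frk_identity = _best_local_hit(templates.frk_consensus, protein)
    if frk_identity < templates.identity_floor:
        raise ValueError(
            f"no forkhead domain locatable (identity {frk_identity:.2f} below "
            f"floor {templates.identity_floor}); not a FoxP-family sequence"
        )
    n_term_prefix = protein[: frk_interval[0]]
    zf_present = False
    zf_interval = None
    if len(n_term_prefix) >= len(templates.zf_consensus) // 2:
        interval, identity = _best_local_hit(templates.zf_consensus, n_term_prefix)
        if identity >= templates.identity_floor:
            zf_present = True
            zf_interval = interval
    lz_lo = zf_interval[1] if zf_interval else 0
    lz_hits = [
        h for h in find_motif(protein, templates.lz_pattern)
        if h[0] >= lz_lo and h[1] <= frk_interval[0]
    ]
    lz_interval = lz_hits[-1] if lz_hits else None  # the match nearest the FRK
    if zf_present:
        n_term_end = zf_interval[0]
    elif lz_interval:
        n_term_end = lz_interval[0]
    else:
        n_term_end = frk_interval[0]
    n_terminal_region = (0, n_term_end)
    pror_fraction = (
        proline_fraction(protein, n_terminal_region) if n_term_end > 0 else None
    )
    return DomainArchitecture(
        pror_interval=n_terminal_region,
        pror_proline_fraction=pror_fraction,
        zf_present=zf_present,
        zf_interval=zf_interval,
        lz_interval=lz_interval,
        lz_first_residue=protein[lz_interval[0]] if lz_interval else None,
        frk_interval=frk_interval,
        n_terminal_region=n_terminal_region,
    )


# ---------------------------------------------------------------------------
# baseline-anchored alignment and signatures

@dataclass
class AnchoredAlignment:
    """Per-sequence rows indexed by baseline position.

    Every row has the baseline's length; residues of other sequences that do
    not align to a baseline position (insertions) are dropped.  ``masks``
    flags missing data: X residues and terminal unaligned stretches, as for
    a partial sequence.
    """

    baseline_id: str
    rows: dict = field(default_factory=dict)
    masks: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.rows[self.baseline_id])

    def has_data(self, seq_id: str, column: int) -> bool:
        return not self.masks[seq_id][column]


def _mask_for_row(row: str) -> tuple[bool, ...]:
    n = len(row)
    mask = [c == "X" for c in row]
    i = 0
    while i < n and row[i] == "-":
        mask[i] = True
        i += 1
    j = n - 1
    while j >= 0 and row[j] == "-":
        mask[j] = True
        j -= 1
    return tuple(mask)


def anchor_align(sequences: dict, baseline_id: str) -> AnchoredAlignment:
    """Globally align every sequence to a baseline (affine gaps, BLOSUM62)."""
    if baseline_id not in sequences:
        raise ValueError(f"baseline {baseline_id!r} not among sequences")
    if len(sequences) < 2:
        raise ValueError("need at least two sequences")
    for sid, seq in sequences.items():
        if not seq:
            raise ValueError(f"empty sequence {sid!r}")
    baseline = sequences[baseline_id]
    aligner = _make_aligner("global")
    out = AnchoredAlignment(baseline_id=baseline_id)
    out.rows[baseline_id] = baseline
    out.masks[baseline_id] = tuple(c == "X" for c in baseline)
    for sid, seq in sequences.items():
        if sid == baseline_id:
            continue
        aln = aligner.align(baseline, seq)[0]
        row = ["-"] * len(baseline)
        for (bs, be), (qs, qe) in zip(aln.aligned[0], aln.aligned[1]):
            for k in range(be - bs):
                row[bs + k] = seq[qs + k]
        row = "".join(row)
        out.rows[sid] = row
        out.masks[sid] = _mask_for_row(row)
    return out


@dataclass(frozen=True)
class SignatureResult:
    columns: tuple[tuple[int, str], ...]
    n_signature: int
    overlap_with_reference_signature: int | None


def signature_residues(
    alignment: AnchoredAlignment,
    ingroup_ids,
    exclusion_sets,
    reference_signature=None,
    max_ingroup_mismatches: int = 0,
) -> SignatureResult:
    """Columns conserved across the ingroup and absent from every exclusion
    sequence.

    A column qualifies when (a) at least one ingroup member has data there
    and all members with data carry the same residue (up to the configured
    mismatch allowance), and (b) that residue does not occur at the same
    column in any exclusion-set sequence with data.  ``reference_signature``
    is a list of (baseline position, residue) pairs; the overlap counts the
    entries whose residue is carried by every ingroup member with data.
    """
    ingroup_ids = list(ingroup_ids)
    if not ingroup_ids:
        raise ValueError("ingroup must be non-empty")
    for sid in ingroup_ids:
        if sid not in alignment.rows:
            raise ValueError(f"ingroup id {sid!r} not in alignment")
    exclusion_ids = [sid for group in exclusion_sets for sid in group]
    columns = []
    for c in range(alignment.length):
        vals = [
            alignment.rows[sid][c]
            for sid in ingroup_ids
            if alignment.has_data(sid, c)
        ]
        if not vals:
            continue
        counts = {}
        for v in vals:
            counts[v] = counts.get(v, 0) + 1
        residue, majority = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
        if residue == "-" or len(vals) - majority > max_ingroup_mismatches:
            continue
        leaked = any(
            alignment.has_data(sid, c) and alignment.rows[sid][c] == residue
            for sid in exclusion_ids
        )
        if not leaked:
            columns.append((c, residue))
    overlap = None
    if reference_signature is not None:
        overlap = 0
        for pos, res in reference_signature:
            vals = [
                alignment.rows[sid][pos]
                for sid in ingroup_ids
                if alignment.has_data(sid, pos)
            ]
            if vals and all(v == res for v in vals):
                overlap += 1
    return SignatureResult(
        columns=tuple(columns), n_signature=len(columns),
        overlap_with_reference_signature=overlap,
    )
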