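"""A small reader for FGENESH-style gene-prediction reports.

Only the parts of the classic report layout that downstream analysis
needs are parsed: the CDS exon rows (CDSf/CDSi/CDSl/CDSo) and the
predicted protein record.  The prediction algorithm itself is out of
scope; its output is treated as an input.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = ["PredictedGene", "read_fgenesh", "format_prediction"]

_EXON_RE = re.compile(
    r"^\s*\d+\s+([+-])\s+(\d+)\s+CDS[filo]\s+(\d+)\s*-\s*(\d+)", re.MULTILINE
)


@dataclass(frozen=True)
class PredictedGene:
    """One predicted gene: 0-based half-open exon intervals plus protein."""

    exons: tuple[tuple[int, int], ...]
    strand: str
    protein: str

    @property
    def n_exons(self) -> int:
        return len(self.exons)


def read_fgenesh(text: str) -> PredictedGene:
    """Parse exon rows and the predicted protein from report text."""
    exons = []
    strands = set()
    for m in _EXON_RE.finditer(text):
        strand, _num, start, end = m.groups()
        strands.add(strand)
        exons.append((int(start) - 1, int(end)))
    if not exons:
        raise ValueError("no CDS exon rows found in FGENESH report")
    if len(strands) != 1:
        raise ValueError("mixed strands in FGENESH report")
    exons.sort()
    protein_lines = []
    in_protein = False
    for line in text.splitlines():
        if line.startswith(">"):
            if in_protein:
                break
            in_protein = True
            continue
        if in_protein:
            chunk = line.strip()
            if chunk:
                protein_lines.append(chunk)
    protein = "".join(protein_lines)
    if not protein:
        raise ValueError("no predicted protein record in FGENESH report")
    return PredictedGene(exons=tuple(exons), strand=strands.pop(), protein=protein)


def format_prediction(seq_name: str, exons, protein: str, strand: str = "+") -> str:
    """Emit a synthetic report in the classic FGENESH layout (for fixtures)."""
    exons = sorted(tuple(e) for e in exons)
    lines = [
        " FGENESH synthetic prediction report",
        f" Seq name: {seq_name}",
        f" Number of predicted genes 1",
        f" Number of predicted exons {len(exons)}",
        "   G Str   Feature   Start        End    Score",
    ]
    for k, (s, e) in enumerate(exons, start=1):
        if len(exons) == 1:
            feat = "CDSo"
        elif k == 1:
            feat = "CDSf"
        elif k == len(exons):
            feat = "CDSl"
        else:
            feat = "CDSi"
        lines.append(
            f"   1 {strand} {k:>6} {feat} {s + 1:>8} - {e:>8}   10.00"
        )
    lines.append("")
    lines.append("Predicted protein(s):")
    lines.append(
        f">FGENESH:   1  {len(exons)} exon (s)   {exons[0][0] + 1}  -  "
        f"{exons[-1][1]}   {len(protein)} aa, chain {strand}"
    )
    for i in range(0, len(protein), 60):
        lines.append(protein[i : i + 60])
    return "\n".join(lines) + "\n"
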