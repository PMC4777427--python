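"""Spliced protein-to-genome alignment (a GeneWise-style exon finder).

A dynamic program aligns a reference protein to genomic DNA at codon
granularity, with affine gaps inside exons and GT..AG introns (length >=
``min_intron``) between exons.  Alignment is local in both sequences, both
strands are tried, introns fall on codon boundaries (phase 0; frameshifts
are not modelled), and N-containing codons are impassable inside exons
while intron interiors are unconstrained -- which is what lets a gapped
region yield a partial exon set.

Ties are broken toward fewer introns (a small per-intron epsilon folded
into the scaled DP score) and then by a fixed transition preference during
traceback, so results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Align import substitution_matrices

from .seqio import revcomp

__all__ = [
    "ScoringScheme",
    "ExonHit",
    "SplicedAlignment",
    "spliced_align",
    "curate_boundaries",
    "exon_report",
]

NEG = float("-inf")
_SCALE = 1024  # must exceed any possible intron count (protein < 1024 aa)
# traceback transition codes
_FROM_M, _FROM_D, _FROM_I, _FROM_N, _FROM_START = 0, 1, 2, 3, 4


@dataclass(frozen=True)
class ScoringScheme:
    matrix_name: str = "BLOSUM62"
    gap_open: int = -12
    gap_extend: int = -2
    intron_penalty: int = -10
    min_intron: int = 30
    donor: str = "GT"
    acceptor: str = "AG"

    def __post_init__(self) -> None:
        if self.min_intron < 4:
            raise ValueError("min_intron must be >= 4")
        if self.gap_open >= 0 or self.gap_extend >= 0 or self.intron_penalty >= 0:
            raise ValueError("penalties must be negative")

    @property
    def matrix(self):
        return substitution_matrices.load(self.matrix_name)


@dataclass(frozen=True)
class ExonHit:
    """One aligned exon: genomic and protein intervals plus splice phase."""

    genomic: tuple[int, int]
    protein: tuple[int, int]
    phase: int = 0


@dataclass(frozen=True)
class SplicedAlignment:
    exons: tuple[ExonHit, ...]
    strand: str
    score: int
    coverage: float
    n_introns: int = 0
    flags: tuple[str, ...] = ()

    @property
    def is_empty(self) -> bool:
        return not self.exons


def _codon_aa_indices(dna: str, alphabet: str) -> np.ndarray:
    """aa index of the codon ending at each position j (or -1 if N inside)."""
    from .seqio import translate

    n = len(dna)
    out = np.full(n + 1, -1, dtype=np.int64)
    if n < 3:
        return out
    aa_index = {aa: k for k, aa in enumerate(alphabet)}
    for frame in (0, 1, 2):
        pep = translate(dna, frame)
        for k, aa in enumerate(pep):
            j = frame + 3 * k + 3
            if aa != "X":
                out[j] = aa_index[aa]
    return out


def _dp_one_strand(protein: str, dna: str, scheme: ScoringScheme):
    """Run the scaled DP on one strand; return (best_combined, alignment bits).

    The alignment bits are None when no positive-scoring local alignment
    exists.  Genomic coordinates refer to the supplied ``dna``.
    """
    m, n = len(protein), len(dna)
    mat = scheme.matrix
    alphabet = mat.alphabet
    aa_index = {aa: k for k, aa in enumerate(alphabet)}
    x_idx = aa_index["X"]
    prot_idx = np.array([aa_index.get(aa, x_idx) for aa in protein], dtype=np.int64)
    smat = (np.asarray(mat) * _SCALE).astype(np.float64)

    dna_u = dna.upper()
    codon_aa = _codon_aa_indices(dna_u, alphabet)
    codon_ok = codon_aa >= 0
    donor_ok = np.zeros(n + 1, dtype=bool)
    acc_ok = np.zeros(n + 1, dtype=bool)
    for j in range(n - 1):
        if dna_u[j : j + 2] == scheme.donor:
            donor_ok[j] = True
    for j in range(2, n + 1):
        if dna_u[j - 2 : j] == scheme.acceptor:
            acc_ok[j] = True

    open_s = scheme.gap_open * _SCALE
    ext_s = scheme.gap_extend * _SCALE
    intron_s = scheme.intron_penalty * _SCALE - 1  # epsilon: prefer fewer introns
    mi = scheme.min_intron

    M_prev = np.full(n + 1, NEG)
    D_prev = np.full(n + 1, NEG)
    I_prev = np.full(n + 1, NEG)

    p_choice = np.zeros((m + 1, n + 1), dtype=np.uint8)
    d_bit = np.zeros((m + 1, n + 1), dtype=bool)
    i_bit = np.zeros((m + 1, n + 1), dtype=bool)
    donor_idx = np.full((m + 1, n + 1), -1, dtype=np.int64)

    idx = np.arange(n + 1)
    best = 0.0
    best_cell = None

    for i in range(1, m + 1):
        # deletion (residue vs nothing)
        d_open = M_prev + open_s
        d_ext = D_prev + ext_s
        D_row = np.maximum(d_open, d_ext)
        d_bit[i] = d_open >= d_ext

        # intron state fed by M of the previous row
        donor_vals = np.where(donor_ok, M_prev, NEG)
        runmax = np.maximum.accumulate(donor_vals)
        prev_runmax = np.concatenate(([NEG], runmax[:-1]))
        improved = donor_vals > prev_runmax
        run_argmax = np.maximum.accumulate(np.where(improved, idx, -1))
        N_prev = np.full(n + 1, NEG)
        if n + 1 > mi:
            cand = runmax[: n + 1 - mi] + intron_s
            N_prev[mi:] = np.where(acc_ok[mi:], cand, NEG)
            donor_idx[i, mi:] = np.where(acc_ok[mi:], run_argmax[: n + 1 - mi], -1)

        # predecessor for a codon match, with fixed preference order
        stack = np.stack([M_prev, D_prev, I_prev, N_prev])
        choice = np.argmax(stack, axis=0).astype(np.uint8)
        P = stack[choice, idx]
        fresh = P < 0.0
        P = np.where(fresh, 0.0, P)
        choice = np.where(fresh, np.uint8(_FROM_START), choice)
        p_choice[i] = choice

        # codon match
        M_row = np.full(n + 1, NEG)
        cod = codon_aa[3:]
        valid = cod >= 0
        scores = np.where(valid, smat[prot_idx[i - 1]][np.where(valid, cod, 0)], NEG)
        M_row[3:] = scores + P[:-3]

        # insertion (codon vs nothing), stride-3 closed-form scan; chains
        # break at N-containing codons (impassable inside exons)
        I_row = np.full(n + 1, NEG)
        for r in range(3):
            pos = np.arange(r, n + 1, 3)
            if len(pos) < 2:
                continue
            t = np.arange(len(pos), dtype=np.float64)
            A = M_row[pos] - t * ext_s
            valid = codon_ok[pos]
            R = np.full(len(pos), NEG)
            bad = np.flatnonzero(~valid)
            for b_idx in range(len(bad) + 1):
                lo = int(bad[b_idx - 1]) if b_idx > 0 else 0
                hi = int(bad[b_idx]) if b_idx < len(bad) else len(pos)
                if hi > lo + 1:
                    R[lo + 1 : hi] = np.maximum.accumulate(A[lo : hi - 1])
            vals = open_s + (t[1:] - 1.0) * ext_s + R[1:]
            I_row[pos[1:]] = np.where(valid[1:], vals, NEG)
        with np.errstate(invalid="ignore"):
            i_bit[i][3:] = M_row[:-3] + open_s >= I_row[3:]

        row_best_j = int(np.argmax(M_row))
        if M_row[row_best_j] > best:
            best = float(M_row[row_best_j])
            best_cell = (i, row_best_j)

        M_prev, D_prev, I_prev = M_row, D_row, I_row

    if best_cell is None:
        return 0.0, None

    # -------- traceback --------
    i, j = best_cell
    exons: list[tuple[int, int, int, int]] = []  # gs, ge, ps, pe (built R->L)
    cur_ge, cur_pe = j, i
    n_introns = 0
    while True:
        # the codon ending at j was entered from (i-1, j-3); its transition
        # choice is stored at the predecessor column
        c = int(p_choice[i, j - 3])
        if c == _FROM_START:
            exons.append((j - 3, cur_ge, i - 1, cur_pe))
            start_res = i - 1
            break
        if c == _FROM_M:
            i, j = i - 1, j - 3
        elif c == _FROM_D:
            ii, jj = i - 1, j - 3
            while not d_bit[ii, jj]:
                ii -= 1
            i, j = ii - 1, jj
        elif c == _FROM_I:
            ii, jj = i - 1, j - 3
            while not i_bit[ii, jj]:
                jj -= 3
            i, j = ii, jj - 3
        elif c == _FROM_N:
            exons.append((j - 3, cur_ge, i - 1, cur_pe))
            jd = int(donor_idx[i, j - 3])
            n_introns += 1
            cur_ge, cur_pe = jd, i - 1
            i, j = i - 1, jd
        else:  # pragma: no cover
            raise AssertionError("corrupt traceback")

    exons.reverse()
    raw = (best + n_introns) / _SCALE
    return best, {
        "exons": exons,
        "n_introns": n_introns,
        "raw_score": raw,
        "protein_span": (start_res, best_cell[0]),
    }


def spliced_align(protein: str, dna: str, scheme: ScoringScheme | None = None) -> SplicedAlignment:
    """Best local spliced alignment of a protein to genomic DNA, both strands."""
    if not protein or not dna:
        raise ValueError("empty protein or DNA input")
    if len(protein) < 5:
        raise ValueError("protein must be at least 5 aa")
    if len(protein) >= _SCALE:
        raise ValueError(f"protein longer than {_SCALE - 1} aa is unsupported")
    scheme = scheme or ScoringScheme()

    best_fwd, tb_fwd = _dp_one_strand(protein, dna, scheme)
    rc = revcomp(dna)
    best_rev, tb_rev = _dp_one_strand(protein, rc, scheme)

    if tb_fwd is None and tb_rev is None:
        return SplicedAlignment(exons=(), strand="+", score=0, coverage=0.0)
    if best_fwd >= best_rev:
        tb, strand = tb_fwd, "+"
    else:
        tb, strand = tb_rev, "-"
    n = len(dna)
    exons = []
    for gs, ge, ps, pe in tb["exons"]:
        if strand == "-":
            gs, ge = n - ge, n - gs
        exons.append(ExonHit(genomic=(gs, ge), protein=(ps, pe), phase=0))
    exons.sort(key=lambda e: e.genomic)
    ps0, pe0 = tb["protein_span"]
    score = tb["raw_score"]
    score_int = int(round(score))
    return SplicedAlignment(
        exons=tuple(exons),
        strand=strand,
        score=score_int,
        coverage=(pe0 - ps0) / len(protein),
        n_introns=tb["n_introns"],
    )


# ---------------------------------------------------------------------------
# boundary curation against a trusted homolog's exon structure

def curate_boundaries(
    alignment: SplicedAlignment,
    reference_exon_structure,
    dna: str,
    protein: str,
    scheme: ScoringScheme | None = None,
    window_nt: int = 6,
) -> SplicedAlignment:
    """Snap exon junctions to a trusted homolog's protein breakpoints.

    A junction whose protein position lies within ``window_nt`` bases (2
    codons) of a reference breakpoint is moved there when the shifted donor
    and acceptor still read GT/AG; otherwise it is left alone and flagged.
    Coverage never decreases (junction shifts conserve the protein span).
    Only plus-strand alignments are curated in place; minus-strand input is
    curated in reverse-complement space.
    """
    scheme = scheme or ScoringScheme()
    intervals = sorted(tuple(iv) for iv in reference_exon_structure)
    for (a0, b0), (a1, b1) in zip(intervals, intervals[1:]):
        if a1 < b0:
            raise ValueError("reference exon structure has overlapping protein intervals")
    breakpoints = [b for _, b in intervals[:-1]]
    if alignment.is_empty or len(alignment.exons) < 2:
        return alignment

    work_dna = dna if alignment.strand == "+" else revcomp(dna)
    n = len(dna)

    def to_work(iv):
        return iv if alignment.strand == "+" else (n - iv[1], n - iv[0])

    exons = [
        [list(to_work(e.genomic)), list(e.protein)] for e in alignment.exons
    ]
    if alignment.strand == "-":
        exons.sort(key=lambda x: x[0][0])
    mat = scheme.matrix
    alphabet = mat.alphabet
    aa_index = {aa: k for k, aa in enumerate(alphabet)}
    codon_aa = _codon_aa_indices(work_dna.upper(), alphabet)

    def codon_score(res_i: int, j_end: int) -> float:
        ci = codon_aa[j_end]
        if ci < 0:
            return NEG
        return float(np.asarray(mat)[aa_index.get(protein[res_i], aa_index["X"])][ci])

    flags = list(alignment.flags)
    score = float(alignment.score)
    max_shift = window_nt // 3
    for k in range(len(exons) - 1):
        (lg, lp), (rg, rp) = exons[k], exons[k + 1]
        bp = lp[1]
        if bp in breakpoints:
            continue
        near = [r for r in breakpoints if abs(r - bp) <= max_shift]
        if not near:
            continue
        r = min(near, key=lambda x: (abs(x - bp), x))
        delta = 3 * (r - bp)
        donor, acceptor = lg[1], rg[0]
        new_donor, new_acceptor = donor + delta, acceptor + delta
        ok = (
            0 <= new_donor - 3 and new_acceptor + 3 <= len(work_dna)
            and lg[1] + delta - lg[0] >= 3 and rg[1] - (rg[0] + delta) >= 3
            and work_dna[new_donor : new_donor + 2].upper() == scheme.donor
            and work_dna[new_acceptor - 2 : new_acceptor].upper() == scheme.acceptor
        )
        if not ok:
            flags.append(f"junction_{k}:no_valid_splice_site_near_{r}")
            continue
        # rescore only the shifted codons (junction-adjacent codons are matches)
        old, new = 0.0, 0.0
        if delta > 0:
            for t in range(delta // 3):
                old += codon_score(bp + t, acceptor + 3 * (t + 1))
                new += codon_score(bp + t, donor + 3 * (t + 1))
        else:
            for t in range(-delta // 3):
                old += codon_score(r + t, donor + delta + 3 * (t + 1))
                new += codon_score(r + t, acceptor + delta + 3 * (t + 1))
        if not np.isfinite(new):
            flags.append(f"junction_{k}:shift_blocked_by_gap")
            continue
        lg[1], rg[0] = new_donor, new_acceptor
        lp[1], rp[0] = r, r
        score += new - old
        flags.append(f"junction_{k}:snapped_to_{r}")

    out_exons = []
    for (g, p) in exons:
        giv = tuple(g) if alignment.strand == "+" else (n - g[1], n - g[0])
        out_exons.append(ExonHit(genomic=giv, protein=tuple(p), phase=0))
    out_exons.sort(key=lambda e: e.genomic)
    return replace(
        alignment,
        exons=tuple(out_exons),
        score=int(round(score)),
        flags=tuple(flags),
    )


def exon_report(alignment: SplicedAlignment, domain_map: dict):
    """Per-exon table of overlapped protein domains and aligned-aa counts."""
    import pandas as pd

    rows = []
    for k, exon in enumerate(alignment.exons, start=1):
        ps, pe = exon.protein
        overlaps = {}
        for name, (ds, de) in domain_map.items():
            ov = max(0, min(pe, de) - max(ps, ds))
            if ov > 0:
                overlaps[name] = ov
        rows.append(
            {
                "exon": k,
                "genomic_start": exon.genomic[0],
                "genomic_end": exon.genomic[1],
                "protein_start": ps,
                "protein_end": pe,
                "aligned_aa": pe - ps,
                "domains": ";".join(sorted(overlaps)),
                "domain_aa": ";".join(f"{d}:{overlaps[d]}" for d in sorted(overlaps)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "exon", "genomic_start", "genomic_end", "protein_start",
            "protein_end", "aligned_aa", "domains", "domain_aa",
        ],
    )
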