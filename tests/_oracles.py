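"""Independent brute-force oracles used to cross-check the package.

These deliberately share no code with the implementations they check:
the N50 oracle applies the definition literally, the alignment oracles are
plain-Python dynamic programs or exhaustive enumerations over exon chains,
and the coverage oracle scans codons one by one.
"""

from __future__ import annotations

from functools import lru_cache

from genevidence.seqio import revcomp, translate

NEGI = float("-inf")


def brute_n50(lengths) -> int:
    """Largest scaffold length L whose >=L scaffolds hold half the assembly."""
    total = sum(lengths)
    for L in sorted(set(lengths), reverse=True):
        if sum(x for x in lengths if x >= L) >= total / 2:
            return L
    raise AssertionError("unreachable")


def brute_nw_score(a: str, b: str, matrix, gap_open: int, gap_extend: int) -> float:
    """Global affine-gap alignment score by memoized recursion."""

    @lru_cache(maxsize=None)
    def f(i, j, state):
        if i == 0 and j == 0:
            return 0.0 if state == "M" else NEGI
        best = NEGI
        if state == "M":
            if i > 0 and j > 0:
                s = matrix[a[i - 1], b[j - 1]]
                best = max(best, s + max(f(i - 1, j - 1, st) for st in "MDI"))
            return best
        if state == "D":  # gap in b
            if i > 0:
                best = max(f(i - 1, j, "M") + gap_open, f(i - 1, j, "D") + gap_extend)
            return best
        if j > 0:  # I: gap in a
            best = max(f(i, j - 1, "M") + gap_open, f(i, j - 1, "I") + gap_extend)
        return best

    return max(f(len(a), len(b), st) for st in "MDI")


def brute_coverage(reads, cds: str):
    """Per-codon exact-match counts by scanning every codon against every
    read occurrence position directly."""
    cds = cds.upper()
    n_codons = len(cds) // 3
    counts = [0] * n_codons
    for read in reads:
        read = read.upper()
        queries = {read, revcomp(read)}
        for q in queries:
            if len(q) < 3:
                continue
            for s in range(len(cds) - len(q) + 1):
                if cds[s : s + len(q)] != q:
                    continue
                for c in range(n_codons):
                    if s <= 3 * c and 3 * (c + 1) <= s + len(q):
                        counts[c] += 1
    return counts


# ---------------------------------------------------------------------------
# spliced-alignment oracle: exhaustive enumeration of legal exon chains

def _substitution(matrix, aa: str, codon: str):
    if "N" in codon:
        return None
    pep = translate(codon)
    return float(matrix[aa, pep])


def oracle_spliced_score_one_strand(protein: str, dna: str, scheme) -> float:
    """Optimal spliced-alignment score by enumerating every legal exon
    chain (splice sites, protein splits) and scoring each exon with a small
    standalone affine-gap DP.  Exponential; tiny inputs only."""
    m, n = len(protein), len(dna)
    dna_u = dna.upper()
    matrix = scheme.matrix
    go, ge, ip, mi = (
        float(scheme.gap_open),
        float(scheme.gap_extend),
        float(scheme.intron_penalty),
        scheme.min_intron,
    )
    donors = [j for j in range(n - 1) if dna_u[j : j + 2] == scheme.donor]
    acceptors = [j for j in range(2, n + 1) if dna_u[j - 2 : j] == scheme.acceptor]

    @lru_cache(maxsize=None)
    def exon_score(ps, pe, gs, gend, free_left, free_right):
        """All of protein[ps:pe] against dna[gs:gend]; M-bounded; ends fixed
        unless free."""
        L = pe - ps
        width = gend - gs
        if L < 1 or width < 3:
            return NEGI
        M = [[NEGI] * (width + 1) for _ in range(L + 1)]
        D = [[NEGI] * (width + 1) for _ in range(L + 1)]
        I = [[NEGI] * (width + 1) for _ in range(L + 1)]
        for i in range(1, L + 1):
            for j in range(width + 1):
                D[i][j] = max(M[i - 1][j] + go, D[i - 1][j] + ge)
                if j < 3:
                    continue
                codon = dna_u[gs + j - 3 : gs + j]
                s = _substitution(matrix, protein[ps + i - 1], codon)
                if s is not None:
                    cands = [M[i - 1][j - 3], D[i - 1][j - 3], I[i - 1][j - 3]]
                    if i == 1 and (free_left or j == 3):
                        cands.append(0.0)
                    b = max(cands)
                    if b > NEGI:
                        M[i][j] = s + b
                if "N" not in codon:
                    I[i][j] = max(M[i][j - 3] + go, I[i][j - 3] + ge)
        if free_right:
            return max(M[L][j] for j in range(3, width + 1))
        return M[L][width]

    best = 0.0
    for i0 in range(m):
        for i1 in range(i0 + 1, m + 1):

            @lru_cache(maxsize=None)
            def chain(p_lo, g_lo, first):
                res = exon_score(p_lo, i1, g_lo, n, first, True)
                for p_mid in range(p_lo + 1, i1):
                    for d in donors:
                        if d < g_lo + 3:
                            continue
                        s1 = exon_score(p_lo, p_mid, g_lo, d, first, False)
                        if s1 == NEGI:
                            continue
                        for a in acceptors:
                            if a < d + mi or a > n - 3:
                                continue
                            rest = chain(p_mid, a, False)
                            if rest > NEGI:
                                res = max(res, s1 + ip + rest)
                return res

            best = max(best, chain(i0, 0, True))
            chain.cache_clear()
    return best


def oracle_spliced_score(protein: str, dna: str, scheme) -> float:
    """Both-strand oracle score (matches spliced_align's contract)."""
    return max(
        oracle_spliced_score_one_strand(protein, dna, scheme),
        oracle_spliced_score_one_strand(protein, revcomp(dna), scheme),
    )


def local_codon_score(protein: str, dna: str, scheme) -> float:
    """Plain local protein-vs-DNA codon alignment (no introns), mirroring
    the within-exon rules; the intron_penalty -> -inf limit of the DP."""
    m, n = len(protein), len(dna)
    dna_u = dna.upper()
    matrix = scheme.matrix
    go, ge = float(scheme.gap_open), float(scheme.gap_extend)
    M = [[NEGI] * (n + 1) for _ in range(m + 1)]
    D = [[NEGI] * (n + 1) for _ in range(m + 1)]
    I = [[NEGI] * (n + 1) for _ in range(m + 1)]
    best = 0.0
    for i in range(1, m + 1):
        for j in range(n + 1):
            D[i][j] = max(M[i - 1][j] + go, D[i - 1][j] + ge)
            if j < 3:
                continue
            codon = dna_u[j - 3 : j]
            s = _substitution(matrix, protein[i - 1], codon)
            if s is not None:
                prev = max(M[i - 1][j - 3], D[i - 1][j - 3], I[i - 1][j - 3], 0.0)
                M[i][j] = s + prev
                best = max(best, M[i][j])
            if "N" not in codon:
                I[i][j] = max(M[i][j - 3] + go, I[i][j - 3] + ge)
    return best
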