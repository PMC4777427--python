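# Methods

`genevidence` asks one question of a genome: when a gene is absent from the
annotation, is it *missing* (true loss) or *missed* (an assembly or
annotation artifact)?  The package operationalizes the evidence chain used
to answer that question for avian *foxp3*: the gene's conserved
neighborhood, the quality of the assembly in and around the locus, direct
exon recovery by spliced protein-to-genome alignment, protein-level domain
diagnostics, and exact-match transcript-read support.  This note records
the models, the defaults, and the design decisions behind each stage.

## Coordinate and sequence conventions

All intervals are 0-based, half-open; GFF3's 1-based inclusive convention
exists only at the I/O boundary (a single conversion point).  Lowercase
bases are soft-masked repeats — the only repeat representation; any `N` is
an assembly gap, so a hard-masked input is indistinguishable from, and
treated as, gap sequence.  Ambiguity codes other than `N` are rejected:
they do not occur in the data this pipeline emulates, and silently
accepting them would hide upstream errors.  Translation renders stops as
`*` and turns every N-containing codon into `X`, even codons such as
`GCN` whose amino acid is actually determined — coverage and alignment
logic must treat gap-touched codons as unknown.

GC content is computed over unambiguous bases and *includes* soft-masked
(lowercase) sequence.  Whether published GC figures for intergenic regions
count masked bases is usually unstated; including them is the choice here
because repeats are real sequence, and the region-GC acceptance band
(±3 points) is wide enough that the choice is not load-bearing on the
simulated data.

N50 follows the standard definition: the largest scaffold length `L` such
that scaffolds of length ≥ `L` contain at least half the assembly.

## The synthetic neighborhood generator

The generator (`simulate.simulate_neighborhood`) emits one scaffold
holding the five-gene neighborhood in its conserved order and orientation:
`naa10(+), ppp1r3f(−), foxp3(+), ccdc22(−), cacna1f(+)`.  Its defaults are
the study conditions, not free dials:

| parameter | default | rationale |
|---|---|---|
| target protein length | 298 aa | length of the predicted ground tit FoxP3 |
| target exon count | 11 | predicted ground tit exon count |
| target region GC | 0.66 | measured GC of the naa10–cacna1f intergenic region |
| background GC | 0.42 | typical avian genome-wide GC |
| repeat density | 0.25 | mid-range of the masked fractions seen across the surveyed region (7–55%) |
| intergenic spacers | 1,500 bp | compact but large enough for ≥2 kb GC measurement windows |
| introns | GT..AG, 60–240 bp, phase 0 | canonical sites; length well above the aligner's 30 bp floor |

The region between the 3′ end of the upstream flank and the 5′ start of
the downstream flank is driven to the target GC by construction: the
target CDS is back-translated with GC-rich preferred codons when the
region target is ≥ 0.55, its G+C is counted, and the base-composition of
every remaining random base in the region (spacers, introns, inner flank
genes) is solved so the region total lands on target.  Repeat tracts are
lowercased inside the spacers only.

The planted target protein carries the FoxP3 layout N→C: a proline-rich
region (ProR), an optional zinc finger (ZF), a leucine zipper matching
V-x(6)-L-x(6)-L-x(6)-L (the first anchor is configurable to I, the
variant seen in the ground tit and coelacanth), and a forkhead (FRK)
domain whose consensus contains the NLSLH peptide.  ZF/FRK copies are
mutated at 3% per non-anchor residue by default so detection is not a
string search.  The ProR proline count is planted exactly (e.g. 31 P in
123 aa → 25.2%).  The domain exemplars (`domains.ZF_CONSENSUS`,
`FRK_CONSENSUS`, `LZ_EXEMPLAR`) are synthetic stand-ins written for this
package, not any species' real sequence.

**Phase-0 introns.** Introns are placed at codon boundaries in the
simulator, and the aligner's splice model matches.  Real genes split
codons across introns (phases 1 and 2); supporting them would roughly
triple the DP state space without changing what the pipeline demonstrates,
so phases are carried through the data model (every exon records phase 0)
but never non-zero.  This is a known, documented limitation, alongside the
absence of frameshifts.

**Fragmentation.** The paper-scale observation — GC-rich regions assemble
poorly — is emulated by a stylized two-parameter model, not a fitted one
(no quantitative GC→failure model exists to fit): breakpoints arrive at
`base_break_rate` per kb, multiplied by `gc_break_multiplier` in 500 bp
windows above 55% GC.  Each breakpoint becomes an internal N-gap run
(uniform 200–3,000 bp) with probability 0.5, otherwise a scaffold split —
the two failure modes seen in real assemblies (the crow's intra-scaffold
gap vs. single-gene scaffolds).  A gene that loses any exon to a gap or a
split is dropped from the annotation by default (`drop_damaged_genes`),
emulating annotation pipelines' reluctance to annotate broken ORFs;
truncation is available instead.  Because the target region is GC-rich
and the flanks are not, raising the multiplier converts ANNOTATED loci
into the full spectrum of failure states, and the missed-locus rate rises
monotonically — the central claim, in silico.

Reads are drawn uniformly from both strands of the CDS with iid
substitution errors; no technology-specific error profile, no diploidy,
no transposon families.

## Locus classification

`synteny.classify_locus` reduces a genome to one of five mutually
exclusive statuses by a fixed cascade: **ANNOTATED** (target annotated
between the flanks), **SPANNED_UNANNOTATED** (both flanks on one scaffold,
largest intergenic gap run < 20% of the span), **GAP_IN_REGION** (spanned
but gapped at or above that threshold), **FLANKS_SPLIT** (flanks on
different scaffolds, or in a non-tolerated relative orientation),
**FLANK_MISSING** (otherwise).  The 20% gap threshold is configurable; it
is set so a region two-thirds gap (the crow case) is firmly unassessable
while incidental short gaps are not disqualifying.  Fallback flank lists
handle genomes where the canonical flank is absent (hsd17b10 substituting
for naa10).  When a flank is annotated more than once, the nearest pair is
used.  Flanks that sit on the opposing strand in the reference layout
tolerate inversions — observed inversions of such genes do not disturb
the neighborhood — while same-strand flank pairs must preserve their
relative orientation.  Classification is invariant under
reverse-complementing the whole record.

Quality stratification assigns each genome to exactly one of three groups
by the maximum number of distinct neighborhood genes on any one scaffold
(0, 1, ≥2), computed from the genome's own annotations; group means of
coverage, N50 and scaffold count are arithmetic, with coverage rounded to
whole fold for display only.

## Spliced protein-to-genome alignment

The exon finder is a codon-granular dynamic program, local in both
sequences: match/delete/insert states inside exons with affine gaps
(BLOSUM62, open −12, extend −2), and an intron state that may jump from
any codon boundary with a `GT` donor to any downstream `AG` acceptor at
least `min_intron` (30) bases away, for a flat penalty (−10).  Intron
interiors are unconstrained — N runs are free there — but every codon
consumed inside an exon (matched or inserted) must be N-free.  That
asymmetry is what lets a gapped region yield a partial exon chain, as in
the falcon-like scenarios.  Alignments start and end on matched codons;
both strands are scored and the better one returned.

Determinism: scores are scaled by 1024 and each intron costs one extra
scaled unit, so among equal-raw-score alignments the DP prefers fewer
introns (sound while proteins are under 1024 aa, which is enforced);
remaining ties resolve by a fixed transition preference in traceback.
The reported score is the raw (unscaled) optimum, recovered exactly.

Boundary curation against a trusted homolog's exon structure snaps a
junction to a reference protein breakpoint within two codons when the
shifted donor/acceptor still read GT/AG, rescoring only the moved codons
(exact, because junction-adjacent codons are matches); impossible snaps
are flagged, never forced, and coverage never decreases.

The DP is verified against an exhaustive oracle that enumerates every
legal exon chain (all splice-site pairs, all protein splits) and scores
each exon with an independent plain-Python alignment; the two agree on
hundreds of random small instances, and with the intron penalty driven to
−∞ the DP collapses to plain local codon alignment.

## Domain architecture and signatures

The LZ is found by exact anchored-pattern matching ([V|I]-x(6)-L-x(6)-L-
x(6)-L); FRK and ZF are located by local alignment to template consensi
with an identity floor of 0.35 over the template span — low enough that a
family-wide alignable FRK always clears it, high enough that a
genuinely absent ZF does not.  A sequence with no locatable FRK is not
classifiable as FoxP-family and raises.  The N-terminal region runs from
the start to the ZF, or to the LZ when the ZF is absent; its proline
fraction (gaps excluded, X included in the denominator) is the ProR
statistic, reported to one decimal to match conventional precision while
comparisons use unrounded values.

Signature discovery works on a baseline-anchored alignment (every
sequence globally aligned to a designated baseline; columns indexed by
baseline position; insertions relative to the baseline dropped; X runs
and terminal truncations masked as missing data).  A column is a
signature when all ingroup members *with data* agree on a residue that
occurs in no exclusion-set sequence at that column; a strictness knob
allows one mismatch.  Whether "absent elsewhere" should quantify over
paralogues only or over all non-ingroup sequences is genuinely ambiguous
in how such signatures are usually presented; both are expressible by the
choice of exclusion sets, and the tests pin only the relation between the
two readings (paralogue-only exclusion can only enlarge the signature).

## Read support, primers, and the verdict

Read support is exact substring matching of reads (either orientation)
against the predicted CDS; a read covers every codon it fully contains,
and overlapping matches accumulate.  No mismatch tolerance, no spliced
mapping: the evidential point is perfect identity.  In-silico PCR scores
the best ungapped placement of a primer over both orientations as
identity over primer length; a perfect match is translated in the codon
frame implied by its offset (exact for an in-frame CDS template),
exposing the peptide the primer encodes.

The verdict cascade is deterministic and total: ANNOTATED →
PRESENT_ANNOTATED; spanned/gapped region with exon evidence (≥1 exon
overlapping the reference FRK by ≥15 aa, mirroring FRK-spanning falcon
exons) → PRESENT_UNANNOTATED; gapped or split region with conserved
flanks and no exon evidence → LIKELY_MISSED; a clean spanned region with
no exons and no read support (≥30 covered codons would count) →
LIKELY_ABSENT; anything else → INDETERMINATE.  Every verdict cites the
rules that fired.

## Synthetic study stand-ins

`genevidence.scenarios` builds labelled synthetic stand-ins for the
study's genomes and panels: a ground-tit-like genome (clean 66%-GC
region, intact but unannotated 298-aa/11-exon target, I-first LZ, no ZF,
31/123 ProR prolines, reads covering 144 of the 152 codons from mid-LZ to
four codons before the FRK end, with one fixed 8-codon uncovered window),
a crow-like genome (23,713 bp N run inside a 36,546 bp intergenic span,
hsd17b10 as fallback flank), falcon-like genomes whose region is
unassembled except a window holding the last 4 (or 3) exons, a 105-genome
mammal co-annotation panel, a 60-genome avian quality panel whose
per-genome metadata average exactly to the survey's group means, squamate-
like proteins at 10.8% and 8.7% ProR proline, and a forkhead panel with
six planted avian signature columns and five retained mammal-signature
residues (two avian columns fall inside the partial saker-like sequence's
missing segment, exercising the missing-data rules).  Every number above
is planted as a generator *input* and recomputed by the pipeline at run
time; the tests assert the recomputation, which validates the measurement
machinery at study scale but — being planted — says nothing new about the
real genomes.

What the stand-ins do not emulate: real repeat families and their
misassembly modes, annotation pipelines' actual evidence thresholds,
sequencing-technology error structure, polymorphism, and orthology
ambiguity (gene ids are taken as resolved).  Passing tests therefore
demonstrate that the machinery measures what it claims on data with known
truth, not that any particular wild genome will classify the same way.

## Problem sizes

The default test and acceptance runs use: 200 random instances for the
DP-vs-oracle check (proteins 5–7 aa, DNA ≤ 42 nt, ≤ 5 donors/acceptors,
min_intron 8); 50 simulator seeds (550 exons) for boundary recovery; 100
planted proteins (250 domains) for architecture recovery; and a 5-point
multiplier sweep × 100 seeds (500 simulated genomes) for the
monotonicity claim.  These sizes give zero-noise or near-zero-noise
checks for the exact properties and ±5%-scale resolution for the rates,
and the whole suite runs in well under five minutes on one core.
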