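# Methods

## The model organismal problem

Genome assemblies carry mariner-like elements (MLEs) in every state of
decay: complete potentially autonomous copies, internally deleted
derivatives trans-mobilised by a partner transposase (MITEs), copies
truncated by assembly breaks or deletion, and full-length but dead copies
riddled with stops and frameshifts. A homology survey must find all of
them from protein similarity alone, fix their boundaries from structural
signals (TIRs, the TA target-site duplication), classify them into
lineages and families, and read their history from their divergence.
`marinerscan` implements that survey as deterministic, configurable
stages, and pairs it with a generator of synthetic genomes whose ground
truth makes every stage falsifiable.

## Pairwise metric (gap as a fifth state)

All classification identities use a global Needleman–Wunsch alignment
(match +1, mismatch −1, linear gap −2; all configurable) scored as
percent identical columns over *all* columns, a gap counting as a fifth
character state, so a base aligned to a gap is a mismatch. Tie-breaking
in the traceback is fixed (diagonal, then gap in the first sequence) and
the argument pair is aligned in canonical lexicographic order so identity
is exactly symmetric. The forward pass is numpy-vectorised per row (the
in-row dependency of a linear gap collapses to a running maximum), which
keeps 2–3 kb pairs at tens of milliseconds without sacrificing the exact,
reproducible tie-breaks that the oracle-equivalence tests require.

A consequence of this metric worth stating plainly: the identity between
an internally deleted copy and its parent is approximately the retained
fraction of the parent. Unrelated full-length elements align at ~50 %
under this scheme, so only derivatives retaining more than roughly 60 %
of the parent can gather with it before unrelated elements join. The
default simulated MITEs delete ~420 bp of a ~1.5 kb element (retaining
~73 %), matching the larger MITE classes seen in real surveys; much
shorter MITEs are still generated and analysed (breakpoints,
microhomology, sublineages) — they are simply not expected to join their
parent's group under the global metric, and the package does not claim
otherwise.

## UPGM-VM

The ascending classification starts from single-sequence nodes and
repeatedly merges the pair of nodes whose consensuses have the highest
gap-as-fifth-state identity (ties to the lexicographically smallest id
pair). There is no arithmetic averaging of distances: after each merge
the node is represented by the relative-majority consensus of the fused
multiple alignment (per column the most frequent of {A,C,G,T,−}; ties
among bases emit the IUPAC code; a strict gap majority drops the column
from the consensus string while staying in the profile), and all
identities involving the node are recomputed by re-aligning consensuses —
the metric therefore varies as the classification ascends. The fusion of
two nodes' alignments walks the pairwise alignment of their consensuses;
columns dropped from a consensus (gap-majority) are carried along
attached to the preceding retained column. Merge heights are 1 − identity
/ 100 and are not guaranteed monotone, which is inherent to a varying
metric. An independent plain-python reimplementation of these definitions
(tests/upgmvm_oracle.py) must reproduce the merge order exactly on random
inputs; this is enforced in the test suite and re-measured by the
acceptance script.

## Mining

The translated search seeds exact 4-mer amino-acid matches between the
query panel and each of the six frame translations, chains seeds within a
16-diagonal band, requires two seeds and an x-drop ungapped extension
score ≥30 (BLOSUM62), and refines each surviving group by local alignment
(gap open/extend −11/−1). Hits need ≥35 % identity over ≥80 aligned
columns. Hits within 1 kb merge into a locus, extracted with 5 kb flanks
(clipped at scaffold ends, which raises the `at_scaffold_end` flag).
Retention filters: elements <250 bp are discarded (strict less-than),
truncated copies at scaffold ends are discarded, and candidates whose
protein scores clearly higher (margin 20) against DDxE references than
against the DDxD panel are excluded as Tc1-like. Because MITEs have no
transposase homology, the pipeline then runs a nucleotide recovery round:
each distinct complete element is re-searched against the genome
(per-scaffold 12-mer index, edlib infix alignment, identity computed from
the CIGAR), and new loci are annotated identically.

## Boundaries

TIR detection scans a window of 800 bp outside plus 150 bp (600 bp for
nucleotide-recovered loci, whose core spans the whole element) inside
each edge of the homology core, computing for every diagonal the
maximal-scoring ungapped run between the left window and the reverse
complement of the right window (match +1 / mismatch −1). Candidate runs
are edge-trimmed until their terminal windows are near-perfect (last 3
columns matching, ≥7 of the last 8), then must satisfy arm length ≥10,
arm identity ≥80 % and score ≥15; candidates are tried best-first. The
score floor suppresses the ~13 chance reverse-complement runs per locus
expected at the 10 bp/80 % floor while keeping every perfect arm ≥15 bp
detectable. Because the TA duplication extends an inverted repeat
(TA + arm ... rc(arm) + TA), boundaries are TSD-aware: the smallest
symmetric trim that exposes TA immediately outside both arms is applied.
TSD calls are yes/no/indeterminate (indeterminate when a flank is clipped
or contains N). Arm structure reports palindromes (arm equals its own
reverse complement) and mirror repeats (maximal substrings ≥8 equal to
their plain reversal, found by centre expansion).

## Transposase annotation

ORF search prefers a proper ORF (M..stop) spanning ≥60 % of the inter-TIR
region; failing that, an interrupted reading from the first start codon
(its internal stops mark dead copies); failing that, two compatible
stop-free stretches in different frames (frameshift evidence). When a
reference panel is supplied, competing readings are ranked by homology to
it rather than raw length — back-translated coding sequence is codon
biased enough that spurious stop-free readings arise on the opposite
strand. The catalytic triad is projected from the best-scoring annotated
reference through a free-end-gap global alignment; the label is
`DD{n}{D|E}` with n the residues strictly between the 2nd and 3rd
catalytic positions (the inclusive convention would shift labels by two
and can be adopted by relabelling references). Domain annotation is
deliberately transparent: fuzzy WVPHEL/YSPDLA scans (≤2 mismatches), a
22-residue HTH window score (key hydrophobic positions, an obligatory
turn glycine, basic-residue bonus, threshold 8), a classic NLS scan (≥4
basics in a 6-mer, or bipartite), and AATAAA scans in the UTRs. Accuracy
claims for these heuristics are limited to the synthetic constructs.

Completeness: truncated (≤1 TIR); deleted (two TIRs and a partner
breakpoint, see below); complete (two TIRs, intact spanning ORF, and full
length relative to the lineage's complete length when one is known);
dead (full-length but interrupted). `potentially_active` additionally
requires a resolved triad and an HTH.

## MITEs and breakpoints

Deleted status is decided by evidence, not length alone: each copy is
aligned (global, match 2 / mismatch −2 / open −12 / extend −0.05) against
the complete elements of other lineages; big partner-side gaps split by
short chance islands (≤15 bp) are merged; the largest internal gap ≥50 bp
is the main deletion, provided identity outside it is ≥75 %. Edges are
left-normalised, then refined independently by edit-distance of the
MITE's junction contexts against the partner (±6 bp), which absorbs the
breakpoint shifts that substitutions and indels near the junction induce.
Microhomology windows run rightward from each edge (under left
normalisation one repeat copy starts the deleted region and its twin
survives just after the junction); the longest direct repeat ≥3 bp with
one copy starting within 10 bp of each edge wins, ties to smaller total
offset. Offsets (0,0) are BPEE, both positive BPNN, mixed BPEN/BPNE
(reported although rarely observed in nature); equal non-zero offsets are
re-anchored to BPEE because they are precisely the signature of a
normalisation shift. Sublineages group MITEs sharing a partner, deletion
edges within ±10 bp and TIR arms ≥90 % identical over their common
prefix; single-member groups are reported but flagged non-MITE (no
evidence of transposition).

## Evolution screen

Sublineage age derives from the relative-majority consensus of a
progressive multiple alignment of the members: each copy is re-aligned to
the consensus and the mean identity is binned (≥97 recent, [95,97)
intermediate, [85,95) ancient, <85 relic — half-open, total, the
intermediate bin closing the gap the two-ended description leaves open).
Cross-genome screening retains local nucleotide hits with identity >60 %
over >65 % of the query (identity over alignment columns; coverage =
aligned query bases / query length); horizontal-transfer candidates need
identity >90 %, coverage >90 % and distinct species.

## The synthetic genomes

Background is i.i.d. uniform A/C/G/T (GC bias configurable) — a null that
cannot contain TIR-like structure at the lengths used. Elements are
assembled as TIR + UTR5 + back-translated ORF (+stop) + UTR3 + rc(TIR),
with fixed most-frequent-codon back-translation, seeded UTRs carrying an
AATAAA signal and an in-frame stop cassette at the UTR5 tail (so the
annotated ORF begins at the real start codon). Synthetic transposases
follow a fixed domain layout (NLS at 21, HTH at 87–108, WVPHEL at 119,
YSPDLA at 151, D1 at 171, triad spacing per family); filler residues
exclude D/E, G/P and R so that triad, HTH and NLS detectability are
controlled by design. Lineages derive from family archetypes with ~25 %
filler substitution — coherent at family level, distinct below the 75 %
nucleotide threshold.

Four lineage designs define the default study conditions (two DD34D
mariner-like designs with 28/30 bp TIRs, one of them carrying the mirror
motif CAATAAAATAAC; a rosa-like DD41D with a 32 bp TIR; a long-TIR DD40D
with a seeded 460 bp arm), planted as 30 copies on 5 × 200 kb scaffolds:
16 complete (some on the minus strand), 10 MITEs in three
breakpoint-sharing groups (BPEE, BPNN, repeat-free), 4 left-truncated.
Copy divergence defaults to 3 % substitutions with 0.2 % indels (1–3 bp,
geometric lengths), indels suppressed in the TIR arms. Copies planted as
*complete* evolve under a purifying-selection mode: no indels inside the
ORF, substitutions that would create a stop are discarded, triad codons
untouched — diverged but functional copies, without which "complete" is
not a recoverable truth label at these rates. All other copies mutate
neutrally. Microhomology planting rewrites the two breakpoint windows
(22 bp each) with rejection sampling until (i) the windows share no
3-mer except the planted repeat, (ii) the classifier-style scan returns
exactly the planted repeat at the planted offsets, and (iii) the parent
ORF stays stop-free (windows sit inside the coding sequence). The truth
set records both TSD-exclusive and TSD-inclusive coordinates, since
published length figures do not state which convention they count.

What the simulator does not emulate — nested insertions, segmental
duplications, low-complexity and repeat-rich background, sequencing and
assembly artefacts beyond N runs, population polymorphism, and real
phylogenetic structure within a family — bounds what passing tests show:
they validate the algorithms' contracts and their behaviour under
divergence, not performance on real assemblies.

## Problem sizes and determinism

Default validation sizes: the 5 × 200 kb study genome (30 copies), the
60-copy microhomology benchmark, 20 oracle trials of ≤6 sequences of
40–70 bp. A full study-genome pipeline run takes ~30 s on one core;
the whole test suite a few minutes. Every stage is deterministic given
its inputs and seed: seeded generators are keyed by (purpose, seed,
index), sorted iteration orders throughout, and all alignment tie-breaks
fixed. Known limitations: triad projection requires a homologous
reference in the panel; the HTH/NLS heuristics are calibrated on the
synthetic constructs only; boundary recovery at high divergence is
accurate to a few bases, not exact; and UPGM-VM is quadratic in copy
number, appropriate for catalogs of hundreds, not tens of thousands.
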