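# Methods

This note documents the models, conventions and numerical choices behind
`mitocomp`, in the order the pipeline uses them.

## Coordinates and the annotation model

All coordinates are 1-based inclusive on a circular genome, matching how
mitogenome papers print locations; BED export converts to 0-based
half-open at the I/O boundary only.  A feature with end < start wraps
the origin; its length is (L − start + 1) + end.  The intergenic spacer
after feature *i* is start(i+1) − end(i) − 1, so abutting genes score 0
and overlaps are negative; the spacer after the last feature wraps to
the first.  Genome length defaults to the maximum end coordinate; when a
sequence is supplied its length wins and a mismatch is a validation
issue.

The validator re-derives every printed size and spacer from the
coordinates.  On the packaged *Perisesarma bidens* summary this flags
exactly one anomaly: the nad4 row (location 6742–8073 vs printed size
1350; the 41 bp spacer printed after nad5 implies nad4 starts at 6724).
The fixture stores the row as printed and the validator reports both
inconsistent readings; the package takes no position on which value is
the sequencing truth.  Class-count checking (13/22/2/1) applies only to
annotations that look complete — those containing a control region —
so partial tables validate cleanly.  Same-strand PCG overlaps are
informational notes: the 7 bp atp8/atp6 overlap is canonical biology.

Dash handling is deliberately permissive: hyphen, en/em dash and Unicode
minus are interchangeable in locations and negative spacers, and a bare
dash means "not declared", because published tables mix all of these.

## Composition and skews

AT skew = (A − T)/(A + T) and GC skew = (G − C)/(G + C), computed on
counts.  Genome-level statistics use the deposited (majority) strand —
the convention under which crab mitogenomes report slightly negative AT
skew — while per-feature statistics use the annotated strand.
Ambiguity codes are excluded from denominators rather than fractionally
allocated.  Reports round percentages to 2 decimals and skews to 3;
full precision is retained internally (the printed −0.021 corresponds
to −0.021254 at full precision from the printed percentages).  Skews of
sequences lacking the relevant bases are NaN, reported as null.

## Codon usage

Translation table 5 (invertebrate mitochondrial) throughout,
configurable only by editing the module constant — the package targets
arthropod mitogenomes.  Sequences whose length is not a multiple of 3
contribute ⌊len/3⌋ codons; the trailing T/TA is the incomplete stop
completed by polyadenylation in vivo, and it is trimmed and counted,
never imputed as a codon.  Start codons are not special-cased in
counting.  Stop codons are excluded from RSCU families and reported
separately.  RSCU is computed within the split families (Leu1 = CUN,
Leu2 = UUR, Ser1 = AGN, Ser2 = UCN, so AGA/AGG sit in Ser1 under this
code), which is how mitogenome papers plot it; sums over an observed
family therefore equal the family size exactly.  Unobserved families
carry RSCU 0 and an explicit flag.

## tRNA cloverleaf heuristic

This is an arm detector, not an energy minimizer: the claim it supports
is qualitative (cloverleaf vs DHU-arm-missing), so a thermodynamic
folder would be out of proportion.  The search is deterministic and
exhaustive over a constrained assignment space:

- acceptor stem: the 5' 7-mer paired against the 3' end, trying 0–2
  unpaired 3' overhang nucleotides; accepted at ≥5 of 7 positions paired
  (G·U allowed);
- anticodon arm: 4–5 bp stem with exactly a 7 nt loop; the anticodon is
  the central triplet;
- DHU arm: 3–4 bp stem, 4–12 nt loop, starting within 3 nt of the
  acceptor stem;
- T arm: 3–5 bp stem, 3–9 nt loop, ending within 1 nt of the 3'
  acceptor strand.

The two positional constraints encode real cloverleaf geometry (short
acceptor–DHU connector, T loop hard against the acceptor); without them
AT-rich sequence offers enough accidental pairings that alternative
assignments can tie the planted one.  Scoring: Watson–Crick pair 1.0,
G·U wobble 0.5; a stem candidate is accepted only if every position
pairs and at least two pairs are canonical.  Ties break deterministically
(total score, number of arms found, acceptor score, 5'-most DHU, then
5'-most anticodon/T placement), so identical input always yields an
identical report.  All bounds and weights live in `CloverleafConfig`.

## Gene orders, breakpoints, diffs

Orders are circular lists of signed labels on the majority strand; the
control region participates as an unsigned element because the
rearrangements of interest are described relative to it.  Identity is
rotation-only — no reflection, no global strand flip — matching how
mitogenome figures present orders; orientation is part of identity.
Breakpoint distance counts ordered, oriented adjacencies of one order
absent from the other; it is symmetric and zero exactly on identical
orders.

The diff reports displaced genes via a healed-slot criterion: a gene is
displaced when its two neighbors in the source order are directly
adjacent in the target (the signature of a clean excision).  Displaced
genes contiguous in the source merge into regions classified as
translocation (single gene, with source and destination junctions),
swap (block reappears reversed in place), or rearrangement.  Genes
caught in changes without a healed slot remain visible through the
breakpoint set rather than being forced into a region — minimality of
such descriptions is not well defined in general, and the healed-slot
rule reproduces the field's verbal descriptions of the sesarmid case
({trnH} moved; {trnI, trnQ} swapped) without search.

## The TDRL model

A tandem duplication–random loss event duplicates a contiguous circular
block immediately after itself and deletes one copy of each duplicated
gene; the survivors, read in position, reorder the block.  Orientations
are carried unchanged (TDRL never inverts — both rearrangements modeled
here preserve orientation), and the control region may sit inside a
block.  "Random loss" is enumeration, not sampling: every (start,
interval length ≤ cap, keep mask) triple is generated in a fixed order
(start, then length, then the mask read as a binary number with the
first gene as the most significant bit and "keep second copy" = 1).
The default interval cap of 6 bounds the 2^k mask space and comfortably
covers the 3-gene events relevant here; it is a parameter everywhere.
`minimal_tdrl` orders by (length, start, mask) instead and returns the
first hit.  Note the minimal scenario need not be the historical one:
the trnI/trnQ swap is reachable by duplicating just the pair, while the
published account duplicates all of trnI-trnQ-trnM; enumeration reports
both and privileges neither.

## The synthetic generator

The generator's job is closure: produce genomes whose planted parameters
the analysis modules recover exactly or within sampling error.  Defaults
are the published *P. bidens* regime — base weights from the printed
composition (A .3661, T .3820, C .1513, G .1006), per-gene lengths and
junction spacers from the packaged summary (using the coordinate-derived
nad4 length of 1332 bp, so the layout reproduces the published
coordinates and the 15,641 bp total exactly), the sesarmid gene order as
template, tRNAs of 65–73 nt with trnS1 built DHU-less, and cob ending on
an incomplete stop (1135 = 3·378 + 1).

PCGs are sampled codon-wise: an amino-acid family first (weights below),
then a codon within the family with probability proportional to the
product of base weights over its three positions raised to an exponent
of 2.25 — the strong A/T third-position bias of these genomes.
Minority-strand genes are written as reverse complements, which is what
generates realistic strand skews on the deposited strand.

Two default parameter sets were calibrated once, analytically plus a
measurement loop over seeds, and then frozen: (i) the family weights,
a realistic brachyuran usage profile constrained to keep the empirical
ranking (Leu2 > Ile > Phe …, Cys least) with margins of a few counts'
standard deviations; and (ii) the background base distribution used for
rRNA/CR/spacer positions.  The second exists because the genetic code
caps how CG-skewed a coding strand can be; in real mitogenomes the
non-coding and rRNA regions carry strong strand asymmetry, and here they
absorb the C/G remainder so that whole-genome composition lands on the
target weights (verified unbiased over 60 seeds; worst per-base
deviation 1.2 percentage points, i.e. binomial scale at n ≈ 15,600).
At ~3,700 codons per genome the Leu2/Ile and Ile/Phe margins are about
two binomial standard deviations, so the exact ranking can flip in a few
percent of seeds; expectation-level recovery is what the generator
guarantees, and ranking tests pin specific seeds.

tRNA construction writes each stem's 3' strand as the reverse complement
of its sampled 5' strand, so planted pairs are all Watson–Crick; the
DHU-less variant replaces the whole acceptor-to-anticodon segment with
an unpairable C-run and draws the anticodon stem's 5' strand from {A, C}
so that no complementary partner for a spurious DHU stem exists within
the detector's search window.  Because raw random draws occasionally
admit an equal-scoring alternative fold, the generator folds each
candidate and redraws until the detector reproduces the planted
classification and anticodon (~1% rejection) — "noise-free construct"
is thus a guarantee, not an expectation.  Where the published layout
makes genes overlap, the later feature owns the shared bases and tRNAs
are written last, so planted tRNA structures are never corrupted; the
few affected PCG tails may lose their stop codon, which the codon
module tolerates by design.

All randomness flows through one `random.Random(seed)` stream (pure
Python integer arithmetic), making output byte-identical across
platforms; the committed fixture pair `synthetic_mitogenome_seed42.*`
is asserted equal to regeneration in the test suite.

What the generator does *not* emulate: substitution/indel evolution,
phylogenetically correlated multi-taxon data, secondary structure of
rRNAs, base modification, or any within-gene selection beyond codon
frequencies.  Tests passing on synthetic data therefore demonstrate the
*algorithms* (coordinate arithmetic, counting, enumeration, detection
thresholds) on realistic-scale input, not biological inference on real
sequence.

## Problem sizes in the test suite

The TDRL enumerator is checked against an independently coded
brute-force oracle exhaustively for unsigned orders of length 3–4 (all
targets) and on seeded signed samples at lengths 5–6; the planted-event
recovery property runs 200 seeded histories on the full 38-gene order.
These sizes keep the whole suite under a minute while covering the
combinatorics the published scenarios need (3-gene intervals on a
38-element circle).
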