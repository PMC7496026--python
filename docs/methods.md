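# Methods

This note documents the models, conventions and numerical choices
behind `promdiv`, in the order the pipeline applies them.

## Coordinates and windows

All coordinates are 0-based, half-open. A TSS position is the index
of the +1 base ("position 0" in promoter notation); a window with
`upstream` and `downstream` flanks has length `upstream + 1 +
downstream` and holds the TSS base at index `upstream`. Minus-strand
windows are the reverse complement of the plus-strand slice, so index
arithmetic is identical for both strands. Windows that would cross a
chromosome edge are dropped, not padded. The analysis window is 601 nt
(±300); the logo window is 40 nt (−34 … +5); both are configurable.
The initiator check requires a pyrimidine at −1 and a purine at 0; an
N at either position fails (conservative choice for assembly gaps).

Genomes carry two layers: unmasked (upper-cased) and masked
(soft-masked bases hardened to N). Candidate search operates against
the masked layer so G+C-rich repeats such as Alu do not seed spurious
hits; the final window is excised from the unmasked layer.

## CpG statistics and classification

G+C content is (n_C + n_G)/N; the CpG score is the Gardiner-Garden &
Frommer observed/expected ratio n_CpG · N/(n_C · n_G), defined as 0
when the denominator vanishes. N bases are excluded from the counts
but not from N itself; windows containing N are normally rejected
upstream, so this only guards synthetic edge cases. Thresholds are
**inclusive**: island ⇔ gc ≥ 0.5 and score ≥ 0.6. Inclusive and
exclusive conventions differ only on a measure-zero boundary for real
data; tests pin the convention. Dinucleotides are always counted with
overlap on the ungapped sequence, in every module, so promoter scoring
and divergence spectra agree on what a CpG is.

## PSL hit selection and anchoring

Hit identity is matches ÷ target span. The denominator is a design
choice (query span or block-only spans are defensible alternatives);
target span was chosen because the target is the genome being searched
and the fixed-length extension happens there. Hits need identity
≥ 0.90 over a span ≥ 200 bp; among passing hits the largest target
span wins (ties broken by match count). The human TSS offset is
mapped through the hit's block structure (with the PSL
reversed-query convention for minus-strand hits); a TSS falling
between blocks rejects the candidate as `unmapped`, a mapped
dinucleotide failing the YR check as `no-YR`, and a window that cannot
be extended to full length or contains N as `gap`. Rejections are
values, not errors, and are counted in the stage log.

## Pairwise alignment

Alignment is global with affine gaps: match +1, mismatch −1, gap open
10, gap extension 0.2 per additional base (a gap of length L costs
10 + 0.2·(L−1)). The extension penalty echoes the one classical
parameter commonly quoted for promoter-scale alignment; the other
values are conventional and configurable. N scores as a mismatch
against everything, including N. The dynamic program is Biopython's
`PairwiseAligner`; the first alignment in its canonical enumeration
order is taken, which makes output deterministic for fixed inputs.
Optimality is cross-checked in the tests against an exhaustive
enumeration of all gapped alignments at small lengths — a deliberately
independent second route.

The "alignment score" used for filtering is 100 × match columns ÷
min(ungapped length A, ungapped length B), the pairwise percent-
identity convention. Pairs below 90 are excluded from the divergence
spectra; the indel stage relaxes the cutoff to 80 because indels
themselves depress the score. Both stages also require the two YR
bases to be identical across species at the anchored columns.

## Divergence spectra

For a chosen source row, every overlapping dinucleotide of the
ungapped source is compared with its aligned counterpart; it is
altered when either counterpart base differs, is a gap or N, or when
inserted counterpart bases fall between the two source positions.
Rates are pooled over all alignments of a group (not averaged
per pair), and groups follow source species × counterpart island
status. Background rates from pre-aligned (axt) pairs are computed by
the same code with no special-casing.

Source CpGs are further classified by fate: CpG (conserved), TpG and
CpA (the two deamination products), other, or gap-containing. The
deamination enrichment between two groups is the ratio of their
per-CpG TpG+CpA frequencies; a conserved group with zero transitions
yields an `inf` sentinel rather than an error.

The CpG transition multiplier is recovered per site, not per
dinucleotide: conditioning on a CpG in the source row means the source
branch did not mutate there, so the mismatch rate over source
CpG-context bases estimates (multiplier × rate) for the counterpart
branch alone, while the background mismatch rate sees both branches
and is converted to a per-branch rate via 1 − √(1 − p). Source TpG/CpA
positions are excluded from the background because their counterparts
carry ancestral CpGs at an elevated rate. A dinucleotide-level ratio
of spectrum rows would be biased low by exactly that contamination,
which is why the estimator does not reuse the heat-map rates. A
residual upward bias remains from CpGs newly created by background
substitutions (whose counterpart mismatches with probability ≈ 1); it
is small at multiplier ≈ 10 and grows relatively as the multiplier
approaches 1, which the tests respect by probing recovery at the
default multiplier.

## Indels

Each maximal gap run in either row is one site; runs separated by at
least one non-gap column are distinct (no merging — merged events
cannot be distinguished from two events without outgroups). Flank
conservation is measured on the 10 alignment columns each side, gap
columns counting as mismatches; sites are kept when both flanks show
≥ 8 matches and neither flank is truncated by the alignment edge. The
8/10 rule is the default; a stricter 9/10 ("90% similarity") reading
also circulates for this filter, and the threshold is configurable.

The CpG delta of a site is the CpG count of the carrier row minus that
of the counterpart row over the gap-run columns extended by one column
each side (ungapped), the minimal window that captures
junction-spanning CpGs; wider junction windows are configurable.
Because gap placement inside a repeat run is alignment-ambiguous,
detected and ground-truth indels are compared after left-normalization
(the standard variant left-alignment: shift left while the base
entering the window equals the base leaving it).

Polarity uses single-event parsimony on the fixed primate topology
((((human, chimpanzee), gorilla), (macaque, baboon)), marmoset): a
branch explains the pattern when its descendant species (restricted to
those with known state) carry one state and all others the opposite.
If all such placements imply the same event type it is returned with
the smallest implicated clade; patterns needing two events, or split
at the root (where insertion-on-one-side and deletion-on-the-other tie),
are `ambiguous` rather than guessed.

## Dot plots and repeat association

A dot marks an exact match of 5-bp windows (stride 1); windows
containing N never match. Reverse-complement orientation compares a
window of A against the reverse complement of B's window. Repeat
association of an indel is an automated operationalization of what is
classically a visual call: the carrier region spanning the indel ± 25
bp is self-plotted, and the site is tandem-associated when an
off-diagonal dot's window intersects the indel interval (inverted:
same rule on the reverse-complement plot). Window size and
neighbourhood are configurable; the rule is documented as an
interpretation, since no quantitative criterion for the visual call
exists.

## Motif matrices and TATAAA scan

Position frequencies are computed over non-N observations per column;
information content is 2 − H bits with no small-sample correction
(matrices, not rendered logos, are the contract). The TATAAA scan
counts the 5′-end positions of exact TATAAA matches lying wholly
within the 40 bp upstream of the TSS (a match ending at −1 is the last
admissible), counting overlapping occurrences separately. The logo
window is 34 nt upstream + TSS + 5 nt downstream; a 35-nt-upstream
variant of the same window circulates, and both flanks are parameters.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
with complete ground truth:

* **Ancestors.** 601-nt sequences from a first-order Markov chain
  whose C→G transition is down-weighted to hit a target CpG
  observed/expected ratio, rejection-sampled until G+C and CpG score
  fall within ±0.05 of the class targets — island: G+C 0.60, score
  0.80; non-island: G+C 0.42, score 0.25, matching where the two
  promoter classes cluster in the (G+C, score) plane. A central YR
  dinucleotide is enforced.
* **Substitutions** (per branch, default rate 0.01/site — promoter
  pairs that survive the score-90 filter are a conserved subset of a
  genome pair diverging by several percent). CpG-context cytosines
  mutate to T (and guanines to A) at multiplier × rate, default
  multiplier 10, emulating deamination of methylated CpG; all other
  sites mutate uniformly. Contexts are read from the ancestor, i.e.
  substitutions are applied simultaneously.
* **Indels.** Slippage events extend or shorten a homopolymer run
  (≥ 3 bases) by one base; tandem events duplicate or delete a 5–10-nt
  unit adjacent to an existing copy, or a pool motif (default TCGGC,
  the canonical CpG-containing expansion unit). Event anchors keep
  ≥ 15 nt from the sequence ends and ≥ 30 nt from each other and the
  centre, so planted flanks are intact by construction. Default
  expectations are 0.1 slippage and 0.05 tandem events per branch.
* **Ground truth.** Every event is logged with ancestor and derived
  coordinates; replaying the log reproduces the derived sequence
  exactly, and the truth bundle records ancestral class, per-species
  classification and pair group.
* **Protected centre.** The central YR is exempt from mutation by
  default so the YR-match filter does not confound recovery tests;
  `protect_center=False` lifts the exemption to test filter attrition
  itself.

What the generator does **not** model: context-dependent substitution
beyond the CpG multiplier, selection, rate heterogeneity along the
window, hypomethylation of islands (the multiplier applies uniformly;
an unmethylated-island condition is simulated by setting the
multiplier to 1), transposon insertion, and large structural events.
Passing tests therefore demonstrate that the pipeline measures what
the generator planted — rates, fates, indel sets — not that real
promoters evolve by exactly this process.

## Problem sizes and determinism

The test suite and the acceptance script regenerate all inputs from
seeds at run time; cohort sizes are 500 pairs for the recovery and
spectrum checks, 1000 windows for the TATAAA scan, and 200/100 trials
for the brute-force oracle comparisons, sizes at which the stochastic
assertions are stable across seeds. Fixed seed implies byte-identical
report bundles; all randomness flows through `numpy.random.Generator`
seeded from the configuration.

## Known limitations

* Repeat association is exact-match only; diverged repeat copies are
  not detected (no mismatch-tolerant windows).
* The multiplier estimator assumes a single uniform background rate;
  under strong rate heterogeneity it recovers an average.
* Indel polarity needs at least three species including an outgroup
  and declines to guess at root ties.
* Maximum detectable indel length is bounded by the alignment-score
  filters, not by the detector.
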