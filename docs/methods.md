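# Methods

## Scope and design

`prequant` implements the quantitative, computable side of a
PRE-reporter study: motif scanning and pair-density scoring of
candidate PRE sequences, in-silico reconstruction of a
deletion/mutagenesis construct series from primer sequences, the
derived reporter statistics of the eye-pigment assay, and a synthetic
generator that emulates the assay's data-generating process. Wet-lab
steps (ΦC31 injection, crosses, pigment extraction) and genome-scale
motif census are out of scope.

All internal coordinates are 0-based half-open on the plus strand;
conversion to 1-based inclusive happens only in the GFF3 writer.
Sequences are normalized to uppercase {A,C,G,T,N}; `N` is accepted in
input but matches no motif symbol, so masked regions can never produce
hits.

## Motif model and pair-density score

Motifs are IUPAC consensi matched position-by-position on both strands;
overlapping matches are all reported, and minus-strand matches are
given in plus-strand coordinates with a strand flag and the
motif-strand matched text. The default set is GAF/PSQ = `GAGAG`,
PHO/PHOL = `GCCAT`, GTGT = `GTGTG` and ZESTE = `YGAGYG`; the GTGT and
ZESTE consensi are configurable because their exact published forms
vary (`GTGT` versus `GTGTG`; several ZESTE consensus variants are in
circulation), and the ZESTE default here follows common usage rather
than any single source.

Tandem occurrences of a short motif are biologically one "repeat
tract", so overlapping or bookended same-motif hits are merged into
repeat blocks (an interval union, carrying the number of underlying
hits). Construct anatomy — e.g. "four GTGT repeats" — is counted in
blocks, not raw k-mer matches.

The PRE score of a window is the weighted number of unordered motif-hit
pairs lying wholly inside the window whose start-to-start distance is
at most the pairing distance; same-type pairs count once per unordered
pair. Defaults: window 500 bp, step 100 bp, pairing distance 220 bp,
unit weights for every pair. The pairing distance is set at the scale
of minimal PRE core fragments (~220 bp); all four values are
configuration, not constants, because pair-scoring approaches differ in
their trained parameters and this package deliberately does not retrain
them. A sequence shorter than one window yields a single whole-sequence
window. The highest-scoring region is the argmax window, ties broken
leftmost; an all-zero track returns the leftmost window with an
`all_zero` flag rather than pretending a peak exists.

## Construct reconstruction

Cloning primers are split into a 5' tail and a 3' annealing portion by
searching an enzyme catalog (NotI/XbaI/SpeI recognition sites taken
from Biopython's restriction tables) within the first 16 bases: the
tail ends at the end of the first recognition-site occurrence found
there. Annealing portions shorter than 10 nt are rejected. In-silico
PCR requires exactly one exact occurrence of the forward annealing
sequence and one of the reverse-complemented reverse annealing
sequence, in amplifiable orientation; the product is
tail + genomic segment + reverse-complemented reverse tail. Exact
matching only: the packaged primers are all exact, and mismatch
tolerance would add ambiguity with no benefit.

QuikChange deletion products are reconstructed from the forward
mutagenesis primer (pairs must be exact mutual reverse complements,
which is validated first). Every split of the primer into left/right
halves of at least 10 nt is tried against the template; each valid
(left at i, right at j ≥ i + |left|) placement implies the deletion
template[i+|left| : j). When the junction flanks end inside a repeat,
several splits describe the same molecule; candidates are therefore
deduplicated **by product sequence**. A single distinct product is
accepted (coordinates reported from the leftmost candidate, a
deterministic convention); genuinely different products raise an
ambiguity error listing all candidates; no candidate raises "junction
not found". A junction already present in the template yields a
zero-length deletion flagged as a no-op, which makes the operation
idempotent.

Motif-loss accounting compares repeat blocks before and after an edit.
Blocks are matched in two passes — first by motif plus block text with
8 bp of flanking context, then (for blocks whose context was changed,
e.g. those now abutting the deletion junction) by motif plus block text
alone. Only genuinely unmatched blocks are reported lost or gained.

## The packaged 106 bp surrogate

The essential ~106 bp region at the 5' end of the 1.6 kb vestigial
(vg) PRE is published only as a figure image, not as machine-readable
sequence. The package therefore ships a **synthetic surrogate**
(`vg_pre_106bp_synthetic.fa`, and a 156 bp extension with downstream
primer context) constructed to satisfy every sequence constraint the
printed primers impose: it embeds the annealing/flank sequences of the
cloning and mutagenesis primers, reproduces the region's annotated
anatomy — exactly one GAGAG block and four GTGT repeat blocks in
106 bp — and supports the full mutagenesis series: each deletion
primer pair finds a unique junction on it and removes the annotated
motif blocks. Notably, the primer sequences themselves imply that the
1st-4th GT deletion was built on the 1st-3rd deletion product (its
junction does not exist on the wild-type sequence), and the surrogate
preserves that property. The record id and description mark it as
synthetic; coordinates on it are not genomic coordinates.

## Reporter statistics

Replicates are summarized per (construct, site, zygosity, background)
by arithmetic mean and sample SD (n−1 denominator — biological
replicates); single-replicate groups are flagged and given SD 0. All
ratios are computed from group means, matching how the assay's derived
indices are defined, with replicate variation propagated as first-order
delta-method standard errors labelled approximate:
`Var(x̄/ȳ) ≈ (x̄/ȳ)² (sx²/(nx x̄²) + sy²/(ny ȳ²))`.

Denominators are floored at 0.1 % of wild-type pigment (configurable).
Strong PREs can silence homozygotes to phenotypically white eyes, so a
zero or near-zero denominator is a real outcome; the floor keeps the
statistic finite and the `censored` flag keeps it honest. Ratios are
unit-free and invariant under rescaling all pigment values (verified by
property test). PSA is reported as (hom/het)/2 so that the pure
copy-number null equals 1 exactly; the direction follows the
pairing-activation reading (homozygotes exceeding the twofold dosage
expectation). No hypothesis testing is attached to these ratios — the
assay's standard analysis reports them descriptively — so none is
implemented.

## Generative model

Pigment for construct c at site i, zygosity z, background b:

    baseline · site_effect_i
      · copy_number_factor^[z=hom] · pairing_activation_i^[z=hom]
      · repression_factor(c,i,z)
      · pc_relief_c^[b=Pc_mutant ∧ z=hom]
      · exp(ε),   ε ~ N(0, σ²),

capped at `saturation_cap`. Noise is multiplicative log-normal because
pigment is positive and all effects in this assay are fold-type;
additive Gaussian noise would permit negative pigment. The 100 % cap
models the assay ceiling of the "% of wild-type pigment" scale.

With σ = 0 every statistic equals its closed form: repression index
= 1/repression_factor, PSS = repression_factor(het)/repression_factor(hom),
PSA = pairing_activation — PRE effects are parameterized separately per
zygosity precisely so PSS is a free, recoverable quantity.

Defaults encode the published parameter regime: heterozygous control
pigment 5-8 % of wild type across four landing sites (the one printed
control value is 7 %), pairing activation 2-5× beyond dosage at three
sites and absent at the fourth, Fab-7 repression factors spanning
3.5-fold repression to 1.5-fold activation (het) and 18-fold repression
to 1.2-fold activation (hom), vg spanning mild uniform heterozygous
repression and 49- to 2.3-fold homozygous repression with the strongest
silencing at site 3, Pc relief 10× (vg) and 5× (Fab-7), σ = 0.2,
2 replicates, 50 heads per assay. Site effects are kept small enough
that the saturation cap is inactive in the default regime, so
closed-form recovery checks are not biased by censoring at 100 %. One
known tension: the published site-3 PSS of 71 for vg exceeds what the
published 49-fold maximum homozygous repression index can produce under
this model; the defaults are anchored to the repression ranges and
yield a site-3 PSS of ~34-47 depending on noise.

The generator emulates between-replicate variability with a single σ;
it does not model between-head variance, batch effects, pigment
measurement error structure, developmental patterning, or chromatin
context of landing sites. Passing recovery tests therefore shows the
estimators are consistent under the stated model, not that real assay
noise is log-normal.

Sequence generation draws i.i.d. bases at a requested GC content,
optionally rejection-samples away all occurrences of excluded motifs
(both strands), then overwrites planted motif texts at fixed or random
non-overlapping positions, returning the exact truth intervals. Planted
text boundaries can create incidental matches, so truth-based tests
assert containment, not equality. All generators are bit-reproducible
given a seed (`GENERATOR_VERSION` marks the sampling scheme).

## Validation problem sizes

The suite cross-checks the scanner and the score track against
independent brute-force oracles on 200 random sequences up to 2 kb;
repression-index/PSS recovery is checked at n ∈ {2, 10, 100, 1000}
replicates (within 3 relative % at n = 1000, σ = 0.2); planted-cluster
recovery is measured over 100 seeded simulations of 2 kb sequences
(≥ 95 required). These sizes give the estimators' sampling error a
comfortable margin relative to the asserted tolerances while keeping
the whole suite around ten seconds.

## Known limitations

- Exact-match primer annealing only; degenerate or mismatched primers
  are not modeled.
- The pair-density score uses untrained unit weights; it ranks windows
  within a sequence but its absolute values are not calibrated across
  sequences.
- The 106 bp surrogate is a constraint-satisfying stand-in, not the
  genomic sequence; analyses of the real region must substitute the
  genomic FASTA.
- Delta-method intervals are first-order and approximate; with two
  replicates they are indicative at best.
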