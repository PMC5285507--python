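# Methods

## The editing model

Uridine insertion/deletion editing never touches non-U bases, so the
preedited and fully edited forms of a transcript share an identical non-U
backbone. `kredit` represents an editing site as an `EditingEvent`: an anchor
position on the preedited transcript (0-based, transcript orientation) plus a
kind (`insertion`/`deletion`) and a U count. Events are applied from the
highest anchor to the lowest so anchor coordinates never shift; deletions
require the Us they remove to be present immediately 3′ of the anchor.

**Editing extent** is counted by the minimal alignment of a
(preedited, edited) pair in which only T-indels are allowed and every
backbone base is a forced match. That alignment decomposes exactly into a
gap-by-gap comparison of T-run lengths between consecutive backbone bases:
surplus Ts in the edited sequence are insertions, deficits are deletions.
The test suite checks this closed form against a full dynamic program.

*Valid event sets.* The round-trip identity — extent of the generated pair
equals the per-kind sums of the event set — holds only if no inter-backbone
T-gap receives both an insertion and a deletion (otherwise the minimal
alignment cancels them against each other). Both the synthetic generator and
the property-test strategy enforce this, plus at most one deletion per T-run
so deletion validity is checkable against the preedited sequence alone. This
is a statement about which event sets are well-posed, not a restriction of
the biology: any achieved editing outcome has a canonical event set of this
form.

All sequences use the DNA alphabet (U stored as T): tags are cDNA and the
genome reference is DNA. Coordinates are 0-based half-open internally,
1-based only in SAM output. The maxicircle is circular, but v1 does not allow
transcripts to wrap the origin — no analysis here needs it — so alignment is
against the linearized sequence.

## Dual references

The edited reference catenates the fully edited sequences of the twelve
editing-category transcripts, separated by 100-N spacers. N matches nothing,
so no tag (≤ 60 nt, ≤ 2 mismatches) can align across a junction; the
projection step asserts this. Never-edited transcripts exist only in the
genome frame and may carry no events.

## The aligner and its guarantees

Alignment is ungapped on purpose: an editing event inside a tag shifts its
flanks and destroys any ungapped genome alignment, which is precisely the
signal the dual-reference design exploits. A gapped aligner would blur the
preedited/fully-edited distinction.

A locus qualifies if the full tag matches with at most `max_mismatches`
(default 2) substitutions and score ≥ `min_score_fraction` (default 0.9) ×
tag length, where score = matches × 1 − mismatches × 1 (mismatch penalty 1).
Candidate loci come from exact seed k-mers (default 12 nt). For a tag of
length L the effective mismatch budget is
m = min(max_mismatches, ⌊L(1−f)/(1+penalty)⌋); the aligner places m + 1
disjoint seeds (shrinking k to ⌊L/(m+1)⌋ when necessary, e.g. k = 10 for a
20-nt tag), so by pigeonhole at least one seed is error-free and **no
qualifying locus can be missed**. The acceptance suite verifies equality with
an exhaustive all-offset, both-strand scan on 200 random instances.

"Uniquely mapped" means exactly one best-score locus across both strands of
the searched reference; ties are `multimapped` and excluded from all counts.
Mapping is sequential: genome first, and only tags with *no* genome locus are
offered to the edited catalog, so a tag from an unedited region — present
identically in both references — is deterministically `preedited`. Tags from
partially edited molecules that span the editing front match neither
reference and legitimately remain `unmapped`; the pipeline reproduces this
ambiguity rather than resolving it.

Transcript projection assigns a genome hit to the annotation containing its
start and requires sense-strand concordance (tags derive from mRNA);
antisense and intergenic hits are flagged and excluded from binding counts.
Edited-catalog hits are sense if they lie on the plus strand of the
catenated frame.

## Binding quantification

Counts are unique tags (multiplicity is carried but not used as weight —
duplicates are PCR artifacts). For editing-category transcripts the
preedited and fully edited frame counts are combined into the per-transcript
total. Category shares are percentages of all uniquely mapped, sense,
intra-transcript tags; region shares (preedited vs fully edited) exclude
never-edited transcripts from the denominator since they have no edited
form. Shares default to raw unique-tag counts; the length-normalized variant
is available alongside.

Gene-length normalization is implemented transparently as tags per
kilonucleotide of preedited transcript length. (A differential-usage tool is
sometimes used for this purpose in the literature; its role reduces to a
length correction here, so the package computes the explicit quantity.)

The binding/editing relationship is summarized by the Pearson
product-moment correlation between per-transcript total share
(100 × transcript tags / all assigned tags) and editing extent across the
pan-edited transcripts, requiring n ≥ 3 and returning NaN with a warning on
zero variance. Positional structure is summarized as per-position coverage
tracks (sum of tracks = sum of contributing tag lengths) and a 5′-bias
statistic: the fraction of tag 5′ ends in the 5′ third of the region
(uniform starts ≈ 1/3, a 5′-restricted binder → 1).

## qPCR arithmetic

ΔΔCt fold change uses a fixed amplification efficiency of 2.0 (exposed as a
parameter; no efficiency calibration is modeled) with technical replicates
averaged on the Ct scale before differencing; a per-replicate mode is
available behind a flag. Percent input adjusts the input Ct by
log₂(1/input_fraction) cycles before differencing. Pulldown and
carrier-control ratios are taken per replicate pair, then averaged (sample
SD, ddof = 1). Mock-IP samples are computed identically and reported
side-by-side; no background subtraction. NaN Cts propagate.

## The synthetic world

The generator emulates the study conditions, not real maxicircle sequence:

- **Genome**: 23,000 nt of uniform random DNA (the real maxicircle is
  ~23 kb), carrying 18 non-overlapping transcripts of 500–900 nt on random
  strands: 9 pan-edited, 3 minimally edited, 6 never-edited.
- **Extents**: pan-edited targets are spread evenly (with small jitter)
  across 50–550 total Us so the binding/extent correlation is identifiable
  over the documented range; minimally edited transcripts draw 4–40;
  ~10% of each target is realized as deletions (editing is
  insertion-dominated).
- **Cascade**: the preedited sequence is tiled into 60-nt gRNA blocks
  consumed strictly 3′→5′; a molecule at progress p carries exactly the
  events anchored in its p 3′-most blocks. Per-molecule progress is uniform
  over {0..n_blocks} — the real distribution of partially edited
  intermediates is unknown, so the least-informative choice is the default
  and is configurable.
- **Binding**: expected tags per transcript ∝ editing extent plus a small
  baseline weight (5.0) so never-edited transcripts acquire rare tags, as
  observed for one of the two paralogs; `five_prime_restricted` confines
  insert 5′ ends to the 5′ third of the preedited region; `uniform` is the
  null model.
- **Reads**: 4-nt barcode + 30–50 nt insert + 3′ adapter, truncated at 75 nt
  (single-end Illumina geometry). Cross-link truncation is modeled simply as
  the insert 5′ end — the analyses here use whole tags, not truncation
  sites. PCR families are geometric (duplication rate 0.3 → mean family
  ≈ 1.4; any heavy-tailed choice works and it is configurable); substitution
  errors (rate 0.001/base, no indel or quality-profile modeling) are applied
  per copy after duplication. The control library is 483 random-sequence
  reads with valid structure, matching the documented background size.

What passing tests therefore show: the pipeline's logic — classification,
accounting, share arithmetic, correlation recovery — is correct under known
ground truth. What they do not show: performance on real maxicircle
sequence, whose composition is strongly biased and repetitive compared with
uniform random DNA (real multimapping rates will be higher), or robustness
to real RNase/ligation sequence biases, which are not simulated.

## Problem sizes and numerical choices

The default verification run pushes 50,000 tags (~71k reads after
duplication) through the full pipeline; correlation recovery uses 20
independent worlds at 6,000 tags each, and bias runs 5,000 tags — sizes at
which binomial noise is far inside the tested bands. Score thresholds use an
absolute guard of 1e-9 when converting the score fraction to an integer
mismatch budget, so 0.9 × L landing exactly on an integer behaves
consistently. Ties in best alignment score are never broken: they define
`multimapped`. Degenerate inputs return NA (empty share denominators,
zero-variance correlation, empty 5′-bias) rather than raising, except where
the input is structurally invalid (unknown transcript, bad deletion anchor,
duplicate barcode), which raises with the offending item named.

## Known limitations

- No gapped or local alignment: junction-spanning tags from partially edited
  molecules are unquantifiable by design (their count is visible in the
  `unmapped` bin of the ground-truth comparison).
- Collapsing is exact-sequence (no UMIs are modeled), so identical biological
  duplicates collapse with PCR duplicates.
- Quality strings are ignored throughout (duplicate identity and alignment
  are sequence-only).
- Origin-wrapping transcripts and minicircle/gRNA sequence modeling are out
  of scope.
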