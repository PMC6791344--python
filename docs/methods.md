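# Methods

## Index-set model

An internal tag is a heterogeneity spacer (0–3 nt) followed by a 5 nt index.
Tags are organized in tetrads whose full-sequence lengths are exactly
{5, 6, 7, 8}: aligned at the 5′ end, the four members of a tetrad put four
different amplicon positions under each sequencing cycle, which is what
restores per-cycle base diversity in monotemplate pools. Channel balance is
evaluated on the MiSeq/HiSeq ≤ 2500 two-laser scheme (A,C red; G,T green) on
5′-aligned full sequences, positions 1–5 only — beyond position 5 tetrad
members run out at different cycles, so per-cycle balance is not defined for
the group. Two-channel chemistries (NextSeq/NovaSeq) use a different color
code and are out of scope.

Edit distance is unit-cost Levenshtein, computed with edlib. Set validation
defaults to the 5 nt uppercase indexes (the identifying part); the distance
over full spacer+index strings is also exposed. For the shipped set both
minima are 3. Forward and reverse tags are pooled into one universe for the
distance check: keeping the two roles mutually distant is a conservative
guard against orientation mix-ups, and the printed set satisfies it.

### What distance ≥ 3 does and does not guarantee

Same-length full sequences at Levenshtein ≥ 3 are also Hamming ≥ 3, so a
single substitution leaves a read at distance 1 from its own tag and ≥ 2
from every same-length alternative: one-mismatch matching can never
misassign such a read. Across *different* lengths the comparison window of a
longer candidate extends past a shorter tag into locus-primer bases, and for
some primer contexts a single substitution produces a tie at distance 1
between the true tag and a longer candidate. The matcher resolves ties by
refusing: the read is reported ambiguous, never assigned to the wrong
sample. Exhaustive enumeration over the default set with the primer pairs
used in the tests puts these safe ambiguities below 3 % of single-error
positions and finds zero misassignments.

## Set generation

`design_set` builds new sets greedily. Candidate 5-mers are enumerated in
seeded random order and accepted only if they keep every pairwise distance
≥ `min_edit` against all accepted indexes (both roles). Each accepted
quadruple is then dressed with spacers: the spacer lengths are a permutation
of the configured range, and the permutation is searched so that the columns
fully determined by index bases (positions 4–5, plus the feasibility
condition at position 3) can balance; the remaining "free" spacer bases are
then assigned channels column-wise to force exact 2 red / 2 green at
positions 1–5, and concrete bases are drawn within the chosen channel. If no
permutation balances a quadruple, one member is swapped out and the search
continues. This constructive approach replaces naive rejection sampling of
whole tetrads, whose acceptance probability collapses (≈ 10⁻⁷ per draw) once
16 indexes are accepted; the greedy search designs an 8 + 12 set in
milliseconds and is deterministic for a fixed seed. Infeasible requests
(e.g. `min_edit` = 6 on 5-mers) fail with an explicit message naming the
constraint.

## Fusion primers

A fusion primer is the literal concatenation tail + spacer + index + locus
primer; IUPAC degeneracy codes in locus primers pass through untouched (only
the demultiplexer expands them, for trimming). The four adapter tails are
the TruSeq and Nextera Read1/Read2 sequencing-primer sequences. Primer names
follow `<locusName>_<chemistry>_<R1|R2>_<tagLabel|NoTag>[_flip]` — unique,
sortable and order-sheet friendly; order sheets render sequences uppercase
(synthesis vendors ignore case) with an annotated column keeping the
lowercase spacer. Flipped panels swap which locus primer carries the Read1
vs Read2 tail while tags stay with their locus primer, so flipped and
unflipped panels contain identical tag/locus combinations. No
thermodynamic QC (hairpins, dimers, secondary structure) is performed, and
the CLI says so; validate oligos before ordering.

## Demultiplexing

Matching uses Hamming distance on fixed-length 5′ prefixes, each candidate
at its own spacer+index length. Indel-tolerant matching was rejected
deliberately: indels in the first 5–8 cycles are rare, and with staggered
lengths an indel-tolerant comparison makes length itself ambiguous. The
default tolerance is one mismatch (safe under the distance-≥ 3 design);
`--max-dist 0` is available. Ties at the minimum distance — including
cross-length ties — are ambiguous, and ambiguous or tagless reads are
written to `unassigned_*` files untrimmed, never dropped. Reads whose two
tags match but whose combination is absent from the samplesheet are counted
as `unexpected_combination` and the full observed tag-pair matrix is always
emitted, so tag-jump rates can be read off directly (leave empty wells in
the plate to measure them). Assigned reads have spacer+index trimmed as one
unit from both mates, qualities in lockstep; optional locus-primer trimming
accepts up to 2 mismatches with IUPAC expansion. Outer i5/i7 demultiplexing
is assumed done upstream; an optional mode filters on `i5=… i7=…` header
comments, counting mismatches as unexpected combinations. Gzip inputs are
detected by magic bytes, not filename.

## Pooling

Molarity uses the conventional average dsDNA base-pair mass of
660 g·mol⁻¹·bp⁻¹ (configurable): nM = ng/µL × 10⁶ / (bp × 660). Pipetting
volumes are proportional to target_reads / molarity, scaled so the largest
volume equals the cap (default 10 µL) or so a designated reference component
gets a set volume. Plans store exact volumes; reports round to 0.1 µL, and
any volume under 0.5 µL earns a dilution warning — bench realism defaults,
both configurable. Clustering-efficiency differences between library types
are not corrected by default, but `plan_pool(efficiency=…)` accepts a
per-component relative efficiency for users who calibrate one.

## Cost model

Prices are January-2019 USD list prices, shipped as a data file
(`taggimatrix/data/method_costs.json`) rather than code constants so users
can substitute their vendors'. The "variable" cost of pooled methods is
interpreted as per-pool — one shared limited-cycle reaction per pool — an
interpretation corroborated by reproducing both the published PCR counts
(192, 193, 97, 192, 97 at one plate/one pool) and the under-$2-per-library
figure at 18 plates. Pools default to plates (96 samples) but are free
parameters.

## Simulator

The simulator renders full library molecules and reads them as an instrument
would after outer-index demultiplexing: R1 starts right after the Read1
site (forward spacer+index first), R2 right after Read2 on the bottom strand
(reverse spacer+index first — read 5′→3′, which by construction is the tag
as synthesized into the primer). Inserts default to seeded-random 150 bp
sequences; reads running past the construct continue into the opposite
adapter tail and then poly-A padding. Errors are substitution-only, iid per
base, with flat Q37 qualities (Phred+33) — sufficient to exercise a
Hamming matcher, which assumes no indels. Two extra knobs support testing:
`errors_per_tag` forces exactly N substitutions uniformly inside each mate's
tag region, and `tag_jump_rate` swaps the reverse tag for another valid one,
mimicking chimera-style unexpected combinations. Outer indexes are emitted
as header comments, not basecalls. Truth tables record sample, tags, insert
span (0-based half-open, R1 coordinates) and every injected error position.

What passing simulations do **not** show about real data: no quality decay,
indels, chimeric inserts, adapter artefacts or cluster-density effects are
modeled, and real Read 2 tag order should be spot-checked against this
strand convention on a known library before trusting large runs.

## Test and verification sizes

The end-to-end round trip exercises all 96 tag combinations at 50 pairs per
sample (4,800 pairs); substitution-robustness checks enumerate all single
mutations of all 20 tags exhaustively rather than sampling. These sizes make
every guarantee checkable in seconds while covering the full combinatorial
space of the plate.
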