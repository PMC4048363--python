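# Methods

## Pipeline model and assumptions

The pipeline treats plant miRNA annotation as a deterministic decision
procedure over collapsed small-RNA tags. All sequences are handled as
uppercase DNA (U -> T); coordinates are 0-based half-open internally
and 1-based inclusive in GFF3 output.

**Preprocessing.** The insert of a raw read is the prefix before the
leftmost exact match of the 3' adapter's prefix. A match requires at
least `adapter_min_overlap` (default 8) adapter nucleotides, or the full
adapter when it is shorter than that; matches may run off the read end
provided they still reach the minimum overlap, so a 3-nt terminal
coincidence never truncates a read. Reads containing N are discarded
and counted. Summaries use the as-sequenced 18-30 nt range; mapping
restricts to 18-26 nt; both bounds are configurable. Singleton
fractions are per-library; the cross-library grand summary counts a
sequence as a singleton when its summed count across libraries is one.

**Mapping and filtering.** Tags are mapped by exhaustive exact string
search on both strands — at fixture scale (genomes < 1 Mb) this is
simpler and more transparent than an index, and the perfect-match rule
makes it exact. Tags with strictly more than `max_genome_hits` (500)
hits are dropped as repeat-associated; tags contained (either
orientation) in a decoy ncRNA/repeat sequence are dropped as annotated.

**Hairpin evaluation.** For each tag-locus, candidate windows at flank
lengths {50, 100, 150, 200} nt are folded (ViennaRNA MFE by default;
a hand-written Nussinov base-pair-maximisation engine with surrogate
energy = -pairs serves as fallback and as a small-scale oracle,
minimum hairpin loop 3 nt). From the dot-bracket pairing table with
mature span `[s, e]`, the miRNA\* span follows Dicer geometry:
`star = [partner(e-2) , partner(s) + 2]`, extrapolating unpaired
anchors from the nearest paired mature position and clamping to the
precursor. Duplex statistics are: mismatches = mature positions in
`[s, e-2]` unpaired or paired within the mature; bulges = asymmetric
loops between consecutive paired mature positions in that window
(event count and maximum size); overhang = number of unpaired mature
3'-terminal bases, so a fully paired mature reads as a blunt
(overhang-0) duplex. A mature span that is entirely unpaired, spans
the terminal loop, or whose star span would overlap it is rejected as
`no_hairpin`.

**Acceptance and reason codes.** A candidate is accepted iff mature
length in 20-24 nt, count > 20 in some library, some window passes
overhang == 2, mismatches <= 4 and at most one bulge of <= 2 nt,
dominance >= 0.70 within +-20 nt, and count > 5 in some library (kept
as an independent gate although it is implied by the > 20 rule).
Rejections carry the first failed criterion in the fixed order
length -> count -> no_hairpin -> overhang -> mismatches -> bulge ->
dominance; across windows the reason that progressed furthest is
reported, and the smallest window producing an accepted hairpin wins.
The mismatch threshold is <= 4 (the alternative strict-< 4 reading is
available via `max_duplex_mismatch`).

**Degradome scoring.** The Allen/CleaveLand-style penalty scheme:
mismatch or gap 1.0, G:U wobble 0.5, doubled at miRNA positions 2-13;
alignments with score <= 4.5 are kept. The search is exhaustive over
gapless windows plus single 1-nt bulges on either strand (prefix-sum
decomposition over the gapless penalty matrix keeps it vectorised);
gap penalties are doubled when the bulge falls inside positions 2-13.
The cleavage site is the transcript position opposite miRNA position
10; an event needs >= 5 degradome 5' ends exactly there (a +-1 nt
tolerance flag exists, default off; the site is not required to be the
profile maximum). Positional weighting is anchored on the guide
strand, so the weighted score is not invariant under swapping the two
duplex strands; the per-position pair states (match/wobble/mismatch)
are, and that is the symmetry the tests assert. ORFs are ATG-initiated
and stop-terminated in the three forward frames with >= 70 codons
(inclusive, configurable) — a deterministic replacement for
stop-to-stop conventions — and the longest ORF is the reference for
5' UTR / ORF / 3' UTR labels.

**Conservation.** Catalog status: exact match = known; equal length and
Hamming distance <= 2 = variant (minimum distance reported); else
novel. The same <= 2-mismatch rule covers variants of conserved
families. Species presence requires a perfect genome match plus a
+-200 bp window refolding into a hairpin passing the structural
criteria (read criteria are waived — no libraries exist for other
species); cross-species matching is exact by default. Lineage classes
are assigned with precedence broadly_conserved (any dicot) >
monocot_wide (all monocots) > wheat_specific (none) > wheat_barley
(barley only) > bep_clade (non-empty subset of barley/Brachypodium/
rice). Patterns with presence outside the BEP set but not all
monocots and no dicots — e.g. maize only — are not covered by those
definitions and are classed monocot_wide ("present in a monocot
lineage beyond BEP"), making the classifier total over all 2^7
vectors.

**Expression.** RP10M = count / library mapped total x 10^7. Group
comparisons use Welch's t on log10(x+1); clustering uses 1 - Pearson
on log2(RP10M+1) with average linkage (constant profiles get the
maximal distance 2 and are counted); optional per-row z-scoring is off
by default. Tissue-preferential calls are an explicit
operationalisation of "preferentially/specifically expressed":
preferential = mean >= 10 RP10M in the target tissues and >= 10x the
maximum outside; specific additionally caps the outside maximum at
1 RP10M; silenced mirrors the rule. All three thresholds are
configurable; counts derived from them are rule-dependent and are not
treated as reference values.

## The synthetic generator

The generator defines the study conditions. Background genome sequence
is i.i.d. uniform over {A,C,G,T} — the simplest null, which at these
lengths essentially never yields a qualifying hairpin with read
support. Precursors are built stem-outward from the desired duplex:
`[lower stem | mature | loop side | star | lower stem']` with a
~10-bp lower stem, 8-bp upper stem and 6-nt loop; mismatches are
symmetric 1x1 internal loops (the identical base never pairs under the
WC+GU rule), bulges are star-side insertions, and the 2-nt overhangs
are unpaired A's with C/G-capped junctions so the thermodynamic fold
cannot slip the duplex register. Each construct is folded and checked
— canonical loci must reproduce the requested statistics exactly,
violation loci must fail on exactly their labelled criterion — and is
redrawn under the same seeded RNG when MFE folding deviates (relevant
mainly for deliberately weak 5-6-mismatch stems); placement in genomic
context repeats the check with flanking sequence. All randomness flows
from the single simulation seed, so outputs are byte-identical across
runs.

Default conditions: 40 expected-pass loci (mature lengths cycling
20-24 nt, 0-2 mismatches, occasional 1-nt bulge, both arms and both
strands) and 10 loci per violated criterion (lengths 19/25; counts
pinned exactly at the 20-read threshold; overhangs 0/1/3; 5-6
mismatches; one 3-nt bulge or two 1-nt bulges; dominance 0.5 — chosen
well below the 0.70 threshold so binomial-scale fluctuation cannot
flip a label) in a 150 kb genome; two libraries at 120 reads per locus
window with exact proportional allocation (mature = round(depth x
dominance), remainder split over three offset tags inside the +-20 nt
window, star reads outside it), 150 background singletons per library
drawn from a typical plant size-class mix, and a single-literal 3'
adapter (the classic Illumina small-RNA adapter; real adapter
chemistry is out of scope). The decoy repeat array uses 520 tandem
copies so every k-mer of the array — including copy-junction k-mers,
which occur once less than the copy number — exceeds the 500-hit
filter; the decoy rRNA is a 200-nt sequence shipped as the annotation
decoy set. Degradome transcripts carry one ~80-codon ORF (UTRs
scrubbed of ATG and the planted ORF verified to be the longest, so
region labels are unambiguous), a binding site that is the reverse
complement of a generated 21-nt miRNA with optional wobble/mismatch
edits, exactly `peak_reads` 20-nt reads starting at the site, and
scattered background reads. The expression simulator plants
grain-specific rows (strong in the two developing-grain libraries,
zero elsewhere) in a heavy-tailed background matrix over the
11-tissue panel.

What the simulator does not emulate — sequencing error, quality decay,
polyploid homoeologs, chained/overlapping loci, expression replicates —
bounds what green tests mean: they demonstrate the decision rules are
implemented exactly and recover planted truth under clean conditions,
not performance on real wheat data.

## Numerical and design choices

* Thresholds are strict or inclusive exactly as stated: > 500 hits
  drops, = 500 retains; > 20 reads passes, = 20 fails; >= 5 degradome
  reads calls; score <= 4.5 kept; >= 70 codons qualifies an ORF.
* Folding-engine selection is `auto` (ViennaRNA if importable, else
  Nussinov); the Nussinov traceback uses a fixed deterministic
  tie-break. Fold inputs are capped at 1000 nt.
* Per-locus evaluation order and the furthest-failure window rule make
  reason codes deterministic; multi-locus tags are evaluated
  independently per locus, so one tag may found several accepted loci.
* The degradome gap search is limited to one 1-nt bulge per alignment;
  windows are restricted to lie fully inside the transcript.
* Degenerate inputs are defined, not accidental: zero-variance equal
  groups give t = 0, p = 1; constant expression profiles get maximal
  clustering distance; empty catalogs classify everything novel; an
  empty dominance window rejects the candidate.
* The standard problem sizes (150 kb genome, 100 loci, two libraries,
  40 degradome transcripts) were chosen so a full run completes in
  well under a minute per stage on one CPU while every criterion is
  exercised tens of times.

## Known limitations

The exact-match mapper and exhaustive alignment search scale to
fixture-sized genomes, not chromosome-scale assemblies. The Nussinov
fallback maximises pairs, not free energy, so its structures differ
from MFE on long inputs (it is intended for <= ~100 nt oracles and
environments without ViennaRNA). Star-read modelling is minimal (a
fixed fraction on the opposite arm), and dominance is computed on the
mature strand only — star reads fall outside the +-20 nt window by
construction. Published study-level counts that depend on the real
genome and full libraries (e.g. numbers of novel/wheat-specific
miRNAs) are outside what the synthetic conditions can or should
reproduce.
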