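# Methods

This note documents the models, conventions and design choices behind
`plastibar`, in the order the pipeline runs them.

## Quadripartite structure detection

A plastome is treated as a circular string over the IUPAC alphabet. The
two inverted repeats are found by seed-and-extend on the doubled sequence
(doubling handles the origin): exact 21-mer seeds are matched against the
reverse complement, seeds are grouped by anti-diagonal (an inverted-repeat
pair with copies A = revcomp(B) keeps `start(A) + end(B)` constant), and
each anti-diagonal is extended outward from its seed under a mismatch
budget. Near-exact IRs at the 20–170 kb scale make suffix-structure
machinery unnecessary; the search is a few hundred milliseconds at 20 kb
and a few seconds at 170 kb. Defaults are `min_len = 1000`,
`max_mismatch = 0` (plastome IR copies are typically identical); both are
exposed as flags. Ambiguity codes never match during extension — they
count against the mismatch budget — which keeps the search conservative
and order-independent.

The two arcs between the IR copies are labelled LSC (longer) and SSC
(shorter); equal arcs are labelled deterministically by lexicographic arc
sequence, with a warning. The partition is reported on the canonical
rotation (LSC starts at position 0, order LSC–IRa–SSC–IRb); the SSC is
kept in its input orientation, since downstream comparisons are within
groups of stable architecture. The conservation identity
`lsc + ssc + 2·ir = length` is asserted on every partition. Coordinates
are 0-based half-open internally and 1-based inclusive in reports.
One-IR removal returns LSC + IRa + SSC of the canonical rotation and
refuses non-circular input.

Degenerate case: if the best repeat pair has no single-copy arcs at all
(a purely palindromic molecule), the search reports none with a warning
rather than a zero-width partition.

## Site classes and nucleotide diversity

Gaps and all ambiguity codes are missing data everywhere: they never
match, never count as a state, and never enter denominators. A column
with fewer than two observed bases is excluded; variable means ≥ 2
distinct bases observed; parsimony-informative means ≥ 2 bases each
carried by ≥ 2 samples; singleton is variable but not informative. The
identity `variable = informative + singleton` is a tested invariant.

π for an interval is the average over all sample pairs of (differing
sites / comparable sites). Under the default complete deletion a column
is comparable only when every sample has an unambiguous base there —
mirroring the defaults of the standard desktop population-genetics tools —
so all pairs share one denominator; pairwise deletion (per-pair
comparability) is available by flag, and the two coincide on gapless
alignments. Zero comparable sites makes π undefined (`None`), never zero.
Sliding windows start at 0, step, 2·step, …, with the final window
truncated at the alignment end and flagged. Report percentages use the
full interval length as denominator, including gap columns, matching how
product sizes are conventionally printed.

## Diagnostic sites

A column is a strict diagnostic for group G when G's observed bases are
all one state and that state is absent from every other ingroup sample's
observed base. Outgroup rows are ignored entirely. Missing data inside G
flags the site `complete = false` but does not disqualify it; a column
where G has no data is skipped for G. Diagnostic-site finding is purely
combinatorial — no multiple-testing machinery belongs here.

## Barcode mining

Candidate cores of length `max_len` (default 800 bp, the practical upper
bound for one-amplicon Sanger verification) and `max_len/2` slide at a
50 bp step. A core is kept iff:

- every *required* group has ≥ `min_diag_per_group` (default 1) strict
  diagnostic sites inside the core. Required groups default to the
  ingroup labels with ≥ 2 samples: a singleton group cannot meaningfully
  anchor fixed-site coverage, and demanding it would veto every window;
- ≥ `min_variable` (default 3) variable sites — "moderate variation";
- gap fraction ≤ 0.05;
- window π ≤ 0.05. This cap operationalises the rejection of
  hypervariable, alignment-unreliable tracts (the IR-internal hotspot)
  as barcode material;
- both `flank_len` (default 25 bp, covering typical 20–24 nt primers)
  flanks are invariant and gap-free across all ingroup samples. A flank
  that runs off the alignment edge fails with reason "edge".

Ranking is fully deterministic without a seed: parsimony-informative
count (desc), then gap fraction (asc), then leftmost start, then longer
core; the top k mutually non-overlapping cores are returned, plus a
per-constraint rejection tally for diagnosability. Candidate cores live
in alignment coordinates; realised product sizes are re-measured per
genome by in-silico PCR, since gap columns make the two differ.

In-silico PCR matches the forward primer on the sense strand and the
reverse primer's reverse complement downstream within `max_product`,
under a per-primer mismatch budget (default 0). Circular templates are
searched across the origin and a product may wrap it, but can never reach
the full circumference. Primer thermodynamics (Tm, GC clamp, dimers) are
out of scope: the miner guarantees conserved flank *sequence*; actual
primer design belongs to a dedicated tool.

## Discrimination

Species/lineage discrimination follows the standard criterion: a group
succeeds iff its samples are monophyletic with bootstrap support strictly
above 50%. Heavy likelihood machinery is deliberately not reimplemented
here; the tree stage is desk-scale by design — neighbor joining on
p/JC69/K2P distances with a classic nonparametric bootstrap — and region
alignments can be exported in FASTA/relaxed PHYLIP for external ML
re-analysis when wanted. The success rule itself is applied verbatim.

Details that matter:

- distances use pairwise deletion by default; JC69/K2P saturation (the
  log argument going non-positive) replaces the pair by twice the largest
  finite distance, with a warning;
- NJ uses the Q criterion with deterministic smallest-index tie-breaking;
  negative branch lengths are clamped to zero with the deficit moved to
  the sibling branch (path lengths preserved). For additive inputs NJ
  provably recovers the generating topology and path distances (tested to
  1e-9 on 4–8 taxa);
- the bootstrap resamples columns with replacement; because pairwise
  difference/transition/comparable counts are linear in column weights,
  all B replicates reduce to one matrix product, making B = 1000 on a
  25 × 800 region take a second or two. Supports are bit-for-bit
  reproducible given (alignment, model, B, seed);
- monophyly on an unrooted tree is a bipartition question; rooting is
  never needed. Zero-length internal edges are collapsed before the
  monophyly call, so a region with no signal yields a star on which every
  multi-sample group honestly fails, rather than an arbitrary
  tie-broken resolution with inflated support;
- outgroup samples sit in the tree but are never scored; single-sample
  groups (the "unstable" sample whose placement shifts between regions)
  are trivially monophyletic, carry no support value, and are reported
  as indeterminate — never counted toward success or failure.

## Synthetic plastome generator

The generator emulates a genus-scale plastome barcoding study: 25
ingroup samples in four multi-sample groups (species A ≈ 2, species B ≈
5, lineages E and W of species C ≈ 9 each), one unstable singleton, one
outgroup. The guide tree mirrors that structure with an outgroup branch
long enough to be clearly external and internal branches shallow enough
to keep background within-group diversity realistic.

Sequences evolve by Jukes–Cantor substitution along the guide tree: the
root is uniform over A/C/G/T, each branch mutates each site independently
with probability (3/4)(1 − e^(−4d/3)) where d = branch length × rate, and
calibration against the closed form is a tested invariant (50 replicates,
3 standard errors). The default rate (0.002 substitutions/site per unit
branch length) keeps background window π under 0.002, matching the level
reported for real congeneric plastomes.

Planted features are deterministic overwrites, so truth is exact:

- 12 diagnostic columns per group — 3 inside the barcode core (one in
  each 50-bp edge zone of the core plus one in the middle, so any window
  shifted off the core loses planted signal and the core is the unique
  ranking optimum) and 9 in a group-specific LSC zone kept a full window
  length away from the core, so no sliding window can bridge a zone and
  the core and accumulate full cross-group coverage;
- one 800 bp barcode window (LSC positions 4000–4800) with 30 bp
  zero-variation flank blocks;
- a 600 bp hotspot inside the IR whose columns are re-simulated at
  rate × `hotspot_multiplier` (default 200). The default makes the tract
  *hypervariable*: its window π (~0.05–0.08) clears the miner's 0.05 π
  cap, so the hotspot plays the same role as the real IR-internal tract
  that gets rejected as barcode material; a mild multiplier (e.g. 20)
  still makes it the diversity maximum over clean background but leaves
  it minable, which is exercised separately in tests;
- group-specific deletions inside the hotspot realise the between-group
  IR-length contrast (default: species B 400 bp shorter than species A)
  when rows are folded into circular genomes LSC + IR + SSC + revcomp(IR)
  with a seeded random rotation per genome;
- the four block-junction columns are pinned to a base that breaks
  complementarity across each junction. Without this, chance
  complementary bases at the LSC/IR and IR/SSC boundaries extend the
  assembled genome's true maximal inverted repeat a base or two past the
  planted partition — a real property of the sequence, but one that would
  make the recorded truth wrong rather than the detector.

Indels are confined to the hotspot (via the per-group deletions at
assembly), so the "true alignment" is gapless and exact, and site-level
truth scoring is unambiguous. Genomes default to ~20 kb — a deliberate
scale-down of the 160–166 kb molecules whose architecture they mimic;
every algorithm is length-agnostic and the full scale is exercised once
in the structure tests (a 162,115 bp replica with a 27,207 bp IR).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: alignment error (inputs are true alignments),
indels outside the hotspot, rate heterogeneity beyond the single hotspot,
base composition bias (GC ≈ 50% rather than the ~41% of real plastomes),
annotation features, and gene flow or incomplete lineage sorting between
groups. Results on real data additionally depend on alignment quality,
which is deliberately outside this package (alignments are consumed, not
produced).

## Pipeline and reproducibility

`run_pipeline` executes structure → scan → mine → discriminate, echoes
every parameter into the report, and derives per-candidate bootstrap
seeds from the run seed, so the JSON report is byte-identical across
reruns with the same inputs and configuration (no timestamps). The report
is checked against a minimal published schema (`report_schema.json`);
stage failures abort with a stage-tagged error. The acceptance script
regenerates everything from a single seed at the default problem sizes
(27 genomes of ~20 kb, B = 200, 50 calibration replicates), which keeps a
full run around five seconds.

## Known limitations

- IR detection with `max_mismatch > 0` extends greedily from the seed
  (budget spent inward first); it is exact for the default budget 0 but
  not guaranteed maximal for large budgets.
- K2P saturation handling (capping at twice the largest finite distance)
  is a pragmatic repair, not an estimator with known properties; saturated
  regions should not be barcodes anyway.
- The miner's constraint set is combinatorial; it reports *candidate*
  regions, and primer design/validation against off-target amplification
  remains external.
- With only two ingroup groups, diagnostic sites are symmetric (a site
  fixed in one group and absent from the other is diagnostic for both),
  so coverage-based ranking cannot distinguish "which group drives this
  window"; three or more groups are the intended regime.
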