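# Methods

## The observation model

A palindrome arm pair in a haploid Y chromosome is treated as a
pseudo-diploid locus. For each single-nucleotide PSV the observable per
chromosome is one of three states — pseudoheterozygous (0/1, arms differ),
pseudohomozygous-ancestral (0/0) or pseudohomozygous-derived (1/1) — plus
MISSING (assay failure) and EXCLUDED (arm-presence check failed, e.g. an
abnormal karyotype; reported separately because it is a biological, not
technical, removal). Alleles are polarised ancestral/derived against the
chimpanzee and gorilla orthologs. Chromosomes attach to leaf haplogroups of
a rooted binary-marker phylogeny; chromosomes sharing a leaf are modelled as
a star polytomy below it, which leaves the per-haplogroup minimum event
count unchanged while assuming nothing about unknown substructure.

## Minimum-event reconstruction

Each PSV is a single-origin character (recurrent mutation at these sites is
neglected). The mutation is placed by parsimony at the MRCA of all
chromosomes carrying a derived allele; a PSV with no carrier has an empty
history, and carriers spanning both root clades place the origin at the
root. Below the mutation the allowed branch transitions are 0/1 → 0/1
(cost 0), 0/1 → 0/0 and 0/1 → 1/1 (cost 1, a conversion); pseudohomozygous
states are absorbing, since regaining the lost allele would require a new
mutation. The minimum total cost is computed by Sankoff-style dynamic
programming over the tree; MISSING/EXCLUDED chromosomes impose no
constraint. The minimum count is invariant across co-optimal
reconstructions; event *placement* is not, so the traceback deterministically
prefers the entering state at every node (pushing events toward the tips)
and sets an `ambiguous_placement` flag whenever a tie exists. Direction
(and hence GC class) of each event is determined by the fixed state observed
below it and is tie-break-independent. The DP is verified against exhaustive
enumeration of all legal state assignments on thousands of random trees.

## Bias tests and rates

Direction (to-ancestral vs to-derived) and GC bias (fixes-S vs fixes-W,
counting only PSVs whose two alleles differ in strong/weak class) are tested
with a Pearson 1-df goodness-of-fit χ² against 1:1, without continuity
correction; arm-vs-spacer 2×2 contrasts use the Yates correction. Both bias
tests are re-run after collapsing each multi-PSV co-conversion tract to a
single event (direction taken from the tract's first member), since
co-converted PSVs are not independent replicates.

Per-generation rates divide event counts by a generation budget. The
calibration equates 95 backbone substitutions over 47 resequenced
chromosomes with 52,000 generations (25-year generations, 118 kyr TMRCA,
6.5 Myr human–chimp divergence), i.e. ≈547.4 generations per substitution.
For a multiply-sampled phylogeny the lower budget counts backbone branches
only; the upper budget adds, per extra chromosome in a haplogroup, the full
clade-root depth in substitutions — as if each extra chromosome descended
from the clade root independently. The bundled 175,000–505,500-generation
budget for the 378-chromosome survey follows this scaling from 323–935
substitutions. The budget of the 83-chromosome phased subset is not
published directly; the bundled value (174,400–220,600 generations) is
back-computed from the published inversion rate and cross-checked against
the published conversion rate in the same chromosome set, and is labelled
synthetic in the code.

## Phase, inversions and tracts

Arm-specific typing assigns each allele of a phased PSV to the proximal or
distal arm. A chromosome's orientation relative to the reference phase is
SAME when every pseudoheterozygous PSV matches the reference arm
assignment, INVERTED when every one is swapped, UNINFORMATIVE with no
heterozygous PSV, and MOSAIC otherwise; MOSAIC patterns are surfaced for
review, never silently resolved. Orientation labels are mapped onto the tree
and the minimum number of flips is found by two-state Sankoff parsimony
(exact on polytomies), with the root anchored SAME on ties because the
reference chromosome is part of the sample. Each call reports the interval
between the outermost informative PSVs of the supporting chromosomes — the
resolution to which the breakpoint is ascertained. Detection is restricted
to the configured phased window; the window is configuration, not a
constant. Unphased chromosomes inherit their haplogroup's orientation only
when all phased members agree.

Co-conversion tracts are inferred per chromosome: a PSV counts as converted
when it is pseudohomozygous and lies inside the PSV's mutation clade (so
the fixation implies a conversion somewhere on its lineage, including
haplogroup stem branches). Maximal runs of adjacent converted PSVs are
built; a pseudoheterozygous PSV breaks a run, while missing or
not-yet-mutated PSVs are passed over without breaking it ("adjacent" means
consecutive among informative genotyped sites). A run is kept as a single
tract only while its fixed alleles remain compatible with one arm-specific
reference haplotype; when the compatible-arm set empties the run is split,
excluding independent opposite conversions. PSVs at which the reference is
itself pseudohomozygous are arm-uninformative and constrain nothing.
Identical tracts in several chromosomes of one haplogroup are counted once
(one historical event). Tract length is the bp span between outermost
members — a minimum, since outer boundaries are unobservable; singleton
tracts have span 0 and are excluded from length summaries. When one deep
event underlies identical tracts in two sister haplogroups the per-haplogroup
convention counts two tracts; this matches the per-haplogroup event logic
but can overcount very deep tracts.

## Interspecific comparisons

Pairwise divergence per region counts only columns ungapped in both
sequences. Fixed differences are polarised with the gorilla outgroup: a
column where chimp and gorilla agree but human differs is a human-lineage
replacement, and symmetrically for chimpanzee; three-way differences and
gorilla-only differences stay unassigned. W↔S tables report, per lineage ×
region, W→S counts over total W nucleotides and S→W counts over total S
nucleotides, their percentages, and the normalised to-W/to-S ratio
(S→W rate ÷ W→S rate). Denominators count the inferred ancestral base (the
base shared by two species) over analyzable columns — a convention that
makes denominators lineage-symmetric; which sequence defines the published
denominators is not stated, and this choice approximately reproduces them.
Hypermutable-context masking removes any column participating, in any of
the three sequences read 5'→3' with gaps skipped, in a CpG, TpG or CpA
dinucleotide; both members of the triggering dinucleotide are masked.
GC-content contrasts use a plain Pearson 2×2 χ² (no correction), with Yates
available as an option. Consensus calling from pileup evidence requires at
least 5 reads of quality ≥20 agreeing with no quality-passing discordant
read; the discordance tolerance is a knob (default 0, strict unanimity).

## The forward simulator

The simulator is the package's test bed and defines what the test suite
demonstrates. Defaults mirror the surveyed study conditions: 63 haplogroups
× 6 chromosomes (≈378), a 340,000-generation tree (midpoint of the
175,000–505,500 budget), ten PSVs at bundled coordinates honouring the
published 81 bp (PSV1–PSV2) and 9023 bp (PSV1–PSV7) spans, per-PSV
conversion rate 5×10⁻⁵/generation (midpoint of the published per-PSV
2.9–8.4×10⁻⁵), ancestral-fixation probability 86/146, S-fixation
probability 59/79, mean tract 2068 bp, and inversion rate 10⁻⁵/generation.

Topology grows by random joins; branch generations are exponential weights
rescaled to the configured total, including a private branch per
chromosome. Each PSV's mutation is planted once (at the root, on a
length-weighted random branch, or a mix). Conversions arrive per branch as
Poisson(rate × generations × n_PSVs); an event picks a focal PSV, draws a
geometric total tract length centred on it (the generative law is a
modelling choice — only minimum tract statistics are observable), and
copies the donor arm onto the other arm across all covered PSVs. The donor
arm is chosen so that a GC-informative focal PSV fixes the strong allele
with probability `p_gc`, and any other focal PSV fixes the ancestral allele
with probability `p_ancestral`. Conversions are inter-arm only; X–Y
gametologous exchange is not modelled. Inversions arrive as
Poisson(rate × generations) and swap the arm assignment of phased-window
PSVs, i.e. they are planted only where detection is ascertainable, mirroring
the real outer-arm ascertainment. Every planted event is logged; observable
fixations (those that changed a pseudoheterozygous state) are logged with
direction, which is what the caller can recover.

Triad sequences evolve down the fixed ((human, chimp), gorilla) tree with
per-branch substitution probabilities derived from the configured pairwise
divergences per region (multiple hits are ignored at these rates) and a
region-specific probability that the substitution target is strong
(defaults 0.60 arm / 0.45 spacer, emulating the observed arm W→S
enrichment). Default triad lengths are 30 kb arm / 15 kb spacer, a
scaled-down analogue of the real ~104 kb / ~46 kb regions chosen so the
property suite exercises the same contrasts quickly; divergence-ordering
tests use 60 kb.

What the simulator does *not* emulate: coalescent demography, selection,
recurrent PSV mutation, indels or alignment error in the triad, assay
dropout structure, and real per-branch generation counts. Passing recovery
tests therefore show correctness of the inference machinery under the
stated generative model, not robustness to those real-data complications.

## Numerical and design choices

* Coordinates are 1-based in all files (GRCh37 convention); internal
  arithmetic is 0-based half-open.
* p-values come from the exact χ² survival function; reproduction tests on
  published p-values use 5% relative tolerance to absorb printed rounding.
* Rate bounds divide by the opposite budget bound (more generations → lower
  rate); published rate reproduction keeps the raw quotients rather than
  forcing printed rounding.
* Per-PSV rates divide the total rate by the full PSV panel size even
  though not every PSV is informative in every chromosome — reproducing the
  published convention; the result is therefore a minimum.
* Degenerate inputs: empty regions are skipped with a warning rather than
  raised; identical sequences give divergence 0 with an undefined (None)
  contrast; zero denominators in replacement tables yield None ratios;
  all-missing PSV columns raise a no-data error.
* The pipeline stamps every table with tool version, a hash of the
  analysis-relevant configuration, and the seed; re-runs are
  byte-identical.
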