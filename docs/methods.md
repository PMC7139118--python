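# Methods

This note documents the models, algorithms, parameter choices and
limitations of `cneduo`. Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`; nothing is asserted that
the code does not itself measure.

## Coordinates and formats

All internal coordinates are 0-based half-open (BED convention) on a
named sequence with strand `+`, `-` or `.`; GFF3's 1-based inclusive
coordinates are converted at the I/O boundary in both directions, so a
read-write cycle preserves the printed coordinates. Spliced reads are
represented as BED12 blocks (aligned segments) rather than SAM/BAM so no
alignment-index tooling is needed; unknown strand `.` is allowed only on
non-transcribed intervals such as signal windows. Every reader/writer
pair is a round-trip identity on valid files, and malformed input raises
a `ParseError` carrying the file and line number.

## Homology discovery

`scan_homologs` is a seed-and-extend scan without gaps: every exact
`seed_len`-mer of the query nominates a candidate full-length window on
either strand, scored as ungapped identity (matches / query length);
windows under `min_identity` are dropped and overlapping same-strand
hits merge keeping the maximal identity (leftmost on ties, for
determinism). Gapped alignment is out of scope: across deep vertebrate
comparisons a ~32-nt element accumulates substitutions rather than
indels, and a fixed-width alignment is what the complementarity analysis
consumes.

Defaults are `seed_len=12`, `min_identity=0.75`. Seed length trades
sensitivity against speed: the probability that a diverged copy retains
an exact 12-mer run falls quickly with divergence (about 77 % of copies
at ~10 % per-copy divergence), so the deep-divergence recovery analyses
in this package (pipeline recovery scoring, the acceptance script, the
demo config) run `seed_len=8`, at which ≥95 % of copies planted at 5 %
substitutions/site/branch on the default two-branch-deep tree are
recovered (measured over 50 replicates, 400 copies). Both parameters are
exposed as CLI flags.

Synteny assignment is purely positional: a hit is labelled `C` (or `D`)
when it lies strictly between the cluster's gene11 and gene12 spans on
one sequence — no overlap with either gene — and `unassigned` otherwise.
A hit on a sequence absent from the annotation is `unassigned`, not an
error; a hit between the flanking genes of two clusters at once
indicates a malformed annotation and raises.

## Complementarity and compensatory substitutions

Both element copies are written 5′→3′ in the orientation of their host
transcripts. Because two 5′→3′ RNAs hybridize antiparallel, column *i*
of the C copy is paired with column *L*−1−*i* of the D copy, and a
column is complementary when the bases form a Watson–Crick pair (A:T,
C:G at the DNA level). G·T wobble is excluded by default — the analysis
treats complementarity as a discrete two-state property — and can be
enabled with a flag. The score equals the identity of seq_C against
revcomp(seq_D), so a perfect reverse-complement pair scores exactly 1.

When no transcript overlaps an element, its orientation is inferred by a
flank rule (default: antisense to the cluster's gene11 strand), and the
provenance (`annotated` vs `inferred`) is always reported so downstream
users can filter to annotated-only evidence. The flank rule is a
modeling choice; with it, orientation matches the generator's truth in
100 % of noiseless replicates.

Ancestral states are reconstructed per column and per side with
unweighted Fitch parsimony — the appropriate tool for a short element
with few changes, where a likelihood model would add parameters the data
cannot constrain. Tie handling is deterministic: a non-root node keeps
its parent's state whenever that state is in its Fitch set; at the root,
the state held by the majority of leaves wins, a residual tie goes to
the state observed in the root's last-listed child subtree (the
conventional outgroup position in written trees), and any remaining tie
breaks alphabetically. The outgroup-position rule keeps paired columns
consistent: because complementary bases sort in opposite alphabetical
order on the two sides, a purely alphabetical root tie-break would
systematically place the two halves of one compensatory event on
different branches and destroy the call. Multifurcating trees are
accepted (the set operations generalize); multifurcations are counted in
the output. On trees of ≤6 leaves the reconstruction is verified against
exhaustive minimum-change enumeration.

A substitution event is any branch whose child state differs from its
parent state. A compensatory call is a branch with events on both sides
at a paired column, classified by the complementarity of the paired
bases before vs after the branch: *gain* (non-complementary →
complementary), *retention* (complementary before and after a double
change), *loss* (complementary → non-complementary). Events on sister
branches are reported per branch and never merged.

## Intron retention

Reads are classified against one caller-designated transcript model:
`exon` if every aligned base is exonic (a spliced read whose blocks skip
an intron exactly has no intronic base and is exonic evidence), `intron`
if every base is intronic, `junction` if bases fall on both sides of an
exon/intron boundary, `unassigned` if any base leaves the transcript
span. Classification ignores read strand by default (unstranded library
convention). Junction reads count toward the retention numerator —
they demonstrate unspliced molecules — while raw per-category counts
are always preserved so either convention can be plotted. Isoform-aware
assignment (EM across overlapping transcripts) is out of scope.

## Enhancer-state calling

CTSS records are clustered per strand by single linkage with
`max_gap=20` bp; the dominant position is the highest tag count
(leftmost on ties). Divergent pairs are (−,+) cluster pairs whose
dominant positions lie within `window=300` bp of the element, with the
minus dominant upstream of the plus dominant, on opposite sides of (or
overlapping) the element; spacing between dominants within
`spacing_band=[100, 250]` bp is flagged nucleosome-scale (a ~147-bp core
particle plus linker).

Signal evidence per mark: mean over the element core, means over both
flanks of width `flank=500` bp, and a local background mean over the
element ±10×flank. DNase openness is core/background (a constant track
gives exactly 1); H3K4me1 is bimodal when both flank means reach
`bimodal_ratio=1.5` times the core mean; a mark is "high" when its
core-or-flank peak reaches `high_ratio=2` times its background.
Uncovered positions count as zero and are tallied as a warning counter.

The decision ladder is strictly ordered: (1) an element overlapping an
annotated promoter is `promoter_ambiguous` regardless of signals —
chromatin profiles cannot distinguish an enhancer from a promoter it
sits in, so the caller must declare the overlap from annotation; (2) not
open (openness < 2) → `closed`; (3) open with high H3K27ac or at least
one divergent pair → `active_enhancer` (bidirectional CAGE is the
decisive active hallmark, so active outranks poised when both pattern
sets hold); (4) open with bimodal H3K4me1 and high H3K27me3 →
`poised_enhancer`; (5) otherwise `closed` with a low-confidence note.
All thresholds are free parameters with the defaults above, grouped in
`StateThresholds`.

## Co-expression

The default estimator is Pearson on log₂(TPM+1) ("pearson-log");
Spearman is the rank-based alternative. Correlations in the cis/trans
table are computed on the co-expressed subset — samples where both the
element and the gene reach the TPM threshold (default 1, matching the
expressing/non-expressing grouping) — so presence/absence patterns do
not masquerade as correlation. Benjamini–Hochberg q-values are computed
across each table; raw p-values are always retained. Zero-variance
features yield r = NaN with an explanatory flag rather than an
exception; fewer than 3 samples is an error. Promoter usage ratios use
log₂((TPM_nc + 0.5)/(TPM_coding + 0.5)); the pseudocount of 0.5 keeps
zero-TPM samples defined; the summary is the median ratio and an exact
two-sided sign-test p-value.

## The synthetic-data generator

The generator's defaults are the study conditions the analyses are
validated under; every planted quantity is recorded in a `TruthLedger`.

* **Ancestral cluster** — a 6-kb uniform-random chromosome with two
  two-exon coding genes (gene11, gene12) and one element of
  `cne_length=32` nt planted strictly between them, recorded 5′→3′ in
  the orientation of its (antisense) host transcript.
* **Duplication and divergence** — at the root, the D copy is the
  reverse complement of the C copy, so antiparallel complementarity is
  perfect by construction. Each branch of the species tree (default: a
  balanced four-taxon tree `((human,mouse),(gar,shark))`, unit branch
  lengths) applies Jukes–Cantor substitutions independently to both
  copies at `substitution_rate=0.02` per site per branch (rates are
  per-branch probabilities; branch lengths are not multiplied in).
  Compensatory events are planted as simultaneous double substitutions
  at paired columns on recorded branches, cycling through
  retention/loss/gain classes. Gain events require a non-complementary
  ancestral state, so the root is pre-set non-complementary at those
  columns (the root modification is not an event). Event columns are
  shielded from background substitution so the ledger's before/after
  states stay exact, and event branches are restricted to those where
  parsimony places a single change unambiguously (strict-minority
  subtrees, plus half-leaf subtrees outside the root's last-child
  position) — without this restriction a planted change on the root's
  outgroup-position edge is inherently unplaceable by any parsimony
  method. Species listed in `drop_c_in` lose their C copy
  (teleost-like lineage loss); `omit_host_transcript_in` removes the
  host annotation to exercise orientation inference. The D copy is
  planted 55 nt downstream of the host transcript's TSS, inside its
  first exon and promoter region.
* **Read libraries** — whole-cell, nuclear and cytosolic libraries of
  `read_depth=10⁴` reads of 50 nt. Per read, the category is
  multinomial: the combined intron+junction mass equals
  `retention_fraction` (default 0.4) in whole-cell and nuclear
  libraries and `retention_fraction/10` in the cytosolic library (an
  order-of-magnitude depletion — detectable but not degenerate);
  junction reads take `junction_share=0.2` of the retention mass, so
  the (intron+junction)/assigned estimator is centred on the planted
  fraction. Placement is uniform within the category; exonic reads may
  span splice junctions as two blocks. No sequencing-error or indel
  model is attempted.
* **CAGE and chromatin** — signals are per-base tracks over the element
  ±5.2 kb: baseline 0.1 RPM everywhere; Gaussian DNase peak (amp 8,
  sd 80) and bimodal H3K4me1 bumps (amp 8, sd 120 at ±250 bp) in open
  states; H3K27ac bumps (amp 6) only when active; a broad H3K27me3
  plateau (amp 5 over ±1 kb) with a central dip, plus p300, only when
  poised. Active elements get divergent CTSS clusters whose dominant
  positions are exactly `cage_spacing=180` bp apart (satellite tags
  within ±3 bp), and an optional promoter CTSS whose amplitude is the
  coupling times the element tag count. `signal_noise` adds independent
  Gaussian noise per position scaled to each mark's amplitude, clipped
  at zero; CTSS counts become Poisson draws. The generator does not
  emulate chromatin-state HMM emission structure, peak-caller artifacts
  or mappability gaps, so passing state-call tests demonstrates that
  the ladder reads the intended signatures, not that the thresholds are
  calibrated for any particular consortium pipeline.
* **Expression** — the element's log₂ TPM is N(4, 1.5²) (log-normal
  TPM); each target gene's log₂ TPM is 3 + 1.5·(ρ·z + √(1−ρ²)·ε) with
  planted coupling ρ, defaults {HOXC11: +0.9, HOXC12: +0.5,
  HOXD11: −0.3, HOXD12: −0.9}, over `n_samples=200` samples with
  `zero_fraction=0.3` of samples zeroed for the element feature
  (non-expressing cell types). The noncoding/coding promoter pair is
  planted at a fixed 3-fold ratio with small log-noise, so the
  noncoding side inherits the coding gene's coupling — mirroring the
  situation where the two share a locus and correlate nearly equally
  with the element. Real expression compendia add batch structure,
  zero-inflation of lowly expressed genes and heavy tails that this
  generator does not model, so sign-recovery results bound estimator
  behaviour under the planted model only.

Same seed ⇒ byte-identical outputs for every generator; independent
named random streams are derived from the root seed, so changing one
stage's parameters does not perturb another stage's draws.

## Problem sizes

The validation analyses use: 50 replicates (400 copies) for discovery
recovery at 5 % per-branch divergence; 15 noiseless and 100 noisy
replicates for compensatory detection; depth 10⁴ for retention recovery
at fractions {0.1, 0.25, 0.5}; 100 replicates × 3 states for state
calls, with and without 20 %-amplitude noise; 1,000 replicates (n=50)
for null calibration and 60 replicates (n=200) for sign recovery. These
sizes give binomial standard errors well under the margins being tested
while keeping a full validation run in the tens of seconds.

## Known limitations

* The scanner is exact-seed and ungapped; elements with indels or with
  divergence beyond ~25 % are outside its design envelope.
* Fitch parsimony reports one optimal reconstruction; on branches where
  several reconstructions tie, the deterministic tie-break chooses one,
  and events planted on inherently ambiguous branches (the root's
  outgroup-position edge splitting the leaves in half) cannot be
  recovered by any parsimony method.
* The state caller consumes per-base tracks and caller-declared promoter
  overlaps; it does not call peaks, learn thresholds, or scan
  genome-wide.
* Correlation is association only; no causal claim, batch correction or
  survival modelling is attempted.
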