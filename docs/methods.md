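# Methods

This note records the models implemented in `bovidy`, the parameters that
matter, what the synthetic-data generator does and does not emulate, and
the numerical choices made where the design was genuinely open.

## 1. Depth-voted pangenome consensus

**Model.** A pan-chromosome graph is a GFA1 graph with explicit segment
sequences, a designated backbone walk (the highest-contiguity assembly),
and one contig walk per sampled individual. Segment depth is the number of
*distinct samples* whose walk covers the segment — a support count, not a
read depth. Bubbles are minimal divergence/reconvergence structures against
the backbone: off-backbone segments are grouped into weakly connected
components, and a component hanging between exactly one backbone source and
one downstream sink is a bubble whose branches are the simple paths through
it plus the backbone's own sub-path. Direct backbone skip edges contribute
an empty (deletion) branch.

**Voting.** Within a bubble the branch with maximal *mean* segment depth is
chosen. The mean (rather than the sum) makes the vote robust to how finely
a branch happens to be segmented; when all branches are single segments the
two criteria coincide, and in that regime the voted path provably equals
the exhaustive maximum-support source-to-sink path (the property the test
suite checks against a brute-force path enumeration oracle on graphs of
≤ 15 segments). With multi-segment branches of unequal length the mean- and
sum-criteria can disagree; the mean is the package's choice.

Deterministic tie-break: the backbone branch wins ties. Regions that are
cyclic, attach to more than two backbone anchors, or exceed the branch cap
(default 64) are *complex*: they resolve to the backbone and are flagged
for manual review rather than raising. Empty deletion branches score 0
because per-segment depth carries no support signal for an edge-only
branch.

**Contig merging.** `merge_overlap` scans suffix(a)/prefix(b) overlaps
(both orientations of b, containment included) for the longest gap-free
overlap of length ≥ `min_overlap` (default 1 000 bp) at identity ≥
`min_identity` (default 0.95). Gap-free scoring is exact under the
package's substitution-only divergence model; with indel-divergent contigs
the identity threshold should be relaxed. Absence of a qualifying overlap
is an error — the function never silently concatenates. The merge report
states both input lengths, the overlap, and the merged length so any
discrepancy with an externally expected total is visible to the user.

## 2. Pseudoautosomal boundary

**Identity route.** `windowed_identity` tiles the positionally comparable
span of the X-homologous and Y sequences into windows (default 5 kb,
minimum 100 bp) of per-base identity. `refine_breakpoint` then aligns the
two sequences globally inside the coarse interval with affine gap scores
(match 1, mismatch −2, gap open −5, gap extend −1 — implemented via
Biopython's PairwiseAligner so no external aligner binary is needed) and
calls the boundary at the last alignment column that (i) ends a run of at
least `min_match_run` = 50 consecutive matches and (ii) is followed by
`probe_len` = 500 columns of identity below `divergence_threshold` = 0.8.
The run/probe thresholds are not dictated by any published procedure; they
were chosen so that sharply constructed boundaries (identical prefix, first
divergent base differing) are recovered base-perfectly, and they are all
configurable. On boundaries followed by *random* (rather than constructed)
sequence, chance matches can extend the call by a few bases — the windowed
scan bounds this to the final window.

**Coverage route.** Female read depth terminates at the PAB; male depth
continues. The boundary is the last position where female depth holds at or
above `frac_median` = 0.1 × reference for at least `run_len` = 200 bases
upstream. The reference is the *median female depth over the female-covered
region* (covered = above `frac_median` × male median): a chromosome that is
mostly male-specific has a chromosome-wide median female depth of exactly
zero, so the covered-region median is the usable analogue of "median
depth". Median-relative thresholds keep the call invariant to the absolute
sequencing depth. The male track is a control: if it terminates at
essentially the same relative point (before 99 % of the chromosome), the
signal indicates assembly truncation, not a PAB, and the call is rejected
with a reason. At 30× depth with Gaussian noise (σ = 2) the coverage call
lands within ±500 bp of the true boundary, and the identity and coverage
routes agree at that level — the concordance the tests assert.

**Telomere arrays.** The sequence near each chromosome end (window default
50 kb) is tiled into motif units at every phase of the motif and of its
reverse complement. The call is the maximum-score unit run with per-unit
score = `max_divergence` − unit divergence (Kadane's rule, ties to the
longer run), extended by exact partial-unit matches at the edges (printed
telomere lengths are generally not multiples of the motif length). Two
properties follow: the call's mean divergence is ≤ `max_divergence`, and
any motif unit adjacent to either edge diverges by at least the bound — so
one-unit extension violates it. An earlier candidate criterion, the
*longest* interval with mean divergence ≤ bound, was rejected because a
long clean array can absorb arbitrary flanking junk while keeping the mean
below any reasonable bound.

**Alignment shifts.** For a PAF of alignments between one reference/query
pair, shift = reference start − query start, binned at 5 kb. A pair is
called collinear when every |shift| ≤ 0.05 Mb. Bin counts always sum to the
number of alignments.

## 3. Ampliconic census

"Complete gene structure" is operationalized as an intact ORF: the spliced,
strand-corrected CDS starts with ATG, ends with a stop codon, has length
divisible by three, and contains no internal stop. This is a deliberately
narrow reading — it classifies any frameshifted or prematurely terminated
copy as non-ASC — and it is the package's operational definition, since
"complete and accurate structure" is a concept, not a test.

Lift-over filtering keeps a candidate iff coverage ≥ 0.5 AND structure
preserved AND exactly one best mapping; each reject carries its reason.
Annotation merging treats lift-overs as primary and discards any de novo
model with ≥ 1 bp of same-strand exonic overlap with a primary model (the
strictest reading of "overlapped"); opposite-strand overlap is allowed.

Read support: short mode counts each read once at its primary placement —
when the aligner has not designated a primary among equal-best placements,
one is chosen with a seeded RNG, mirroring short-read aligner tie-breaking.
Long mode counts primary placements with MAPQ ≥ `min_mapq` = 20. A read
supports the copy containing at least half of it. Thresholds
`min_short` = `min_long` = 1 read define TSC and hTSC; both are exposed as
parameters since "successfully mapped" fixes no count. All provided
alignment sets are pooled (no per-tissue restriction).

Dosage ratios are rounded half-up to two decimals (the convention that
reproduces printed tables; banker's rounding does not). A 0/0 family is
reported as 0.00 ("inactive"); a nonzero numerator over a zero denominator
is undefined and reported as such. Amplification tiers are half-open
[lo, hi) except the first, which is the closed range [1, 10] — so 10 is
"1–10" and 100 is "100–200".

## 4. Repeat composition

Within each superfamily, overlapping records are merged before summing, so
a base counts once per superfamily. Class totals are ClassI =
LINE + SINE + LTR + Penelope, ClassII = DNA + Helitron (rolling-circle
elements ride with the DNA transposons, as composition tables
conventionally print them), Rest = everything else. All percentages are
computed on exact integer ratios and rounded half-up to two decimals only
at presentation; cross-species percentage-point deltas are taken on the
unrounded fractions and rounded last. Rounding first can shift a delta by
0.01 — the published-ledger regression tests in the suite are sensitive to
exactly this.

Self-similarity blocks: HS iff identity > 0.95, MS iff 0.90 ≤ identity ≤
0.95. With a non-PAR length supplied, the labeled and HS-only coverage
fractions are reported, and HS coverage > 0.95 is summarized as a
"saturated-HS" architecture (a few large high-identity blocks protecting
nearly the whole male-specific region).

## 5. PRDM9 zinc-finger motifs

Fingers are matches of C-x(2,4)-C-x(12)-H-x(3,5)-H (lazy quantifiers,
non-overlapping, left to right). The four base-contacting residues (helix
positions −1, 2, 3, 6) are read at fixed 1-based offsets 5, 8, 9, 12 into
the 12-residue spacer after the second cysteine — a fixed-offset convention
appropriate for the canonical x(12) spacing this pattern enforces.

The per-residue × base affinity table shipped in
`data/zf_recognition.tsv` is a coarse, literature-informed approximation of
canonical C2H2 preferences (Arg→G, Asn/Gln→A, Asp/Glu→C, His→G,
aliphatics→T; alanine contributes nothing). It is synthetic in the sense
that it was written for this package, not fitted to binding data, and it is
user-replaceable. Consequences that depend only on the *algebra* — finger
counts, activity filtering, motif lengths, column normalization — are
exact; per-base probabilities and consensus composition are qualitative.

zf_score is the mean over the four contacts of the residue's best base
affinity, a [0, 1] measure of how decisively the finger can prefer any
base; `active` requires zf_score ≥ 0.5. This replaces HMM e-value
screening; an optional hook accepts externally computed e-values and
deactivates fingers above a cutoff. Raising the threshold can only shrink
the active set (tested).

PWM assembly lays active fingers down in reverse array order (the
C-terminal finger reads the 5′ end), three columns per finger from contacts
6, 3, −1, with the position-2 residue contributing the base immediately 3′
of the subsite — averaged into the next subsite's first column, or appended
as one trailing column for the last finger laid down. Length is therefore
3n + 1: 19 bp for six active fingers, 16 bp for five, 40 bp for
thirteen. This reverse-order one-base-overlap convention is the unique one
consistent with both of those printed motif lengths. Probabilities come
from a temperature-parameterized exponential normalization
(p ∝ exp(affinity / T), T = 0.2): lower T sharpens columns; it affects
probabilities, never lengths.

## 6. The synthetic-data generator

The generator emulates the statistical structure the analyses rely on, at
1/100 scale by default (424 kb chromosome, 68.4 kb PAR, 189 bp telomere,
matching the proportions of a real bovid Y): a PAR shared base-for-base
between X and Y (telomere array included) with independently random
sequence beyond; ampliconic families planted as arrays of copies mutated
from a family master at `copy_divergence` (default 1 %, substitutions
only); a configurable fraction of copies pseudogenized by an in-frame
premature stop, and expression restricted to intact copies (default
families form a four-tier panel at roughly 1/10 real copy counts, with
half of intact copies silent). Short transcriptome reads (100 bp, 10×) are
placed by exhaustive Hamming comparison against every same-family copy —
exact, because the error model has no indels — with all equal-best
placements reported and a seeded-random primary; long reads are full
transcripts that place uniquely at 1 % divergence. Depth tracks are a step
function (female) or constant (male) at 30× with clipped Gaussian noise.
Graphs are a linear backbone with single-segment bubble branches and one
walk per sample; the truth path is the per-bubble majority with ties to
the backbone.

Fixed seed implies byte-identical outputs (hash-compared in the tests).

**What it does not emulate** — and hence what passing tests do not show
about real data: indels and structural variation within gene copies (real
pseudogenes are often frameshifted, not point-stopped); platform error
profiles, read-length distributions and coverage biases; transcript
splicing (planted genes are single-exon, so spliced-alignment ambiguity is
untested); reverse-strand copies by default; Hi-C signal; diploid
autosomes; and multi-segment bubble branches or nested bubbles beyond the
complex-flag fallback.

**Problem sizes used by the test suite** (chosen as comfortable
desk-scale replicates of each property): the consensus-vs-oracle
equivalence runs on 200 seeded graphs of ≤ 15 segments; boundary recovery
on a 1 Mb chromosome with a 161.3 kb PAR; census recovery on ten seeded
replicates cycling 10–200 planted copies at 1 % divergence with 5× long
reads (hTSC = expressed set in every replicate; TSC ≥ hTSC in ≥ 95 %).

## 7. Coordinates, rounding, degenerate inputs

All emitted truth, reports and tables use 1-based inclusive coordinates
(GFF3 convention); internal arithmetic is 0-based half-open. All printed
percentages and ratios round half away from zero at two decimals, computed
from exact integer ratios wherever the inputs are integers. Degenerate
inputs are defined rather than accidental: a zero-length PAR yields
unrelated X/Y; an expression-free family yields zero reads; an empty
alignment set yields zero counts everywhere; an empty PAF yields an empty
histogram; absence of a telomere motif yields None, not an error.

## 8. Known limitations

- The consensus voter resolves bubbles independently; linked polymorphisms
  spanning multiple bubbles are not modeled (real haplotype structure is
  ignored, as in the per-bubble majority it emulates).
- `merge_overlap` is gap-free; contigs whose true overlap contains indels
  need a lower identity threshold or external alignment.
- The breakpoint refiner assumes the coarse interval contains exactly one
  homology collapse; multiple boundaries inside one interval return only
  the last.
- The ZF recognition table is an approximation; downstream per-base
  probabilities should not be interpreted quantitatively.
- `count_support` assigns reads by genomic overlap of the primary
  placement; it does not re-align or rescue reads the aligner placed
  elsewhere.
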