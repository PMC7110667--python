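# Methods

This note documents the models and algorithms behind `repcons`, the
parameters that matter, the design decisions where several choices were
defensible, and what the synthetic-data tests do and do not demonstrate.

## Coordinate model

All in-memory intervals are 0-based, half-open, stranded. RepeatMasker
`.out` tables are 1-based inclusive on disk and converted on input; UCSC
chain files follow the standard convention (target = genome, always `+`
strand; query = consensus, possibly `-` with coordinates on the
reverse-complemented strand). Chains are written genome→consensus so that
generic liftOver tooling can consume them directly. Block arithmetic
(`Σsize + Σdt = tEnd − tStart`, `Σsize + Σdq = qEnd − qStart`) is validated
on both parse and construction, and writing is canonical, so write∘parse is
bit-exact.

## Fit alignment

Repeat instances are fragments of their family consensus: most LINE-1
copies are 5′-truncated, and escape lineages carry internal deletions. The
aligner therefore solves the *fit* (glocal) problem — the instance aligns
end-to-end, the consensus contributes a substring, end gaps on the
consensus are free. Scores are integer affine: match +1, mismatch −2, gap
open −6, gap extend −1 (a gap of length L costs `−6 − L`). The mismatch and
extension penalties are deliberately mild relative to the opening penalty
so that a 129 bp deletion survives as one contiguous gap (cost −135)
rather than being shredded into mismatches.

Two execution paths share one Gotoh-style three-state kernel (jitted with
numba):

* **Full DP** over the whole rectangle, used when the pair is small
  (≤ 4×10⁶ cells; above that the memory for three 64-bit state matrices
  plus traceback pointers becomes unreasonable and the call is refused
  unless anchoring applies).
* **Anchored banded DP** for long pairs. Maximal exact shared 12-mers are
  merged into same-diagonal segments and chained co-linearly (O(s²) sparse
  chaining on matched length with a small penalty per diagonal shift;
  chained segments may overlap by a few bases where a k-mer happens to
  straddle a junction, and the overlap is trimmed in the chain score). The
  chain defines a per-row diagonal track, linearly interpolated across
  unanchored stretches, and the DP runs in a band around that track. The
  band half-width adapts: 24 plus the largest diagonal jump between
  consecutive anchors, capped at the `band` parameter (default 200). A
  single-anchor chain reduces to the classic one-diagonal band. If no
  12-mer is shared and the pair exceeds the full-DP cap, the pair is
  reported unalignable.

Determinism: ties inside the DP are resolved by a composite integer
objective — score first, then fewer gap openings, then the leftmost target
end — so repeated runs produce byte-identical alignments. Note that
*equally scoring gap placements* still exist in the problem itself: when
the bases flanking a deletion junction are locally repeated, the gap can
sit a few bases left or right at identical score. All instances of a family
resolve the tie identically (same consensus context, same rule), so
detected windows keep their exact width but may sit within a couple of
bases of the planted coordinate. Degenerate pairs whose optimum aligns no
bases at all (possible only for tiny or unrelated inputs) raise an error
rather than returning an empty block list.

The test suite checks the kernel against an independently written
plain-Python fit-DP oracle on random and related pairs, checks banded
against full DP, and cross-checks substitution counts against an external
infix edit-distance aligner on mutation-only pairs.

## Consensus building

Selection follows the standard recipe for building repeat references from
annotated copies: the longest `ceil(0.01·n)` sequences are removed (very
long "copies" are typically recombination or misannotation events), then
the 50 longest remaining are kept, ties broken by identifier. The multiple
alignment is a deterministic center-star: the longest sequence is the
center, every other row is fit-aligned to it, and pairwise insertions open
shared, left-aligned gap columns ("once a gap, always a gap"). A
profile-refining aligner would give prettier columns, but for majority
consensus calling the center's coordinate system is what matters, the
procedure is exactly reproducible, and an externally computed alignment
can be supplied instead (`--msa`).

Consensus calling is per column: a column is dropped when its gap fraction
exceeds 0.5 (`gap_majority`) or when the winning base occurs fewer than 2
times (`min_base_count`); base ties break alphabetically. With ≥ 10
full-length rows at ≤ 1% divergence and no indels this recovers the
ancestral sequence exactly (the probability of any column majority being
wrong is ≪ 10⁻³ across a 6 kb consensus), which the tests assert.

## Lifting

`lift_interval` intersects an interval with the aligned blocks of every
overlapping chain; the lift succeeds on a chain when the aligned fraction
reaches `min_match` and reports the minimal consensus span covering the
mapped bases (point-like output suits summit pileups better than fragment
lists; fragments are derivable from the chains). Defaults: `min_match`
0.95 — the usual same-species liftOver setting — and `multiple=True`, so
one genomic interval may lift to several consensuses, as happens where
repeat annotations nest. The meta-summit workflow overrides `min_match` to
0.5 because an 11 nt extended summit adjacent to a chain gap should still
lift on its mapped half. Failures carry a reason code: `deleted` (no
overlapping chain) or `partial` (aligned fraction too low).

## Meta-summits

Summits are extended by `flank` = 5 nt on each side, lifted, and piled up
per base. The caller tests each base's pileup height against a uniform
Poisson background, `λ = Σ values / L`, upper tail `P(X ≥ h)` <
`pvalue_cutoff` (default 10⁻⁵), merges significant bases separated by at
most `merge_gap` = 30 nt, and requires `min_summits` = 5 supporting
summits. On a single short consensus a genome-scale peak caller's
local-background machinery reduces essentially to this model, and the
self-contained version is exactly testable; externally produced peak calls
can be substituted at the CLI level. With 200 instances and summit jitter
of sd 2 the called meta-summit falls within ±3 nt of the planted site in
≥ 99 of 100 seeded simulations (asserted in the tests at a 3 kb consensus
— the quantity is independent of consensus length, which only sets the
background λ).

## Deletion windows

A fixed deletion carried by a sub-lineage produces a coverage drop whose
edges are sharp at low divergence. The detector works in three stages,
all on the coverage array:

1. **Marking.** Base *i* is marked when `values[i] < drop_fraction ·
   max(median[i−f,i), median(i,i+f])` and that baseline is at least
   `min_spanning` (defaults: drop_fraction 0.5, f = `flank_win` = 100 nt,
   min_spanning 10). The *larger* flank median is the reference because in
   a 5′-truncated family the upstream flank is itself depressed by the
   rising coverage ramp.
2. **Merging.** The interior of a drop wider than `flank_win` sees only
   its own depressed flanks, so its mask fragments. Marked runs are
   iteratively merged whenever every base between them stays below the
   threshold set by baselines measured *outside* the candidate windows.
3. **Refinement and gating.** Boundaries are pushed outward/inward against
   the outer baselines; a window is accepted only if **both** outer flanks
   reach `min_spanning` coverage — a genuine deletion has solid coverage
   on both sides, which is exactly what distinguishes it from a truncation
   edge or an array end. Windows narrower than `min_width` = 5 nt are
   dropped, those separated by less than it are merged.

On noiseless simulations this recovers planted 129 / 20 / 11 bp deletions
at exactly their planted widths. One boundary note: when the carrier
fraction among spanning instances equals `drop_fraction` the decision sits
on the threshold by construction (expected in-window coverage =
drop_fraction × baseline); recovery claims are therefore made at carrier
fractions comfortably above the threshold (0.6–0.9 in the tests).

## Genotyping and ordering

Genotyping returns to per-instance alignments: an instance *spans* a
window when its aligned blocks touch both `span_margin` = 20 nt flanks,
and a spanning instance is a *carrier* when its aligned bases cover less
than `covered_max` = 20% of the window. Ordering of two windows A and B is
decided on instances spanning both: `A_first` iff `P(A|B) ≥ tau_high`
(0.9) and `P(A|B) − P(B|A) ≥ tau_margin` (0.2), symmetrically for
`B_first`, else `unresolved` — an old deletion is present in essentially
every carrier of a younger one, but not conversely.

The 100-seed ordering study in the tests scores the decision rule on
status matrices derived from the generator's truth, after first proving on
full pipeline runs that alignment-based genotyping reproduces the truth
matrix cell-for-cell at zero divergence; this keeps the hundred-seed study
fast without weakening what it demonstrates. The simulated history uses
nested deletions on full-length elements (as in a > 6 kb full-length
filter) with carrier fractions 0.9 and 0.65·P(old) so both windows stay
individually detectable above the 50% drop threshold, and a 5% leak so
that 5% of young-deletion carriers lack the old deletion.

## Synthetic families

The generator emulates a young LINE-1 family:

* **Truncation.** The 5′ start offset is geometric
  (`truncation_geom_p`, default 1/3000 for a 6 kb consensus, capped so
  every copy keeps ≥ 200 nt of 3′ sequence): short 3′ fragments dominate
  and coverage rises monotonically toward the 3′ end.
* **Deletions.** Each planted deletion has a carrier fraction; a deletion
  may `require` an older one, in which case carriers are drawn at the
  stated conditional fraction among carriers of the required deletion and
  at a small `leak_fraction` elsewhere. Deletions overlapping the
  truncated region are simply absent from that copy, and the truth records
  what was actually removed.
* **Mutations.** I.i.d. substitutions at `mut_rate` (default 0.02, in the
  range of within-family divergence of young primate LINE lineages); no
  indel polymorphism, no CpG or transition bias.
* **Binding sites.** A bound copy whose site survived truncation and
  deletion emits one 1 bp summit at the homologous genomic base plus
  integer-rounded Gaussian jitter applied along the consensus direction.
* **Planting.** Copies are embedded between random spacers (2 kb) in a
  synthetic chromosome, about half reverse-complemented, with
  RepeatMasker-style annotations; extraction round-trips exactly.

All randomness derives from the single spec seed; identical specs give
byte-identical outputs. What the simulator does *not* model — realistic
substitution processes, insertions, nested/chimeric elements, segmental
duplications, alignment-confounding low-complexity sequence — bounds what
the passing tests show: they demonstrate that the pipeline's coordinate
arithmetic, detectors and decision rules are correct under the generative
model, not that the model captures every complication of real genomes.

## Problem sizes and runtime choices

Test and reproduction runs use desk-scale sizes chosen to keep the full
suite in a few minutes on one core: 6 kb consensus and 300 copies for the
deletion-recovery scenarios, 800 full-length copies per seed for the
ordering study, 200 copies × 100 seeds for the meta-summit study, 30
copies for the exhaustive per-base lift equivalence check. The anchored
aligner handles a truncated 6 kb instance in a few milliseconds, the full
three-state DP being reserved for short pairs and oracle comparisons.

## Known limitations

* Deletions at the extreme ends of the consensus cannot be distinguished
  from truncation and are (correctly) not called; the both-flanks gate
  means windows touching an array end are rejected.
* Window coordinates inherit alignment gap-placement ambiguity of a base
  or two where junction-flanking sequence is locally repeated; widths are
  unaffected.
* The anchored band is a heuristic: an optimal path wandering more than
  the adaptive half-width from the anchor track would be missed. The
  banded-vs-full equivalence tests cover the regimes the pipeline uses
  (truncation + point mutations + internal deletions up to ~150 bp).
* Coverage counts one chain per instance; multi-chain instances are
  rejected rather than resolved.
* The Poisson background is uniform; a consensus with strongly non-uniform
  mappability would need a local background model.
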