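# Methods

## The measurement being modelled

cDNA-AFLP scores transcript abundance as band intensity on silver-stained
polyacrylamide gels. One *unit* is one band position (primer combination ×
gel size) compared across three lanes: the A-genome parent, the somatic
hybrid, and the E-genome parent. Intensities are ordinal: the package uses
integer levels `0..L` with `L = 3` by default (absent / weak / medium /
strong). `L ≥ 3` is the minimum at which additivity (a strict intermediate),
dominance (equality with one parent) and transgression (outside the parental
range) can all be represented at once.

## The 12-state classifier

With an equality band `eq(x, y) ⇔ |x − y| ≤ δ` (default `δ = 0`), a unit
`(a, h, e)` is classified by:

1. parents equal: hybrid above both → VIII, below both → VII, else NO_CHANGE;
2. parents unequal: hybrid equal to a parent → dominance (IV/IX on the A
   side, II/XI on the E side, "expressed" when the matched parent has the
   band, "silent" when it lacks it); hybrid outside the parental range →
   transgressive (V/VI up, III/X down); strictly between → additivity
   (I when the A parent is the high parent, XII when the E parent is).

With `δ > 0` a hybrid level can be "equal" to both readings at once;
dominance is then tested before strict intermediacy, and the A side before
the E side. The mapping is a total partition of the level cube (verified
exhaustively against an independent sign-pattern oracle for `L ≤ 5`,
`δ ≤ 1`), and swapping the two parents mirrors the labels
(I↔XII, IV↔II, IX↔XI, V↔VI, III↔X; VII, VIII, NO_CHANGE fixed).

Novel (acquired) expression is `a = e = 0, h > 0` (a special case of VIII);
silencing is `a > 0, e > 0, h = 0` (a case of III, VII or X). NO_CHANGE
units are mid-parent values and are excluded from every percentage
denominator.

## Replicate reconciliation

Gels are scored in replicate (default 2). The default `ALL_PRESENT` rule
requires a band in *every* replicate before a taxon is called positive, then
takes the half-up rounded replicate mean — the conservative reading of
duplicate silver-stained gels; `MEAN_ROUND` skips the presence gate. On a
single-replicate matrix both rules are the identity, and the `ALL_PRESENT`
support is always a subset of `MEAN_ROUND`'s.

## Summary arithmetic

All percentages are `100·count/n_differential`, rounded half-up to one
decimal. Two roll-up conventions coexist in published tables of this kind
and both are exposed: `CategoryTally.group_percentage` divides the summed
group count (239/2240 → 10.7), while `ContributionReport` sums the rounded
per-category percentages (15.7 + 8.1 → 23.8), which can differ in the last
decimal (e.g. a component-sum down-total of 19.8 vs 19.7 from counts).

Subgenome attribution: additivity state I (A parent high) is attributed to
the A subgenome and XII to the E subgenome; contribution_A = additivity_A +
dominance_A (I + IV + IX), likewise for E. The attribution map is
configuration, not computation, and can be swapped.

The per-taxon novel/silencing table is likewise defined by explicit
composition maps from cells to category percentages (defaults in
`summarize.DEFAULT_NOVEL_SILENCING_COMPOSITION`), because those cell
semantics are a reporting convention; the defaults reproduce the published
sums when fed the published per-category percentages. The functional-class
table is pure tabulation of externally supplied annotation counts — sequence
annotation itself (BLAST/GO) is out of scope.

## The synthetic-data generator

`SimulationConfig` defaults are the study conditions: 2240 differential
units, 1000 no-change units, duplicate gels, `L = 3`, intensity jitter
SD 0.3 and dropout 0.02. The default category composition
(`DEFAULT_CATEGORY_COUNTS`) honours the published group totals exactly
(239 / 533 / 474 / 552 / 442 of 2240) and the published within-group splits
where those are arithmetically consistent with the group totals; where they
are not (the published transgressive-up components 15.3 + 7.9 + 5.4 = 28.6
exceed the published group total 24.6), the group total wins and the
remainder is split in the published ratio (V = 124, VI = 85). The
transgressive-down split III = 193 (8.6%), VII = 105 (4.7%), X = 144 (6.4%)
is consistent with every published down-group figure. These published
inconsistencies are reported by the tooling as they stand, not resolved.

Generation: category counts are drawn multinomially (or apportioned by
largest remainder under `allocation="exact"`, for noise-free reproduction of
a target composition); each unit's true `(a, h, e)` is drawn uniformly from
the level triples consistent with its category — by construction, noiseless
classification recovers the truth with accuracy 1. No-change units get a
shared level drawn from `1..L` (an all-zero triple would not be a visible
band position). Observation: per lane,
`clamp(round(true + N(0, jitter)), 0, L)`, then every positive observation
is independently zeroed with the dropout probability. Replicates share the
truth but not the noise. All randomness flows from one integer seed.

What the generator does *not* emulate: primer-specific amplification bias,
band co-migration of unrelated fragments, cross-gel size miscalibration,
correlated (lane-wide) scoring errors, and partial digestion. Passing
recovery tests therefore show the analysis logic is sound under idealised
scoring noise, not that the wet-lab protocol is unbiased.

Under the default noise settings, duplicate `ALL_PRESENT` reconciliation
keeps the mean recovered group share within ~1.5 percentage points of the
simulated truth (inside 3 binomial SDs at n = 2240); with zero noise the
pipeline reproduces the published group percentages exactly.

`generate_transcripts` produces i.i.d.-base sequences at a given GC fraction
and fixed length — a deliberate null model for exercising the digestion
engine, with no codon structure or homology.

## In-silico AFLP

Digestion is complete: every EcoRI (`G^AATTC`) and MseI (`T^TAA`) site is
cut at its top-strand offset; fragments tile the input. Only EcoRI–MseI
fragments are treated as amplifiable (standard AFLP chemistry suppresses
same-end products; a flag includes them). A fragment amplifies under a
primer pair when the bases immediately interior to each site remnant match
the primer's 3′ selective extension — read directly at the fragment's left
end and in reverse complement at its right end, since that primer extends
along the bottom strand. Band size is the top-strand fragment length plus a
configurable adapter constant (default 0), bands are keyed at 1 bp
resolution (co-migrating fragments share a band), and the default retained
window is 100–600 bp.

One numerical subtlety: both enzymes cut off-centre, so a fragment's top-
and bottom-strand lengths differ by the overhang excess. Top-strand lengths
tile the input (conservation), but only the strand-symmetric *duplex extent*
(`DigestFragment.duplex_length`: top-strand length + 4 at an EcoRI cut right
end, + 2 at an MseI one) is invariant under reverse complement; the tests
check each property on the quantity for which it holds. Ambiguity codes are
rejected rather than expanded.

## qPCR

`delta_delta_ct` implements the pure comparative-Ct method: arithmetic mean
of replicate Ct values, `ΔCt = Ct(target) − Ct(reference)` within a sample,
`ΔΔCt = ΔCt(sample) − ΔCt(calibrator)`, fold = `2^−ΔΔCt`. No
amplification-efficiency correction is applied. Two invariants follow and
are tested: fold ratios between samples are calibrator-independent, and a
constant Ct shift applied to all genes of one sample (e.g. input amount)
cancels.

## Numerical and degenerate-input conventions

- Rounding is half-up everywhere (`Decimal`-based, no float-tie artefacts),
  both for percentages (1 decimal) and replicate means (integer levels).
- Empty tallies raise on percentage access rather than returning NaN.
- Coordinates are 0-based half-open; cut positions refer to the top strand.
- An empty sequence digests to an empty fragment list; an empty transcript
  set predicts an empty profile.
- Pipeline outputs embed a 16-hex-digit SHA-256 prefix of the canonical
  config, and identical config + seed reproduces byte-identical tables.

## Problem sizes

The bundled tests and the acceptance script run the full study-size
simulation (2240 + 1000 units, duplicate lanes); the Monte-Carlo recovery
check uses 20 seeds, which holds the mean group-share bias well inside three
binomial standard deviations of the truth. The whole suite completes in a
few seconds on one CPU.

## Known limitations

- The 12-state layout beyond the verbally anchored states fixes III/X and
  V/VI by the parent-high convention (A parent high → the lower numeral);
  any residual within-group relabelling leaves every group-level statistic
  unchanged.
- Ordinal gel intensities carry no calibrated abundance scale; "additivity"
  means a strict intermediate level, not a quantitative mid-parent test.
- Band identity is positional: two different transcripts co-migrating at one
  size are one unit, and homoeologs are not sequence-resolved.
- No statistical test is attached to proportion differences between
  categories; the package reports composition, not significance.
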