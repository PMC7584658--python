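# Methods

## Scope and model

`cnaps` infers intrachromosomal structural variants from *segmented*
SNP-array copy-number profiles and predicts their transcriptional
consequences.  The underlying model is deliberately minimal: a deletion
removes a closed genomic interval and joins its flanks; a tandem duplication
inserts a copy of an interval next to the original, joining the interval's
end back to its start.  Both create exactly one novel junction whose two
sides are, up to probe resolution, the boundaries of the copy-number
segment.  Inversions and interchromosomal events are invisible to copy
number and are out of scope, as is any raw-array normalization or
segmentation (input profiles are already segmented) and any purity/ploidy
estimation (strict filtering substitutes for it).

## Copy-number states and segment hygiene

Segment log2 ratios are binned into HOMDEL (< −1), HEMIDEL ([−1, −0.2)),
NEUTRAL ([−0.2, 0.3)), GAIN ([0.3, 0.7)) and AMP (≥ 0.7).  The published
description of the neutral bin contains an evident typo (an empty interval);
the bins used here are the unique reading under which the five intervals
partition the real line.  All thresholds live in `PipelineConfig` and are
configurable.

Consecutive same-state segments separated by less than `merge_gap_max`
(default 100 kb — the only distance scale the filtering rules mention) are
merged; the merged amplitude is the probe-count-weighted mean (unweighted
when probe counts are absent), a choice that is inert downstream because
amplitudes are never re-used after classification.  Segments immediately
flanking a no-data gap strictly greater than `nodata_gap_min` (100 kb) are
removed; chromosome ends are not gaps.  Merging precedes gap-filtering,
matching the order in which the rules are stated.

Coordinates are treated as 1-based closed (the common SEG dialect);
chromosome names are normalized by stripping `chr`; X and Y are processed
like autosomes since the log2 ratio is already relative to matched normal.
Rows with non-finite amplitudes are dropped with a logged count rather than
rejected, because real level-3 files contain them.

## SV rules and filters

Three rules read events off the per-sample state sequence: a HEMIDEL
segment whose neighbors are both not HOMDEL is a deletion; a HOMDEL segment
whose neighbors both exist and are HEMIDEL is a deletion (the nested-loss
pattern); a GAIN segment with no AMP neighbor is a tandem duplication.  A
missing neighbor at a chromosome end satisfies "not HOMDEL"/"not AMP" but
fails "is HEMIDEL" — the literal reading; terminal events are mostly removed
by the telomere filter anyway.  Calls spanning fewer than `sv_min_size`
(15 kb) bases, or with a breakpoint within `telocent_excl` (2 Mb) of
position 1, the chromosome end, or the centromere interval, are removed.
Breakpoints are the first and last base of the event segment; the true
breaks lie somewhere in the flanking probe gaps, so downstream gene matching
treats them as points with no added slack.

## Promoter-substitution geometry

For a deletion of [bp1, bp2] the junction's genomic left side is bp1 and its
right side bp2; for a tandem duplication the sides are bp2 (left) and bp1
(right).  A plus-strand promoter donor must sit on the left side with its
TSS retained (TSS ≤ junction position); minus-strand donors mirror this.
FUSION requires both sides inside *different* same-strand coding genes;
UPSTREAM requires exactly one side inside a coding gene (donor) and the
other side intergenic, with the nearest same-strand coding TSS at most
`upstream_window` (200 kb) downstream of it.  The 5′/3′ role table that
follows from this orientation argument is validated exhaustively against an
independent derived-chromosome oracle in the test suite.  Design choices
where the published logic is silent:

- the upstream search is re-run over same-strand coding genes rather than
  reusing the annotation slot (whose nearest gene may be opposite-strand or
  non-coding); the distance is measured breakpoint → partner TSS;
- a target position inside a lincRNA blocks the upstream case (coding-only
  applies to both partners);
- two intergenic breakpoints never produce an event (no promoter fragment);
- an SV internal to a single gene is not a promoter substitution;
- multiple overlapping coding genes at a breakpoint resolve to the smallest
  span, then lexicographic id — deterministic and most specific.

Annotation priority (coding overlap → lincRNA overlap → closest upstream
gene on its own strand) uses full gene-body spans; exon structure belongs to
RNA-level analyses that are out of scope.

## Expression screen

Expression is analyzed on log2(x + 1) (pseudocount 1, standard for
RNA-seq-derived matrices).  "Unaffected" samples are all samples of the
cancer type not carrying that pair's event — baselines therefore cannot be
inflated by the event itself, but samples with unrelated alterations are not
excluded.  Promoter strength difference is log2(median5′+1) −
log2(median3′+1) over unaffected samples; per-sample induction is
log2(x+1) − log2(median unaffected + 1).

The global association dichotomizes each (pair, cancer type) at 0 on both
axes (configurable) and applies a two-sided Fisher exact test.  The
recurrent screen restricts to candidates with ≥ `recurrence_min` (2)
distinct affected samples and promoter difference ≥ log2(2), applies a
two-sided pooled-variance t-test (Welch behind a flag, linear scale behind a
flag), and controls BH FDR at `fdr_level` (0.10) *across the candidate set
only* — the analog of screening only gated recurrent cases.  Degenerate
candidates (one affected sample, or zero spread in both groups, detected by
range rather than floating-point variance) keep p = 1 with a flag.  Rank-sum
case tests use exact enumeration when both groups have ≤ 10 observations
and no ties, else the normal approximation with tie correction.

## Synthetic cohorts

The generator emulates the four pipeline inputs.  DNA layer: diploid
baseline; deletions set CN 2→1 with an optional nested 1→0 core, duplications
2→3; the observed amplitude is `log2((p·CN + (1−p)·2)/2) + N(0, σ)` floored
at −8 (the floor avoids −∞ at CN 0, purity 1).  Segment boundaries are
jittered uniformly within ± one probe spacing (2 kb, the SNP-array scale) to
stand in for probe-grid discretization; spurious extra boundaries exercise
merging, and the centromere is emitted as a no-data gap to exercise
gap-filtering.  Planted events keep 2.5 Mb clear of telomeres/centromeres
and 200 kb clear of each other, so recovery tests are not confounded by the
filters.  RNA layer: per-gene, per-cancer-type log-normal baselines (log2
means uniform in [3, 9], σ = 0.5); planted PS pairs get a 4-fold stronger 5′
baseline and an 8-fold 3′ induction in affected samples.  Defaults: 3 × 30
samples, 3 × 100 Mb chromosomes, 60 genes/chromosome (80 % coding, 10 %
lincRNA), purity 0.6 (a realistic tumor-cell fraction), σ = 0.1, ~3
background SVs per sample sized log-uniformly in [50 kb, 2 Mb].  A fixed
seed yields byte-identical outputs; `null_cohort` zeroes only the induction
effects, leaving the DNA layer untouched, for FDR-control tests.

What the generator does **not** model: probe-level intensities and
segmentation error beyond boundary jitter, ploidy ≠ 2, subclonality,
focal complexity (chromothripsis-like patterns), correlated expression
programs, and batch effects.  Passing recovery tests therefore demonstrate
the correctness of the rule logic and statistics under the stated noise
model, not performance on real arrays.

A purity note: at purity exactly 1.0 a single-copy loss has expected
amplitude log2(1/2) = −1, which is precisely the HOMDEL/HEMIDEL boundary;
with symmetric segment noise about half of such deletions classify HOMDEL
and, flanked by NEUTRAL, match no rule.  Deletion recall at purity 1.0 is
therefore ≈ 0.5 by construction (duplications are unaffected; their
amplitude log2(3/2) sits mid-bin).  At any realistic purity below ~0.9 the
deletion amplitude moves off the boundary and recall is high.  This is an
intrinsic property of the threshold scheme, not a tunable defect, and the
recovery numbers reported by `scripts/acceptance.py` reflect it honestly.

## Numerical and engineering choices

- Statistics are delegated to scipy/statsmodels (Fisher exact, t-test,
  Mann–Whitney, BH); the test suite checks them against independent
  enumerations (hypergeometric sums, rank-split enumeration, hand step-up)
  so the delegation is verified, not assumed.
- Concordance matching is greedy one-to-one by smallest total breakpoint
  offset (ties by external input order) with a 100 kb per-breakpoint
  tolerance — the probe-resolution scale — with reciprocal overlap available
  behind a strategy flag.
- Screens and tables are order-invariant: outputs are sorted by (p, pair).
- The CLI (`cnaps`) exposes one subcommand per stage plus `full`; every
  threshold flows through `PipelineConfig` (YAML-loadable) with no hidden
  defaults in code paths.  Problem sizes in the tests and the acceptance
  script (50-sample recovery cohorts, 200 screen replicates, 630-case
  geometry enumeration) were chosen as the smallest sizes at which the
  measured rates are stable.

## Known limitations

- Complex copy-number patterns (e.g. stacked or adjacent events producing
  mixed state runs) are intentionally not interpreted; the rules only fire
  on clean single-segment signatures.
- The upstream case assumes transcriptional readthrough without modeling
  distance decay beyond the hard 200 kb window.
- Promoter strength is proxied by median expression, which conflates
  promoter activity with post-transcriptional stability.
- The t-test's pooled-variance assumption is used as published; with 2–5
  affected samples its power is limited and the Welch flag does not change
  that.
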