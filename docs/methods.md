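# Methods

This note records the models, conventions and design choices behind
`faceenh`, in the order the pipeline runs them.

## Coordinates and interval algebra

All coordinates are 0-based half-open (BED convention) everywhere in
memory; 1-based inputs (dbSNP-style SNP positions) are converted at the
reader boundary. Strand is carried on intervals but ignored by all overlap
logic, because H3K27ac peaks and candidate enhancers are unstranded.
Merging uses bedtools semantics: with `max_gap = 0`, overlapping *and*
bookended intervals merge. Overlap queries are backed by an interval tree;
merge and the TSS filter are single sorted sweeps. The test suite checks
both against brute-force base-wise oracles on random instances.

"Within 1 kb of a TSS" means any ≥ 1 bp overlap with the symmetric window
`[pos − 1000, pos + 1000)` — the standard distal-peak filter — rather than
a midpoint-distance rule. At radius 0 the window degenerates to the single
TSS base.

## Catalog construction

The reproducibility rule is **≥ 2 distinct samples within one week**
(`reproducibility_scope="week"`), which makes catalog membership and the
weekly activity matrix mutually consistent: every catalog enhancer is
active in at least one week. The looser pooled reading (≥ 2 samples at any
stage) is a config switch (`"global"`). Support bookkeeping records, per
region and week, every sample whose peaks overlap the region by ≥ 1 bp.

The stage→week map defaults to wk4={CS13}, wk5={CS14,CS15},
wk6={CS16,CS17}, wk7={CS18,CS19}, wk8={CS20,CS22,CS23}; only the week-7
grouping is fixed by the motivating study design, the rest is a documented
default and configurable.

The TSS filter runs after merging (merge → distal filter → reproducibility),
so a proximal peak can never rescue or split a distal region.

## Temporal classification

Classification operates on the boolean 5-vector only — no signal-magnitude
smoothing. The four classes partition all rows with ≥ 1 active week:
constant (5/5), week-specific (1/5), continuous (2–4 in one run),
non-continuous (the rest). An exhaustive 31-case truth table is asserted in
the tests. All-false rows are a contract violation: under the within-week
rule they cannot arise from the catalog.

## Conservation

`liftover_interval` walks chain blocks and succeeds iff mapped bases /
interval width ≥ `min_match` (default 0.95, the common liftOver default;
the motivating analyses state no threshold) **and** all mapped bases come
from a single chain. Intervals for which several chains qualify are
rejected as ambiguous, mirroring liftOver's split/multiple rule.
Minus-strand chains are flipped to forward coordinates on return. Only
single-direction mapping is implemented (no reciprocal-best check).

The synteny check takes the nearest flanking protein-coding gene on each
side (within a 2 Mb window) and requires **at least one** flanking ortholog
to reappear among the mapped interval's flanking genes (`mode="any"`); the
strict both-flanks mode is a switch. The lenient default avoids discarding
regions that sit next to unannotated orthologs. With no flanking gene in
the window the check passes with nothing to contradict it.

Functional conservation = ≥ 1 bp overlap between the mapped interval and
any target-species peak, pooled over stages. The three statuses partition
the catalog by construction.

## SNP enrichment

LD expansion returns leads ∪ {partners with r² ≥ 0.8}, deduplicated across
studies and populations; unknown lead ids are skipped with a warning
(catalogs never match perfectly). A SNP at position p is inside `[s, e)`
iff s ≤ p < e. The associated set for the 2×2 table is the union of
LD-expanded SNPs over all studies.

The chi-squared statistic uses the clamped Yates form
`max(0, |ad − bc| − N/2)` so near-null tables yield exactly 0 rather than
an inflated discrepancy. A zero cell raises unless the Haldane option is
enabled, which adds 0.5 to all cells for the odds ratio only. Confidence
intervals use the Woolf logit interval.

## TMM normalization and the pair test

TMM follows the standard algorithm: reference = library whose
75th-percentile count fraction is closest to the mean of those fractions;
per library, M = log2 relative fold-change and A = average log abundance
over rows positive in both libraries; rows in the extreme 30% by M or 5%
by A (two-sided) are trimmed; the factor is 2^(precision-weighted mean M)
with inverse delta-method variances as weights; factors are rescaled to
geometric mean 1. One test cross-checks the implementation against edgeR's
`calcNormFactors` on a composition-biased fixture.

Spearman's ρ is the Pearson correlation of mid-ranks (ties averaged); zero
variance in either vector yields NaN, which is excluded downstream. The
Mann–Whitney comparison of pair ρ versus background ρ uses exact
enumeration when both groups have ≤ 8 observations and no cross-group
ties, otherwise the normal approximation with tie and continuity
correction. The default alternative is one-sided *greater* (predicted
pairs are expected to correlate positively); sidedness and tie handling
are our documented choices, as is testing background = all other
enhancer × gene combinations over the tested ids (subsampled to 20,000
when larger).

## Synthetic study generator

The generator emulates the study design, not the sequence: a small
multi-chromosome genome (default 4 × 10 Mb), protein-coding genes on a
jittered ~100 kb grid, and 2,000 non-overlapping 1.5 kb enhancers placed in
slots that keep them ≥ 1 kb plus a jitter margin away from every TSS and
≥ 2.5 kb apart (so jittered peaks from neighbours can never merge).

Defaults are the study conditions: temporal class proportions are the
observed catalog mix (11.6% constant, 45.5% week-specific, 26.9%
continuous, 16.0% non-continuous; drawn multinomially so goodness-of-fit
testing stays honest, with the weekly vector uniform over those consistent
with the class); samples per week {4:3, 5:3, 6:4, 7:6, 8:4} (week 7
richest, as in the motivating panel); peak dropout 0.05 and edge jitter
sd 50 bp; conservation fractions 0.87 alignable / 0.59 functionally
conserved (fractions of the whole catalog); ATAC tracks covering 70% of
week-7 enhancers; a planted SNP odds ratio of 1.27 over 20,000 associated
and ~180,000 background SNPs; 200 true enhancer:gene pairs with coupling
0.6 across 10 matched samples; 130 validated elements of which 29% overlap
an enhancer by ≥ 100 bp.

Mechanics worth knowing:

- *Peaks*: an enhancer active in a week emits a peak per sample with
  probability 1 − dropout; edges get independent Gaussian jitter clamped
  inside the separation margin. Background (false-positive) peaks occupy
  enhancer-free slots; two samples rarely pick the same slot, so the
  catalog occasionally gains a handful of spurious regions — as real
  catalogs do.
- *SNPs*: background SNPs are uniform over the genome, so their
  in-enhancer rate is the enhancer bp fraction p₀. Associated SNPs land
  inside enhancers with probability p₁ solving p₁/(1−p₁) = OR·p₀/(1−p₀),
  planting the odds ratio exactly in expectation. Background SNPs are not
  matched for MAF or LD structure, mirroring the simple catalog partition
  the analysis assumes. LD blocks are bounded by span and gap
  (`ld_block_size`); true partners draw r² ∈ [0.8, 1], decoy partners
  r² ∈ [0.4, 0.79), so the threshold is always exercised and expanding the
  emitted leads at r² ≥ 0.8 recovers the associated set exactly.
- *Chains*: one forward chain per chromosome whose source-side gaps fall
  exactly over the planted non-alignable enhancers; gene order is
  preserved under the monotone map, so synteny holds for all alignable
  regions (synteny failures are exercised by unit fixtures instead).
- *Signal/expression*: log-normal intensities; a true pair's gene shares
  the enhancer's per-sample latent factor with coupling `pair_effect`. One
  library gets a composition bias (30% of rows × 4) so TMM has real work;
  the bias is switchable off for the no-noise checks.

Everything is deterministic given the seed (per-sample streams are derived
from seed, week and a CRC of the sample id), and emitted files round-trip
through the package readers byte-compatibly.

What the generator does **not** model — and hence what passing tests do
not show about real data: read-level noise, peak-caller artifacts,
sequence content, realistic population LD, MAF structure, cell-type
composition shifts across stages, and assembly idiosyncrasies (multiple
overlapping chains, inversions within an interval).

## Problem sizes and numerical choices

Planted-recovery checks run at n = 5,000 enhancers; calibration of the
enrichment test uses 50 replicates at 30,000 associated / ~2,000,000
background SNPs (confidence-interval coverage of a planted OR of 1.3) and
200 replicates under the null; the pair test is checked for null p-value
uniformity over 500 small replicates and for power over 50 replicates at
the default effect. These sizes give sampling noise well inside the
asserted tolerances while keeping the default test run quick.

Ties in ranks use mid-ranks everywhere. Degenerate inputs fail loudly:
empty track lists, mixed assays, all-zero libraries, zero-variance
vectors, all-false activity rows and malformed chains all raise with a
message naming the offender. The catalog keeps the first-seen sorted order
for equal keys (stable sorts throughout), and region ids are assigned in
genome order.

## Known limitations

- The catalog's reproducibility rule is support-count based; it does not
  model peak-calling uncertainty or signal strength.
- Liftover handles one chain per interval; genuinely split mappings are
  reported as not alignable rather than stitched.
- The pair test treats pair correlations as exchangeable; correlations
  sharing an enhancer or gene row are dependent, which is why the null
  calibration uses disjoint background pairs.
- TMM assumes most rows are not differential between libraries; with
  majority composition shifts the trimmed mean is biased, as in any TMM
  implementation.
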