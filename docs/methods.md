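# Methods

This document records the statistical model behind each stage, the default
parameters and why they were chosen, and the known limitations.

## Coordinates and tags

All coordinates are 0-based, half-open `[start, end)`. A sequencing read is
reduced to its 5′ tag position: the record start on the `+` (or unspecified)
strand, `end − 1` on the `−` strand. Tag collections keep per-chromosome
sorted position arrays with parallel strand arrays.

## Simulator

The generator emulates a two-condition histone-mark promoter-profiling
experiment: treated and control chromatin immunoprecipitations, each paired
with a sequenced-input control.

**Occupancy model.** Each gene's promoter occupies
`[tss − h, tss + h)` with `h = tss_half_width` (default 500 bp, giving the
sharp ~1 kb domains typical of active-promoter marks). In a sample with `N`
total tags over a genome of `G` bp, the expected tag count of a promoter
window is

```
fold × (N / G) × 2h
```

— the fold is expressed relative to the depth-normalized genome-average tag
rate — and the uniform background fills the *complement* of the promoter
windows with the remaining probability mass. This design is deliberate: with
a renormalized mixture (background over the whole genome) the effective
treated/control ratio at an unchanged promoter would drift away from 1 by a
compositional factor (~15% at the defaults), so configured folds would not be
true folds. With the complement design the configured alteration fold equals
the exact expected count ratio after depth equalization, which is what makes
the truth table exact rather than approximate.

**Classes.** A fraction of genes (default 60%) carries promoter enrichment
at `base_fold` (default 8) in the control ChIP. Of these, 10% of all genes
gain signal in the treated condition (`fold_up = 4`) and 10% lose it
(`fold_down = 0.25`); the remainder are unchanged (true fold exactly 1).
Input samples are uniform (all folds 1).

**Sampling.** Per sample, a multinomial over (genes…, background) fixes
counts so totals exactly match the configured depths. Each event is a
chromatin fragment: a midpoint uniform in its promoter window (or in the
background complement), a length uniform in 100–300 bp (sonication range),
a random strand, and one 5′ tag at the fragment start (`+`) or end − 1
(`−`). TSSs are placed with a minimum spacing of 4,100 bp so ±2 kb promoter
windows never overlap, keeping gene-level truth unambiguous.

**Depths.** Defaults are 380k / 250k (control input / ChIP) and
200k / 230k (treated input / ChIP): unequal on purpose, with the control
library deeper than the treated one, so the depth-normalization path is
always exercised. The scale (~1M tags total, 10 Mb genome) keeps a full run
at a few seconds while leaving >100 expected tags per enriched promoter.

**Seeding.** One integer seed fans out to independent substreams (gene
placement, tag sampling, term annotation) via `SeedSequence.spawn`, so the
same genes are produced regardless of how many samples are drawn.

## Depth normalization

The two ChIP libraries are compared directly by region counts, so the deeper
one is randomly subsampled without replacement to the depth of the shallower
one (exact target size, uniform inclusion, order-preserving, deterministic
given a derived seed). Input samples are *not* subsampled by default:
ChIP-versus-input comparisons scale the input expectation by the depth ratio
instead, so no input information is discarded
(`normalize.subsample_inputs: true` restores physical subsampling).

## Peak calling

A simplified two-sample window model. Tags are extended `fragment_length`
(default 200 bp, the sonication-range midpoint) 3′-ward into fragments; the
genome is tiled with non-overlapping 100 bp windows; a window's count is the
number of fragments overlapping it. The expectation is

```
λ = max(input_count × depth_ratio, genome_rate × width, floor × width / window)
```

(the per-window input count scaled to ChIP depth, the ChIP sample's
genome-average window count, and a small floor `min_background_lambda = 0.1`
that guards against λ → 0 in input-empty windows). Windows with upper
Poisson tail `P(X ≥ count) < 0.05` are kept and runs separated by at most one
window width are merged into peaks. BH q-values over all windows are
reported alongside, but selection is by raw p < 0.05. Omitted on purpose:
fragment-size estimation, multi-scale local λ, duplicate filtering.

## Differential regions

Peaks from the two conditions are matched by transitive genomic overlap;
each group becomes one region spanning the union extent, flagged by which
condition(s) contributed peaks. Over each region the depth-normalized
fragment counts `(c, t)` are re-counted, the fold change is pseudocounted,
`(t + 1) / (c + 1)`, and the p-value is the exact two-sided binomial test of
`t` out of `n = c + t` at proportion 1/2 — the conditional form of comparing
two equal-depth Poisson counts.

**Matched-only gene qualification.** Regions arising from a peak in a single
condition are retained in the regions table (gain/loss of a peak is real
signal), but by default (`promoter.require_both: true`) only regions with
peaks in *both* conditions qualify genes. A single-source region exists
precisely because one condition's counts spiked; conditioning the binomial
test on that selection event makes it anticonservative (measured ~20% false
positives on truly unchanged promoters versus the 5% nominal), roughly
doubling gene-level FDR. On matched regions the null test holds its size
(measured null log2-fold SD 0.150 versus 0.149 theoretical; null
false-positive fraction consistent with zero).

## Promoter annotation

A region qualifies a gene when it overlaps the window of 2,000 bp on either
side of the TSS, inclusive at the boundary and strand-symmetric. Per gene
the representative region is the one with the smallest p-value (ties:
smallest TSS distance, then leftmost). Gene-level BH q-values are computed
across the table; up/down gene lists use raw p < 0.05, capped at the top
2,000 by p-value.

## Enrichment

Up- and down-regulated gene lists are tested against a term→genes annotation
with the one-sided hypergeometric tail and its EASE variant (overlap reduced
by one before taking the tail, so single-gene overlaps are never
significant); EASE is the default because it is the more conservative of the
two. The universe defaults to the genes that entered the gene table. BH
q-values across tested terms.

## Reporting and recovery

TSS density profiles count fragment overlaps in 50 bp bins across ±2 kb,
orientation-corrected for minus-strand genes, scaled per million tags — the
same counting definition as the peak caller. Recovery metrics against
simulation truth: per-class sensitivity (reported at p < 0.05 *and* correct
direction), observed FDR (fraction of reported genes that are truly
unchanged) and direction accuracy among reported truly-altered genes.
qPCR validation arithmetic (2^−ΔΔCt) is provided for completeness.

## Numerical and engineering choices

- Established implementations are used for the standard distributions
  (scipy's Poisson/hypergeometric tails and exact binomial test,
  statsmodels' BH); the test suite independently verifies them against
  direct series summation, exact rational-arithmetic enumeration and
  brute-force references.
- All floating output uses `%.6g`; logs contain no timestamps; a SHA-256
  manifest is written per run, and identical config + seed reproduce every
  output byte for byte.
- The largest-remainder method apportions genes across chromosomes, and
  multinomial draws pin per-sample tag totals exactly.

## Limitations

- The simulator has no duplicate reads, no mappability/GC structure, no
  copy-number variation and no fragment-length mismatch between conditions;
  the caller correspondingly omits duplicate filtering and local-λ scans.
- The binomial region test assumes the two normalized ChIPs differ only at
  the tested region; genome-scale composition shifts (e.g. a large fraction
  of the genome changing) would bias it.
- Single-source regions are reported but deliberately excluded from
  gene-level claims (see above); analyses that need gain/loss calls should
  treat those regions with a selection-aware test.
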