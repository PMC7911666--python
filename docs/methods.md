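# Methods

## Coordinate and tiling conventions

All intervals are 0-based half-open (BED/bedGraph convention) internally
and in every file the package writes; helpers convert a 1-based
fully-closed dialect losslessly. Bins (5 kb) and segments (200 kb) tile
each chromosome from position 0 at fixed positions; the final partial
interval at a chromosome end is retained and flagged rather than dropped,
so coverage accounting is exact. Bin positions for smoothing are taken on
the uniform nominal grid `index · bin_size`; the sub-bin offset of a final
partial bin is ignored, which changes nothing for full bins and at most
half a bin width for one bin per chromosome.

## Timing profiles

Each early/late library is scaled to one million reads. The per-bin timing
value is `log2((E + c)/(L + c))` with pseudocount `c = 1` per-million unit;
bins whose combined raw count is below 10 reads are masked as unreliable.
Both choices are pragmatic guards against zero counts and are exposed as
parameters; the pseudocount only matters in bins the coverage mask would
usually remove anyway.

LOESS smoothing is degree-1 local regression with tricube weights over a
fixed genomic span (default 300 kb, i.e. ±150 kb around each bin), fitted
per chromosome with masked bins excluded; no robustness iterations. The
fixed genomic span — rather than a global point fraction — keeps the
effective bandwidth constant across chromosomes of different lengths. The
local weighted-least-squares solution is evaluated through exact moving
weighted moments (a closed form of the normal equations), so it agrees
with a naive per-bin WLS fit to machine precision while running in
O(window) per bin; a window with a degenerate design (a single usable
point) falls back to the local weighted mean, and a chromosome with fewer
than two unmasked bins is emitted fully masked with a warning.

Segment values are the mean of unmasked bin values in each fixed 200-kb
window; segments with under 50% valid bins are masked. **The segment-level
statistics are computed from the unsmoothed bin ratios.** Smoothing over
±150 kb would bleed a genuine single-segment timing change into both
neighbouring segments and make neighbour calls indistinguishable from real
switches; the 200-kb averaging already provides the noise pooling the
statistic needs, while LOESS profiles serve visualization and bin-level
analyses. This is the package's design choice where common practice varies.

## Switching statistic and FDR

With replicate segment tracks for two groups, the between-group statistic
per segment is the absolute difference of group means (for more than one
replicate per group this is the distance between replicate-mean values; the
two-replicate case the design targets reduces to it exactly). The empirical
null pools within-group replicate differences across all segments and both
groups. Because `Var(mean_A − mean_B) = s²(1/n_A + 1/n_B)` while a single
replicate pair difference has variance `2s²`, the pool entries are scaled
by `sqrt((1/n_A + 1/n_B)/2)`; under the null the statistic and the pool
entries are then draws from the same per-segment scale mixture, making the
empirical p-values marginally uniform — the property FDR estimation
requires. An uncalibrated pool (the raw replicate differences) is available
via `calibrate=False` and yields conservative p-values.

P-values use the add-one rule `p = (1 + #{null ≥ d})/(1 + N)` so that no
p-value is zero. Q-values follow Storey's procedure with the fixed-λ
estimator `π₀ = #{p > 0.5}/(0.5·m)` capped at 1 — simple and reproducible;
the spline-smoothed λ→1 extrapolation is deliberately out of scope. A
`π₀ = 1` mode reduces exactly to Benjamini–Hochberg adjusted p-values and
is cross-checked against an independent implementation in the tests. The
empirical-p granularity floors attainable q at roughly `m/(N·rank)`;
with two replicates per group, calling at q ≤ 0.01 therefore needs on the
order of thousands of segments — genome scale, not toy scale.

Classification uses 0 on the log2(E/L) scale as the early/late boundary,
applied to replicate-averaged group means: a significant segment with
control mean > 0 and negative delta is EtoL, the mirror case LtoE;
significant segments that moved within their compartment (early → earlier)
and all non-significant segments are labelled by endpoint signs
(EtoE/LtoL; a non-significant segment whose means straddle zero takes the
control side's label, since its change is not trusted). Adjacent segments
with identical class and significance merge into domains whose q is the
minimum member q. Overlap between two call sets is scored with the exact
hypergeometric upper tail against a universe of analyzable segments, with
the expected overlap `|A|·|B|/universe` reported alongside.

## Synthetic data generator

The generator emulates the study design so that every pipeline stage has
known ground truth. What it models — and what it deliberately does not:

- **Timing landscape**: domain boundaries from a Poisson process (default
  mean 1 Mb) with per-domain levels from an equal mixture of
  Normal(+1.5, 0.5) and Normal(−1.5, 0.5), the early/late dichotomy of
  Mb-sized replication domains. Real genomes also contain timing
  transition regions and copy-number/mappability artefacts; none are
  modelled, so passing tests say nothing about copy-number robustness.
- **Planted switches**: whole 200-kb segments shifted by ±Δ (default 1.5).
  Only segments with |mean rt| ≥ 0.5 are eligible — a segment at the
  early/late boundary has no well-defined switch direction, so the planted
  truth is restricted to unambiguous cases. The edit bookkeeping is exact
  and recoverable by diffing the two landscapes.
- **Counts**: the latent bin timing plus per-replicate iid Normal(0, 0.3)
  noise maps to an early-read weight through the logit-base-2 link
  `p = 1/(1 + 2^(−rt))`, so `rt = log2(p/(1−p))` lives on the same scale
  the pipeline estimates; early/late libraries draw Poisson counts
  proportional to `p` and `1−p` at ~20 reads/bin/fraction with library
  sizes jittered ±20%. Library normalization leaves a global composition
  constant `log2(Σ(1−p)/Σp)` in the estimated profile, exactly as in real
  data; it is ~0 for a balanced genome. Replicate noise on the latent
  timing (not on counts) is what the within-group null must absorb —
  the structure the statistic assumes. GC/mappability bias and fragment
  models are not simulated.
- **Omics coupling**: ChIP deltas are `r·z + sqrt(1−r²)·ε` with `z` the
  standardized RT delta, so the planted Pearson correlation is exactly
  `r`; gene log2 fold changes use the same construction through the
  gene's segment, scaled by `fc_sd`. Genes are uniform over the genome —
  no clustering, no multi-TSS genes.
- **Fibers**: origins fire synchronously at the start of the first pulse;
  each lays a central first-label track (2·v·t₁) flanked by second-label
  tracks (v·t₂), with converging forks stopping at inter-origin midpoints
  and same-label tracks merging. Inter-origin spacings are Gamma with
  cv = 0.25 (default mean 120 kb): origin interference makes real spacings
  far more regular than a memoryless process, and exponential spacings
  would merge ~⅓ of signatures at 20-min labels, censoring the truth the
  recovery tests score against. Track boundaries get Normal(0, 0.15 µm)
  measurement jitter; λ molecules are Normal(48.5/stretch, 1.0 µm).
  Asynchronous firing, second-pulse-only origins and fiber breakage are
  not modelled.

Defaults (2 Gb genome → 10,000 segments, depth 20/bin/fraction, noise
0.3, 5% switches at |Δ| = 1.5, 150 molecules with 120-kb spacing and
1.2 kb/min forks) are the package's study conditions: large enough that the
empirical-p floor sits well below the 0.01 cutoff, small enough that the
full evaluation suite runs in seconds.

## Fiber measurement rules

The stretch factor is `48.5 kb / mean(λ length)` with its s.d. propagated
by the delta method (`48.5·sd/mean²`). The factor is treated as kb/µm:
a 48.5-kb λ genome combing to ~21 µm gives ~2.3 kb/µm, and all printed
lengths in the µm range are only consistent with that unit reading.

Fork speed is measured on second-label tracks only — a first-label track
at an origin spans two forks, while a second-label track bounded by one
first-label neighbour records a single fork over the full, known pulse
time. Tracks bridging two first-label tracks (converged forks) and tracks
touching a molecule end (censored length) are excluded; the end exclusion
avoids the downward bias of broken-fiber fragments. Origins are reported
at the midpoint of first-label tracks abutted by second-label tracks on
both sides; "abutting" tolerates 1 µm of positional noise — about four
times the simulated measurement jitter and an order of magnitude below
genuine unreplicated gaps — because a tolerance at the jitter scale breaks
~5% of true signatures and inflates spacing estimates by summing across
missed origins. Inter-origin distances are center-to-center between
adjacent origins on one molecule, pooled across molecules; sampling
spacings inside finite molecules under-represents long spacings, a bias of
about −1.5 kb at the default 6.7× molecule-to-spacing ratio (documented,
not corrected). A Mann–Whitney rank-sum comparison is provided for
two-condition fiber contrasts.

## Numerical and degenerate-input choices

- Empirical p-values count ties as "at least as extreme" (`null ≥ d`).
- Q-value step-up uses a stable mergesort; q is clipped into (0, 1] and is
  invariant to input order. NaN (masked) entries pass through all
  statistical stages without contributing to m or the null.
- Top-percentile selection takes `⌈pct/100 · n⌉` finite values with ties
  broken by coordinate order, so selections are deterministic.
- Fisher odds ratios use the Haldane 0.5 correction only when a cell is 0.
- bedGraph intervals not aligned to the bin grid are length-weighted onto
  overlapping bins (totals conserved); overlapping intervals are an error,
  not silently summed. Masked bins are omitted on write; on read, bins
  without coverage are 0 by default or masked on request.
- All generators are deterministic under a fixed seed and accept either an
  integer or a `numpy.random.Generator` for stream chaining.

## Known limitations

- Two S-phase fractions only; no multi-fraction timing deconvolution.
- No copy-number, GC or mappability correction; inputs are assumed
  pre-filtered to analyzable regions.
- The within-group null assumes exchangeable replicates and pools a single
  genome-wide null; per-segment variance differences enter only through
  the scale mixture the pool itself inherits.
- Expression analysis consumes a pre-normalized expression matrix and a
  single TSS per gene.
- Fiber analysis assumes the first/second label order is known and that
  molecules are individually calibrated by a common stretch factor.
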