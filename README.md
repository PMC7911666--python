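# replikit

Replication-timing (Repli-seq) analysis for two-condition comparisons:
early/late S-phase log2-ratio profiling, detection of replication-timing
switching domains with false-discovery-rate control, integration with
ChIP-seq and expression changes, and DNA-combing fork measurements — all
backed by a ground-truth synthetic-data generator so every stage is testable
without sequencing data.

## Who this is for

Groups comparing genome-wide replication timing between two cell states
(e.g. a chromatin-modifier knockout against its parental line) from
early/late S-phase fractionated, BrdU-enriched sequencing libraries, who
need per-segment statistical calls ("this 200-kb window switched from early
to late replication") rather than just browser tracks, plus the usual
companion analyses: does the timing change track a histone mark, does it
track transcription, and do single-molecule fork measurements change.

## The model

**Profiles.** Reads from the early (E) and late (L) fraction are counted in
5-kb bins, each library is normalized per million reads, and replication
timing per bin is `RT = log2((E + c)/(L + c))` (pseudocount `c = 1`;
positive = early replicating). Display profiles are LOESS-smoothed
(degree-1 local regression, tricube weights) over a fixed 300-kb genomic
span per chromosome.

**Switching segments.** Unsmoothed bin ratios are averaged into
fixed-position 200-kb segments per replicate. For each segment the
between-group statistic is

    d_i = | mean(RT over control replicates) − mean(RT over mutant replicates) |

and the empirical null pool collects the within-group replicate differences
|RT_rep_j − RT_rep_k| over all segments and both groups, scaled by
`sqrt((1/n_ctrl + 1/n_mut)/2)` so the pool has the sampling variance of a
difference of group means. Per-segment p-values are add-one null ranks,
`p_i = (1 + #{null ≥ d_i}) / (1 + N)`, converted to Storey q-values
(π₀ from the fixed-λ = 0.5 estimator; a π₀ = 1 mode reproduces
Benjamini–Hochberg exactly). Significant segments (q ≤ 0.01
high-confidence, q ≤ 0.05 lower-confidence) that were early in control
(mean RT > 0) and moved later are **EtoL** switches; late-to-earlier are
**LtoE**; everything else is non-switching EtoE/LtoL. Adjacent same-class
segments merge into domains; set overlaps between call sets are scored with
a hypergeometric tail test.

**Integration.** Per-segment ChIP enrichment changes correlate against RT
deltas (Pearson R), are summarized per switch class (Tukey box statistics),
and ranked into top 1/5/10% gain/loss sets. Genes map to segments by TSS;
enrichment of gene sets (e.g. >2-fold upregulated) in switch classes uses a
two-sided Fisher exact test.

**Fibers.** Combed λ-DNA (48.5 kb) calibrates stretch in kb/µm; a fork's
speed is its second-label (CldU) track length × stretch / 20 min; origins
are midpoints of second–first–second track signatures and origin spacing is
the center-to-center distance of adjacent origins on one molecule.

## Worked example

Simulate a 40-Mb toy genome with 8 planted switching segments, build
per-replicate ratio tracks, and call switches:

```sh
printf 'chr1\t20000000\nchr2\t20000000\n' > toy.chrom.sizes
replikit simulate --genome toy.chrom.sizes --seed 3 --n-switch 8 --out sim/
for c in ctrl mut; do for r in 1 2; do
  replikit profile --genome toy.chrom.sizes \
    --early sim/${c}_rep${r}.early.bedgraph --late sim/${c}_rep${r}.late.bedgraph \
    --span-kb 0 --out ${c}_rep${r}.ratio.bedgraph
done; done
replikit diff --genome toy.chrom.sizes \
  --ctrl ctrl_rep1.ratio.bedgraph --ctrl ctrl_rep2.ratio.bedgraph \
  --mut mut_rep1.ratio.bedgraph --mut mut_rep2.ratio.bedgraph \
  --q 0.05 --out switch
```

prints

```
EtoL    8
LtoE    2
```

and `switch.calls.tsv` holds one row per 200-kb segment:

```
chrom  start   end     delta   d       p       q       class  significant
chr1   0       200000   0.159  0.159   0.157   0.500   LtoL   False
chr1   400000  600000  -1.408  1.408   0.0025  0.0414  EtoL   True
```

The 10 significant segments include all 8 planted switches (the planted
truth is written to `sim/truth_switches.bed`); two extra calls at q ≤ 0.05
are the expected price of the 5% FDR level on 200 segments. `delta` is
mutant-minus-control timing, `d` the between-group statistic, and `q` the
estimated false-discovery rate if every segment down to this one is called.
`switch.domains.bed` carries the merged switch domains with BED scores
`round(1000·(1−q))`.

The same steps are available as library calls (`simulate_rt_landscape`,
`plant_switches`, `simulate_counts`, `profile_pipeline`,
`average_into_segments`, `switch_analysis`, …); `replikit integrate` and
`replikit fibers` cover the omics and combing analyses.

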