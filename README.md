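# tilefate

Massively parallel reporter assays for RNA fate insert thousands of short
sequence fragments ("tiles", typically 110–140 nt) into a common reporter
backbone — linear spliced or unspliced mRNAs, or circular RNAs — and read
out, by pooled amplicon sequencing of fractionated cells, how each tile
shifts the host RNA's subcellular localization, expression and stability.
`tilefate` is the computational side of such an experiment: it turns raw
UMI-tagged reads into tile-level count matrices, localization and expression
ratio statistics, half-life estimates, back-splice-junction circRNA
quantification, and motif / eCLIP-cluster association analyses. A
ground-truthed synthetic-data generator stands in for raw sequencing data,
so every stage is testable end to end on a laptop.

## The statistics at the core

**Read matching.** Each R1 read is `[UMI][adapter][tile insert]`. A read is
assigned to the tile with the fewest mismatches under gapless comparison,
where mismatches are allowed only at positions with base quality ≥ 35, at
most 2 may fall in the first 15 nt (the seed) and at most 4 overall; ties at
the minimum are discarded as ambiguous. Counts collapse to distinct UMIs per
tile by default.

**Localization.** With pseudocount c = 0.5 and per-sample normalization to
counts-per-million N(·), each replicate pair gives

    log2 ratio_i = log2( N(nuc_i + c) / N(cyto_i + c) ),

tiles needing ≥ 20 raw reads in both members. A tile is called *nuclear*
when median_i(ratio) > 0.3 with P < 0.05 (two-sided one-sample t-test of
replicate ratios against 0), *cytoplasmic* below −0.3 with P < 0.05.
Group-level contrasts (G/C, motif strata) use the two-sided Wilcoxon
rank-sum test, exact for small tie-free groups.

**Stability.** After transcription shutoff, spike-normalized levels y(t)
relative to t = 0 are fitted by OLS on the log2 scale, and

    t_1/2 = (log2(0.5) − intercept) / slope,

undefined (NaN) when the slope is non-negative.

**circRNAs.** Chimeric junction records support an annotated circRNA when
both breakpoints lie within 5 nt of its boundaries; circRNAs are kept with
≥ 10 read pairs in at least one sample, ≤ 5 exons, and ≤ 5 kb mature
length, then ratioed with the same pseudocount/CPM convention.

## Worked example

```bash
tilefate run --seed 5 --out-dir demo_run
```

runs the full synthetic pipeline (40 tiles of 110 nt, three replicate
nuclear/cytoplasmic/WCE samples, a 4-timepoint decay series, 12 simulated
circRNAs, motif stratification) and finishes in seconds, printing

```
pipeline complete; outputs under demo_run
```

`demo_run/` then holds diffable TSVs: `counts.tsv` (tile × sample UMI
counts), `match_stats.tsv` (per-sample matched / no-adapter / unmatched /
ambiguous totals, which always sum to the read total), `localization.tsv`
(median log2(Nuc/Cyto), t-test P, class), `half_lives.tsv` (per-tile
intercept, slope, r², half-life against the simulated truth),
`circ_quant.tsv` (filtered junction counts with log2(Nuc/Cyto)), and
`motif_strata.tsv`. The same stages are exposed individually
(`tilefate simulate|count|localize|stability|circquant|annotate`) for real
input files.

The `analysis/` directory walks the same pipeline as numbered scripts at a
larger scale (120 tiles, 600 reads/tile/fraction). A representative run
prints, for step 03:

```
localization calls: {'cytoplasmic': 40, 'unclassified': 40, 'nuclear': 40}
sign recovery on shifted tiles: 100.0% (n=80); false calls on null tiles: 0.0% (n=40)
```

meaning every tile simulated with a ±1 log2 shift was called in the correct
fraction and no unshifted tile was called localized — and, for step 04,
per-tier half-life medians within ~10% of the simulated 1/2/4/8 h truths
under 10% multiplicative noise.

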