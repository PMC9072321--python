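# Methods

## Scope and model

`tilefate` analyzes pooled reporter experiments in which short designed
tiles are embedded in a shared RNA backbone and sequenced as amplicons from
subcellular fractions, timepoints after transcription shutoff, or
circRNA-enriched libraries. The package treats the tile as the unit of
inference throughout: reads are collapsed to tile × sample counts, and all
downstream quantities (log2 Nuc/Cyto, WCE/input, half-life, motif and
cluster associations) are per-tile statistics. The analysis assumes the
amplicon orientation is fixed by the primer design (no reverse-complement
search), that indels in reads are rare enough to ignore at the matching
stage, and that within one sample all tiles share the same capture and
amplification efficiency up to the per-sample factors removed by CPM or
spike normalization.

## Read matching

A read must contain the exact adapter (`TAGGAGGCCTCATCTGACTG` by default)
preceded by a complete UMI; otherwise it is classed `no_adapter`. The
insert (bases after the adapter) is compared gaplessly to each tile from
position 0 over the overlap of the two. A candidate tile is valid when

* every mismatch sits at a position with Phred quality ≥ `quality_min`
  (default 35) — note the rule *permits* mismatches only at high-quality
  positions, so a low-quality mismatch invalidates the candidate;
* mismatches in the first `seed_length` = 15 compared positions number
  ≤ 2, and ≤ 4 overall.

The unique valid candidate with the fewest total mismatches wins; a tie is
`ambiguous` and discarded; no valid candidate is `unmatched`. The four
statuses partition the input, an invariant the tests assert on random
fixtures.

`match_read` scores every tile (reference semantics). `count_tiles` uses a
pigeonhole index: each tile's compared region is cut into
`max_total_mm + 1 = 5` contiguous pieces, so any tile within 4 mismatches
of the insert must agree exactly on at least one piece and is retrieved by
hashing the insert's pieces. The index can therefore never miss a valid
candidate, and the two paths are asserted equal in the tests (and `match_read`
against an independently written brute-force scorer). Counting collapses
exact-match UMIs per tile per sample by default — UMIs exist to remove
amplification duplicates — with `count_mode="read"` available to count raw
reads instead. The UMI length is not dictated by the protocol text and
defaults to 10 nt; it is configuration, as is everything else in
`MatcherConfig`.

## Localization statistics

Pseudocount before normalization: 0.5 is added to *raw* counts and each
sample column is then scaled to 10^6 total. The order matters — a
count-scale pseudocount applied after CPM scaling would be meaningless —
and the chosen order makes `log2(N(num+0.5)/N(den+0.5))` finite for all
tiles passing the ≥ 20-read floor, which is enforced per pair in *both*
members. Per-tile significance is a two-sided one-sample t-test of the
replicate log2 ratios against 0: the simplest replicate-level test
compatible with a per-tile P at n = 3 replicates. It is computed in
`summarize_ratios` and could be swapped without touching the call rule. No
multiple-testing correction enters the classification (an effect-size
threshold of ±0.3 is applied jointly with raw P < 0.05); a
Benjamini–Hochberg FDR column is emitted for reference. With a single
replicate the class falls back to the threshold alone and P is reported
absent. Context-versus-context agreement uses Spearman correlation on the
intersection of quantified tiles, requiring ≥ 3 shared tiles.

Group contrasts use the Mann–Whitney/Wilcoxon rank-sum test (scipy),
exact when both groups have ≤ 10 observations and no ties, otherwise the
tie-corrected normal approximation; the tests verify exactness against
full enumeration of rank partitions.

## Stability

Levels are divided by the summed spike-in counts of their sample (two
spike species, emulating dual input concentrations, are summed first), then
expressed relative to the t = 0 sample of the same series, and
log2-transformed for OLS against time. Half-life is
`(log_b(0.5) − intercept)/slope` with b = 2, so the slope is in halvings
per hour and the numerator is −1; the base is configurable because the
protocol formula leaves it open, and with t=0 normalization the intercept
is ≈ 0 so the choice of base cancels in the ratio. Nonpositive levels are
dropped with a warning; fewer than two distinct timepoints yields no fit;
slope ≥ 0 yields half-life NaN (undefined, not an error). Replicate samples
at the same timepoint enter the regression as extra points rather than
being averaged, which weights timepoints by their replication.

## circRNA quantification

Annotations are 0-based half-open genomic spans (BED convention); junction
records keep their aligner's 1-based positions; the conversion lives in one
place (`_boundaries_1based`). A record supports an annotation when both
breakpoints are within the 5-nt tolerance on the same chromosome and a
compatible strand ('.' matches either, as unstranded protocols exist).
Records within tolerance of several annotations go to the smallest summed
boundary distance; exact ties are counted for all tied annotations and
flagged rather than silently dropped or double-counted invisibly. Retention
filters: ≥ 10 supporting pairs in at least one sample, ≤ 5 exons, ≤ 5 kb
mature length. Ratios reuse the tile pseudocount/CPM convention, so the
two ratio paths cannot drift apart.

## Motifs, clusters, folding

Motifs are inputs (IUPAC strings or 4×w PWMs with a log2-odds threshold
against a uniform background); no motif is shipped as ground truth because
the relevant binding models are study-specific — the examples use a
purine-rich consensus. Counting is non-overlapping left-to-right with
restart after each match; stratification into 0 / 1 / >1 bins is
insensitive to that policy, but an overlapping mode exists. eCLIP clusters
are filtered at P < 0.01 and ≥ 2-fold enrichment over input (narrowPeak
pValue columns, conventionally −log10, are converted to probabilities on
read). Interval intersection is a native sorted `searchsorted` sweep —
count = #(starts < feature.end) − #(ends ≤ feature.start) per
chromosome/strand group — verified against an all-pairs oracle; no
external binary is shelled out for it. Folding ΔG is the one external-tool
hook (`RNAfold`); when the program is absent the column is absent and the
pipeline continues.

## Synthetic data: what it does and does not emulate

The generator emulates the measurement chain, not the biology: true shifts
and half-lives are parameters. Reads are `[UMI][adapter][insert]` with
substitution-only errors confined to the insert — the matcher forbids
indels, so simulated indels would only land in the unmatched class; an
optional indel rate exists precisely to exercise that accounting — and
Phred qualities drawn from a rounded normal(37, 4) truncated to [2, 41],
chosen to straddle the Q35 rule so the quality filter is genuinely
exercised. Fraction allocation is symmetric: a tile with shift δ has
expected depth·2^(δ/2) nuclear and depth·2^(−δ/2) cytoplasmic reads, so the
expected count ratio is 2^δ while the library-wide totals stay balanced.
Per-tile counts are Poisson; UMIs are drawn uniformly, so collisions occur
at observable rates at high depth. Decay series carry a per-sample scale
factor shared by tiles and spikes (making spike normalization
identifiable) and multiplicative lognormal noise parameterized by its CV.
Junction records are boundary positions plus rounded-normal jitter with
Poisson support.

Not emulated: PCR duplication structure beyond UMI reuse, quality-dependent
error profiles, position-dependent error rates, splicing or circularization
efficiency, partial-degradation bias across a transcript, and any coupling
between sequence content (G/C, motifs) and true localization unless
explicitly injected. Passing tests therefore demonstrate that the
*computational* chain recovers known parameters under realistic sampling
noise — not that the biological assumptions hold in real libraries.

Default problem sizes (e.g. 300 tiles × 2,000 reads/tile/fraction × 3
replicates for the recovery experiment, 1,000 reads for oracle comparison,
40 tiles × 4 tiers for decay) were chosen to give comfortable statistical
power for the recovery margins while keeping a full run in the minutes
range on one CPU.

## Numerical and degenerate-input choices

* Tie at minimum mismatches → ambiguous (never order-dependent); tile
  iteration order cannot affect outcomes otherwise, asserted by test.
* Truncated UMI (adapter too close to the read start) is classed
  `no_adapter`: the `[UMI][adapter]` structure was not found intact.
* Empty insert/tile overlap is an invalid candidate, not an error.
* All-zero count columns, zero spike totals, unknown sample names, missing
  annotations, infeasible G/C ranges: explicit `ValueError`s naming the
  offender, never silent repair.
* r² is clamped to [0, 1] against floating-point residue; a zero-variance
  response defines r² = 1.
* Identical nonzero replicate ratios give a degenerate t statistic; the
  implementation treats them as maximally significant (P = 0), which only
  matters on noiseless synthetic data.
* TSV outputs use `%.6g` floats so reruns are byte-identical and diffable.

## Known limitations

The per-tile test at n = 3 replicates has limited power for small shifts;
the classification is intentionally conservative (joint effect-size + P
rule). The matcher's exact-adapter requirement means adapter-region
sequencing errors cost the whole read. Junction parsing accepts a single
tab-separated dialect and does not attempt annotation-free circRNA
discovery. The pipeline's CLI `run` command orchestrates the synthetic
demo; real-data runs compose the stage subcommands, which operate on
standard FASTQ/TSV/BED inputs.
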