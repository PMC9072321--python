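#!/usr/bin/env python
"""Nuc/Cyto ratio statistics, localization calls, and recovery vs truth.

Computes pseudocounted CPM-normalized log2(Nuc/Cyto) per replicate pair,
calls tiles nuclear/cytoplasmic with the |median| > 0.3 and P < 0.05 rule,
then scores the calls against the simulated ground truth and compares G/C
content between localization classes with the rank-sum test.
"""

import argparse
from pathlib import Path

import pandas as pd

from tilefate import (
    TileLibrary,
    call_localized_tiles,
    compute_ratios,
    gc_content,
    group_comparison,
    summarize_ratios,
)

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

counts = pd.read_csv(args.out / "counts.tsv", sep="\t", index_col=0)
lib = TileLibrary.from_tsv(args.data / "library.tsv")
truth = pd.read_csv(args.data / "ground_truth.tsv", sep="\t", index_col=0)

pairing = [(f"nuc_rep{r}", f"cyto_rep{r}") for r in (1, 2, 3)]
ratios = compute_ratios(counts, pairing, pair_names=["rep1", "rep2", "rep3"])
table = call_localized_tiles(summarize_ratios(ratios))
table.to_csv(args.out / "localization.tsv", sep="\t", float_format="%.6g")

merged = table.join(truth["shift_log2"])
shifted = merged[merged["shift_log2"] != 0]
correct = ((shifted["shift_log2"] > 0) & (shifted["localization"] == "nuclear")) | \
          ((shifted["shift_log2"] < 0) & (shifted["localization"] == "cytoplasmic"))
null = merged[merged["shift_log2"] == 0]
false_calls = (null["localization"] != "unclassified").mean()
print(f"localization calls: {table['localization'].value_counts().to_dict()}")
print(f"sign recovery on shifted tiles: {100 * correct.mean():.1f}% "
      f"(n={len(shifted)}); false calls on null tiles: "
      f"{100 * false_calls:.1f}% (n={len(null)})")

gc = pd.Series({tid: gc_content(s) for tid, s in lib.sequences.items()})
cyto = gc[merged.index[merged["localization"] == "cytoplasmic"]]
rest = gc[merged.index[merged["localization"] != "cytoplasmic"]]
if len(cyto) and len(rest):
    _, p = group_comparison(
        pd.concat([cyto, rest]).to_numpy(),
        ["cyto"] * len(cyto) + ["rest"] * len(rest))
    print(f"G/C cytoplasmic vs rest: medians {cyto.median():.3f} vs "
          f"{rest.median():.3f}, rank-sum P = {p:.3g} "
          "(no G/C-localization coupling is built into the generator)")
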