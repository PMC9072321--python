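"""Normalization, pseudocounted log-ratios, localization calls, group tests.

The central quantity is the per-tile log2(Nuc/Cyto) ratio: raw counts get a
pseudocount of 0.5, each sample column is scaled to counts-per-million so a
tile's level is relative to the overall expression of all tiles in the same
fraction, and the ratio of the paired samples is log2-transformed. A tile is
called nuclear when its median replicate ratio exceeds +0.3 with P < 0.05,
cytoplasmic below -0.3 with P < 0.05 (the 0.3 cutoff corresponds to roughly
a 25% abundance difference), and unclassified otherwise. WCE/input ratios
(expression conferred by a tile relative to its plasmid-pool representation)
use the identical convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

CPM_SCALE = 1e6

CLASS_NUCLEAR = "nuclear"
CLASS_CYTOPLASMIC = "cytoplasmic"
CLASS_UNCLASSIFIED = "unclassified"


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample column to a total of 1e6 (CPM convention)."""
    totals = counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"all-zero sample column(s): {list(zero.index)}")
    return counts * (CPM_SCALE / totals)


def compute_ratios(
    counts: pd.DataFrame,
    pairing: list[tuple[str, str]],
    pseudocount: float = 0.5,
    min_reads: int = 20,
    pair_names: list[str] | None = None,
) -> pd.DataFrame:
    """Per-replicate log2 ratios for (numerator, denominator) sample pairs.

    The pseudocount is added to *raw* counts, columns are then CPM-scaled, and
    the ratio is ``log2(norm(num + pc) / norm(den + pc))``. A tile enters a
    pair's ratio only if its raw count reaches ``min_reads`` in *both* members
    of the pair; other tiles get NaN for that pair.
    """
    for num, den in pairing:
        for s in (num, den):
            if s not in counts.columns:
                raise ValueError(f"sample {s!r} not in count matrix")
    norm = normalize_counts(counts + pseudocount)
    if pair_names is None:
        pair_names = [f"{num}/{den}" for num, den in pairing]
    out = {}
    for name, (num, den) in zip(pair_names, pairing):
        ratio = np.log2(norm[num] / norm[den])
        passed = (counts[num] >= min_reads) & (counts[den] >= min_reads)
        out[name] = ratio.where(passed)
    table = pd.DataFrame(out, index=counts.index)
    table.index.name = counts.index.name or "tile_id"
    return table


def summarize_ratios(ratios: pd.DataFrame) -> pd.DataFrame:
    """Per-tile median across replicate ratio columns plus a one-sample test.

    The per-tile significance test is a two-sided one-sample t-test of the
    replicate log2 ratios against 0 (declared here, swappable in principle);
    a tile with fewer than 2 finite replicates gets a NaN P-value. A
    Benjamini-Hochberg FDR column is emitted for reference but never used for
    classification.
    """
    med = ratios.median(axis=1, skipna=True)
    n = ratios.notna().sum(axis=1)
    pvals = np.full(len(ratios), np.nan)
    values = ratios.to_numpy()
    for i in range(len(ratios)):
        row = values[i]
        row = row[np.isfinite(row)]
        if len(row) >= 2 and np.ptp(row) > 0:
            pvals[i] = sps.ttest_1samp(row, 0.0).pvalue
        elif len(row) >= 2:
            # identical nonzero replicates: degenerate t, call by sign
            pvals[i] = 0.0 if row[0] != 0 else 1.0
    out = pd.DataFrame(
        {"median_log2_ratio": med, "n_replicates": n, "pvalue": pvals},
        index=ratios.index,
    )
    finite = np.isfinite(pvals)
    fdr = np.full(len(ratios), np.nan)
    if finite.sum():
        fdr[finite] = sps.false_discovery_control(pvals[finite], method="bh")
    out["fdr_bh"] = fdr
    return out


def call_localized_tiles(
    summary: pd.DataFrame,
    threshold: float = 0.3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Assign localization classes by the joint effect-size + significance rule.

    nuclear: median > +threshold and P < alpha; cytoplasmic: median <
    -threshold and P < alpha; otherwise unclassified. With a single replicate
    (P absent) the class is computed from the threshold alone.
    """
    med = summary["median_log2_ratio"]
    p = summary["pvalue"]
    sig = p.isna() | (p < alpha)  # single-replicate tiles: threshold only
    cls = np.where(
        med.gt(threshold) & sig, CLASS_NUCLEAR,
        np.where(med.lt(-threshold) & sig, CLASS_CYTOPLASMIC, CLASS_UNCLASSIFIED),
    )
    cls = np.where(med.isna(), CLASS_UNCLASSIFIED, cls)
    out = summary.copy()
    out["localization"] = cls
    return out


def group_comparison(values, labels) -> tuple[float, float]:
    """Two-sided Wilcoxon/Mann-Whitney rank-sum test between two groups.

    Exact null distribution when both groups have <= 10 observations and no
    ties across groups; normal approximation with tie correction otherwise.
    Returns (U statistic of the first group, two-sided P).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, got {list(uniq)}")
    x = values[labels == uniq[0]]
    y = values[labels == uniq[1]]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    no_ties = len(np.unique(values)) == len(values)
    method = "exact" if (len(x) <= 10 and len(y) <= 10 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return (float(res.statistic), float(res.pvalue))


def gc_content(seq: str) -> float:
    """Fraction of G/C bases; accepts DNA or RNA, any case."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def context_correlation(
    tables: dict[str, pd.Series],
    min_overlap: int = 3,
) -> pd.DataFrame:
    """Spearman correlation of per-tile median ratios between contexts.

    Each entry uses the intersection of tiles quantified (finite) in both
    contexts; pairs with fewer than *min_overlap* shared tiles get NaN.
    """
    names = list(tables)
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            sa, sb = tables[a].dropna(), tables[b].dropna()
            shared = sa.index.intersection(sb.index)
            if len(shared) < min_overlap:
                mat.loc[a, b] = mat.loc[b, a] = np.nan
                continue
            rho = sps.spearmanr(sa.loc[shared], sb.loc[shared]).statistic
            mat.loc[a, b] = mat.loc[b, a] = rho
    return mat
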