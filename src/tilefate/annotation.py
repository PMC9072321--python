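"""Sequence and interval annotations: RBP motifs, eCLIP clusters, folding.

Tiles (or circRNAs) are annotated with the number of occurrences of
RNA-binding-protein motifs (IUPAC consensus strings or position weight
matrices), the number of overlapping filtered eCLIP crosslinking clusters,
and optionally the predicted minimum free energy of folding; localization
ratios are then stratified by these annotations and compared between strata
with the two-sided Wilcoxon rank-sum test.

Motif definitions are configuration inputs: the motifs used in any given
study (e.g. purine-rich SR-protein motifs, CA-rich IGF2BP motifs) are not
built in as ground truth.
"""

from __future__ import annotations

import logging
import re
import shutil
import subprocess
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .localization import group_comparison

logger = logging.getLogger(__name__)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class MotifDef:
    """A named motif: IUPAC consensus, or PWM (4 x w, rows A/C/G/T) + threshold."""

    name: str
    pattern: str | None = None
    pwm: tuple[tuple[float, ...], ...] | None = None
    score_threshold: float = 0.0

    def __post_init__(self) -> None:
        if (self.pattern is None) == (self.pwm is None):
            raise ValueError("provide exactly one of pattern or pwm")
        if self.pattern is not None:
            bad = set(self.pattern.upper().replace("U", "T")) - set(IUPAC)
            if bad:
                raise ValueError(f"invalid IUPAC character(s): {sorted(bad)}")
        else:
            m = np.asarray(self.pwm, dtype=float)
            if m.shape[0] != 4 or not np.allclose(m.sum(axis=0), 1.0):
                raise ValueError("PWM must be 4 x w with columns summing to 1")


def _normalize_seq(seq: str) -> str:
    return seq.upper().replace("U", "T")


def scan_motif(seq: str, motif: MotifDef, overlapping: bool = False) -> int:
    """Count motif occurrences, non-overlapping left-to-right by default.

    After each match the scan restarts at the match end (or one base later in
    ``overlapping`` mode). PWM motifs count windows whose log2-odds score
    against a uniform background reaches ``score_threshold``, same policy.
    """
    s = _normalize_seq(seq)
    if motif.pattern is not None:
        pat = "".join(
            c if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]"
            for c in _normalize_seq(motif.pattern)
        )
        if overlapping:
            return len(re.findall(f"(?=({pat}))", s))
        return len(re.findall(pat, s))
    m = np.log2(np.maximum(np.asarray(motif.pwm, dtype=float), 1e-9) / 0.25)
    w = m.shape[1]
    count = 0
    i = 0
    while i + w <= len(s):
        window = s[i:i + w]
        if set(window) <= _BASE_INDEX.keys():
            score = sum(m[_BASE_INDEX[b], j] for j, b in enumerate(window))
            if score >= motif.score_threshold:
                count += 1
                i += 1 if overlapping else w
                continue
        i += 1
    return count


def count_motifs(
    sequences: dict[str, str],
    motifs: list[MotifDef],
    overlapping: bool = False,
) -> pd.DataFrame:
    """Per-sequence occurrence counts, one column per motif."""
    data = {
        motif.name: {sid: scan_motif(seq, motif, overlapping)
                     for sid, seq in sequences.items()}
        for motif in motifs
    }
    out = pd.DataFrame(data)
    out.index.name = "tile_id"
    return out


# ------------------------------------------------------------ eCLIP clusters


@dataclass(frozen=True)
class ClusterRecord:
    chrom: str
    start: int   # 0-based half-open
    end: int
    strand: str
    fold_enrichment: float
    pvalue: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("cluster start must be < end")
        if self.fold_enrichment <= 0:
            raise ValueError("fold enrichment must be > 0")
        if not (0 < self.pvalue <= 1):
            raise ValueError("pvalue must be in (0, 1]")


def load_clusters_narrowpeak(path: str | Path) -> list[ClusterRecord]:
    """Read ENCODE-style narrowPeak: signalValue = fold enrichment over input,
    pValue column = -log10(P) (converted to a raw probability here)."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 8:
                raise ValueError(f"{path}:{ln}: narrowPeak needs >= 8 columns")
            out.append(ClusterRecord(
                chrom=f[0], start=int(f[1]), end=int(f[2]), strand=f[5],
                fold_enrichment=float(f[6]),
                pvalue=min(10 ** (-float(f[7])), 1.0),
            ))
    return out


def filter_clusters(
    clusters: list[ClusterRecord],
    p_max: float = 0.01,
    min_fold: float = 2.0,
) -> list[ClusterRecord]:
    """Keep clusters with P < p_max and fold enrichment >= min_fold."""
    return [c for c in clusters if c.pvalue < p_max and c.fold_enrichment >= min_fold]


def intersect_clusters(
    features: pd.DataFrame,
    clusters: list[ClusterRecord],
) -> pd.Series:
    """Number of clusters overlapping each feature by >= 1 base.

    *features* needs columns chrom, start, end, strand (0-based half-open).
    Strand-aware: '.' on either side matches both strands. Implemented as a
    sorted sweep (searchsorted on cluster starts/ends per chromosome+strand
    group); overlap count = #(cluster.start < feature.end) minus
    #(cluster.end <= feature.start).
    """
    for col in ("chrom", "start", "end", "strand"):
        if col not in features.columns:
            raise ValueError(f"features missing column {col!r}")
    groups: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for c in clusters:
        groups.setdefault((c.chrom, c.strand), []).append((c.start, c.end))
    sorted_groups = {
        key: (np.sort(np.array([iv[0] for iv in ivs])),
              np.sort(np.array([iv[1] for iv in ivs])))
        for key, ivs in groups.items()
    }

    def count_one(chrom: str, start: int, end: int, strand: str) -> int:
        strands = ("+", "-", ".") if strand == "." else (strand, ".")
        n = 0
        for s in strands:
            g = sorted_groups.get((chrom, s))
            if g is None:
                continue
            starts, ends = g
            n += int(np.searchsorted(starts, end, side="left")
                     - np.searchsorted(ends, start, side="right"))
        return n

    vals = [
        count_one(r.chrom, int(r.start), int(r.end), r.strand)
        for r in features.itertuples()
    ]
    return pd.Series(vals, index=features.index, name="n_clusters")


# --------------------------------------------------------------- stratifying


def stratify(
    values: pd.Series,
    annotation_counts: pd.Series,
    bins: tuple[int, ...] = (0, 1),
) -> dict:
    """Stratify per-feature values by annotation count bins and compare strata.

    ``bins=(0, 1)`` produces the categories "0", "1", ">1": each listed count
    is its own bin and everything above the last is pooled. Returns a dict
    with per-bin value arrays, a summary table (n, median, quartiles), and
    pairwise two-sided Wilcoxon rank-sum P-values; comparisons involving an
    empty bin are skipped and logged.
    """
    shared = values.dropna().index.intersection(annotation_counts.index)
    v = values.loc[shared]
    a = annotation_counts.loc[shared]
    labels = [str(b) for b in bins] + [f">{bins[-1]}"]

    def label_of(count: int) -> str:
        return str(count) if count in bins else labels[-1]

    by_bin = {lab: v[a.map(label_of) == lab] for lab in labels}
    summary = pd.DataFrame({
        lab: {
            "n": len(vals),
            "median": vals.median() if len(vals) else np.nan,
            "q1": vals.quantile(0.25) if len(vals) else np.nan,
            "q3": vals.quantile(0.75) if len(vals) else np.nan,
        }
        for lab, vals in by_bin.items()
    }).T
    pairwise = {}
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            if len(by_bin[la]) == 0 or len(by_bin[lb]) == 0:
                logger.info("stratify: skipping %s vs %s (empty bin)", la, lb)
                continue
            merged = pd.concat([by_bin[la], by_bin[lb]])
            grp = [la] * len(by_bin[la]) + [lb] * len(by_bin[lb])
            stat, p = group_comparison(merged.to_numpy(), grp)
            pairwise[(la, lb)] = p
    return {"bins": by_bin, "summary": summary, "pairwise_p": pairwise}


# -------------------------------------------------------------- RNA folding


def fold_energy(seq: str, program: str = "RNAfold") -> float | None:
    """Minimum free energy (kcal/mol) from an external folding program.

    Returns None when the program is not on PATH; the annotation column is
    then simply absent and the pipeline continues.
    """
    exe = shutil.which(program)
    if exe is None:
        logger.warning("%s not found on PATH; folding energy unavailable", program)
        return None
    proc = subprocess.run(
        [exe, "--noPS"], input=seq + "\n", capture_output=True, text=True,
        check=True,
    )
    # last line: "<structure> ( -12.30)" — dG inside the final parentheses
    last = proc.stdout.strip().splitlines()[-1]
    m = re.search(r"\(\s*(-?\d+\.?\d*)\s*\)\s*$", last)
    if not m:
        raise RuntimeError(f"could not parse {program} output: {last!r}")
    return float(m.group(1))


def fold_energies(sequences: dict[str, str], program: str = "RNAfold") -> pd.Series | None:
    if shutil.which(program) is None:
        return None
    return pd.Series({sid: fold_energy(s, program) for sid, s in sequences.items()},
                     name="delta_g")
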