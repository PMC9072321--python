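"""circRNA quantification from chimeric-alignment junction records.

Back-splicing joins a downstream splice donor to an upstream acceptor,
producing a circular RNA whose junction shows up as a chimeric read pair in
spliced alignments. This module parses junction records (tab-separated, STAR
``Chimeric.out.junction`` dialect, 1-based coordinates), assigns each
back-splice record to an annotated circRNA when both breakpoints fall within
a tolerance (default 5 nt) of the annotated boundaries, applies the support
and annotation filters (>= 10 read pairs in at least one sample, <= 5 exons,
<= 5 kb mature length), and computes pseudocounted log2(Nuc/Cyto) ratios with
the same convention as the tile localization module.

Coordinate conventions: annotations are stored 0-based half-open (BED style,
``start < end``); junction records keep the aligner's 1-based positions. The
conversion happens exactly once, inside :func:`assign_junctions`.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .localization import compute_ratios

logger = logging.getLogger(__name__)

ASSIGNED = "assigned"
DROPPED_BY_TYPE = "dropped_by_type"
UNMATCHED = "unmatched"


@dataclass(frozen=True)
class JunctionRecord:
    chrom: str
    donor_pos: int      # 1-based
    acceptor_pos: int   # 1-based
    strand: str         # '+', '-', '.'
    read_id: str

    def __post_init__(self) -> None:
        if self.donor_pos < 1 or self.acceptor_pos < 1:
            raise ValueError("junction positions are 1-based (>= 1)")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class CircAnnotation:
    circ_id: str
    chrom: str
    start: int          # 0-based half-open genomic span of the mature circle
    end: int
    strand: str
    exon_count: int
    mature_length: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.circ_id}: start must be < end")
        if self.exon_count < 1 or self.mature_length < 1:
            raise ValueError(f"{self.circ_id}: exon count and length must be >= 1")


def load_annotations(path: str | Path) -> list[CircAnnotation]:
    """BED6+2 reader: chrom start end name score strand exon_count mature_length."""
    anns = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 8:
                raise ValueError(f"{path}:{ln}: expected 8 BED6+2 columns, got {len(f)}")
            anns.append(CircAnnotation(
                circ_id=f[3], chrom=f[0], start=int(f[1]), end=int(f[2]),
                strand=f[5], exon_count=int(f[6]), mature_length=int(f[7]),
            ))
    return anns


def _is_backsplice(chrom_d, pos_d, strand_d, chrom_a, pos_a, strand_a) -> bool:
    if chrom_d != chrom_a:
        return False
    if strand_d != strand_a and "." not in (strand_d, strand_a):
        return False
    strand = strand_d if strand_d != "." else strand_a
    # linear splicing runs donor -> downstream acceptor; a back-splice has the
    # donor genomically downstream of the acceptor on '+' (upstream on '-')
    if strand == "-":
        return pos_d < pos_a
    return pos_d > pos_a


def parse_chimeric(path: str | Path) -> tuple[list[JunctionRecord], dict[str, int]]:
    """Parse a junction file; keep same-chromosome back-splice records.

    Columns (tab-separated): chrom_donor, pos_donor, strand_donor,
    chrom_acceptor, pos_acceptor, strand_acceptor, junction_type,
    repeat_left, repeat_right, read_name, [...]. Records with a negative
    junction-type code (non-chimeric / artifact classes), on different
    chromosomes, or without back-splice orientation are dropped; the returned
    dict reports how many records fell into each class.
    """
    records: list[JunctionRecord] = []
    dropped = {"junction_type": 0, "interchromosomal": 0, "orientation": 0}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 10:
                raise ValueError(f"{path}:{ln}: expected >= 10 columns, got {len(f)}")
            try:
                chrom_d, pos_d, strand_d = f[0], int(f[1]), f[2]
                chrom_a, pos_a, strand_a = f[3], int(f[4]), f[5]
                jtype = int(f[6])
                read_id = f[9]
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: {exc}") from exc
            if jtype < 0:
                dropped["junction_type"] += 1
                continue
            if chrom_d != chrom_a:
                dropped["interchromosomal"] += 1
                continue
            if not _is_backsplice(chrom_d, pos_d, strand_d, chrom_a, pos_a, strand_a):
                dropped["orientation"] += 1
                continue
            strand = strand_d if strand_d != "." else strand_a
            records.append(JunctionRecord(chrom_d, pos_d, pos_a, strand, read_id))
    for cls, n in dropped.items():
        if n:
            logger.info("parse_chimeric: dropped %d records (%s)", n, cls)
    return records, dropped


def _boundaries_1based(ann: CircAnnotation) -> tuple[int, int]:
    """(acceptor boundary, donor boundary) in 1-based coordinates.

    On '+' the acceptor is the first base of the circle (start+1) and the
    donor its last base (end); reversed on '-'.
    """
    first, last = ann.start + 1, ann.end
    if ann.strand == "-":
        return last, first
    return first, last


def assign_junctions(
    records: list[JunctionRecord],
    annotations: list[CircAnnotation],
    tolerance: int = 5,
    sample: str = "sample",
) -> tuple[pd.Series, pd.DataFrame]:
    """Count read pairs supporting each annotated circRNA.

    A record supports a circRNA when both breakpoints are within *tolerance*
    nt of the annotated boundaries on the same chromosome and a compatible
    strand ('.' in the record matches either). A record within tolerance of
    several annotations goes to the one with the smallest summed boundary
    distance; exact ties are counted for all tied annotations and flagged.

    Returns (per-circRNA count Series named *sample*, per-record assignment
    table with columns read_id, status, circ_id, tied).
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    by_chrom: dict[str, list[CircAnnotation]] = defaultdict(list)
    for ann in annotations:
        by_chrom[ann.chrom].append(ann)
    counts = {ann.circ_id: 0 for ann in annotations}
    rows = []
    for rec in records:
        best: list[str] = []
        best_dist = None
        for ann in by_chrom.get(rec.chrom, ()):
            if rec.strand != "." and ann.strand != rec.strand:
                continue
            b_acc, b_don = _boundaries_1based(ann)
            d_a = abs(rec.acceptor_pos - b_acc)
            d_d = abs(rec.donor_pos - b_don)
            if d_a > tolerance or d_d > tolerance:
                continue
            dist = d_a + d_d
            if best_dist is None or dist < best_dist:
                best, best_dist = [ann.circ_id], dist
            elif dist == best_dist:
                best.append(ann.circ_id)
        if not best:
            rows.append((rec.read_id, UNMATCHED, "", False))
        else:
            for cid in best:
                counts[cid] += 1
            rows.append((rec.read_id, ASSIGNED, ",".join(best), len(best) > 1))
    report = pd.DataFrame(rows, columns=["read_id", "status", "circ_id", "tied"])
    series = pd.Series(counts, name=sample, dtype=int)
    series.index.name = "circ_id"
    return series, report


def quantify(
    junction_files: dict[str, str | Path],
    annotations: list[CircAnnotation],
    tolerance: int = 5,
) -> pd.DataFrame:
    """Parse + assign every sample's junction file into a circ x sample matrix."""
    cols = []
    for sample, path in junction_files.items():
        records, _ = parse_chimeric(path)
        counts, _ = assign_junctions(records, annotations, tolerance, sample=sample)
        cols.append(counts)
    mat = pd.concat(cols, axis=1)
    mat.index.name = "circ_id"
    return mat


def filter_circs(
    counts: pd.DataFrame,
    annotations: list[CircAnnotation],
    min_pairs: int = 10,
    max_exons: int = 5,
    max_length: int = 5000,
) -> pd.DataFrame:
    """Keep circRNAs supported by >= min_pairs in at least one sample and whose
    annotation has <= max_exons exons and mature length <= max_length nt."""
    ann_by_id = {a.circ_id: a for a in annotations}
    missing = [cid for cid in counts.index if cid not in ann_by_id]
    if missing:
        raise ValueError(f"counted circRNA(s) without annotation: {missing}")
    keep = []
    for cid in counts.index:
        ann = ann_by_id[cid]
        if (counts.loc[cid].max() >= min_pairs
                and ann.exon_count <= max_exons
                and ann.mature_length <= max_length):
            keep.append(cid)
    return counts.loc[keep]


def circ_ratios(
    counts: pd.DataFrame,
    nuc_sample: str,
    cyto_sample: str,
    pseudocount: float = 0.5,
) -> pd.Series:
    """log2(Nuc/Cyto) per circRNA, pseudocount + CPM convention as for tiles.

    No additional read-support floor is applied here (the >= min_pairs filter
    runs beforehand), so min_reads is 0.
    """
    for s in (nuc_sample, cyto_sample):
        if s not in counts.columns:
            raise ValueError(f"fraction sample {s!r} missing from counts")
    table = compute_ratios(
        counts, [(nuc_sample, cyto_sample)], pseudocount=pseudocount,
        min_reads=0, pair_names=["log2_nuc_cyto"],
    )
    return table["log2_nuc_cyto"]
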