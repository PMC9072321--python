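"""UMI-aware, mismatch-constrained matching of amplicon reads to library tiles.

Each R1 read is expected to carry ``[UMI][adapter][tile insert]``. A read is
matched to a tile by gapless comparison of the insert (the bases following the
first exact occurrence of the adapter) against the tile sequence from position
0, over the overlap of the two. The matching rules:

* mismatches are permitted only at positions whose base quality is at least
  ``quality_min`` (default Q35) — a mismatch at a lower-quality position
  invalidates the candidate;
* at most ``max_seed_mm`` (default 2) mismatches in the first ``seed_length``
  (default 15) compared positions;
* at most ``max_total_mm`` (default 4) mismatches overall;
* among valid candidate tiles the one with the fewest total mismatches wins;
  a tie at the minimum discards the read as ambiguous.

Counting collapses reads to distinct UMIs per tile by default (``count_mode
= "umi"``); ``count_mode = "read"`` counts raw reads.
"""

from __future__ import annotations

import gzip
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .library import TileLibrary

DEFAULT_ADAPTER = "TAGGAGGCCTCATCTGACTG"

STATUS_MATCHED = "matched"
STATUS_NO_ADAPTER = "no_adapter"
STATUS_UNMATCHED = "unmatched"
STATUS_AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class ReadRecord:
    identifier: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.identifier!r}: {len(self.qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )

    @classmethod
    def from_fastq_fields(cls, title: str, seq: str, qual: str) -> "ReadRecord":
        return cls(title.split()[0], seq.upper(),
                   tuple(ord(c) - 33 for c in qual))


@dataclass(frozen=True)
class MatchOutcome:
    status: str
    tile_id: str | None = None
    umi: str | None = None
    total_mismatches: int | None = None
    seed_mismatches: int | None = None


@dataclass(frozen=True)
class MatcherConfig:
    adapter: str = DEFAULT_ADAPTER
    umi_length: int = 10
    quality_min: int = 35
    seed_length: int = 15
    max_seed_mm: int = 2
    max_total_mm: int = 4
    min_reads: int = 20
    count_mode: str = "umi"  # "umi" | "read"

    def __post_init__(self) -> None:
        if not self.adapter:
            raise ValueError("adapter must be non-empty")
        if self.seed_length <= 0:
            raise ValueError("seed_length must be positive")
        if self.max_seed_mm > self.max_total_mm:
            raise ValueError("max_seed_mm cannot exceed max_total_mm")
        if self.count_mode not in ("umi", "read"):
            raise ValueError(f"unknown count_mode {self.count_mode!r}")


@dataclass
class MatchStats:
    total: int = 0
    matched: int = 0
    no_adapter: int = 0
    unmatched: int = 0
    ambiguous: int = 0

    def record(self, status: str) -> None:
        self.total += 1
        setattr(self, status, getattr(self, status) + 1)

    def as_dict(self) -> dict[str, int]:
        return {
            "total": self.total,
            "matched": self.matched,
            "no_adapter": self.no_adapter,
            "unmatched": self.unmatched,
            "ambiguous": self.ambiguous,
        }


# --------------------------------------------------------------- primitives


def find_adapter(sequence: str, adapter: str) -> int | None:
    """0-based start of the first exact occurrence of *adapter*, else None."""
    if not adapter:
        raise ValueError("adapter must be non-empty")
    pos = sequence.find(adapter)
    return pos if pos >= 0 else None


def extract_umi(sequence: str, adapter_pos: int, umi_length: int) -> str | None:
    """The ``umi_length`` bases immediately preceding the adapter.

    Returns None when the read starts too late to hold a full UMI.
    """
    if adapter_pos < umi_length:
        return None
    return sequence[adapter_pos - umi_length:adapter_pos]


def score_candidate(
    insert: str,
    insert_quals: Sequence[int],
    tile_seq: str,
    cfg: MatcherConfig,
) -> tuple[bool, int, int]:
    """Gapless scoring of an insert against one tile.

    Returns ``(valid, seed_mismatches, total_mismatches)``. Comparison runs
    over ``min(len(insert), len(tile_seq))`` positions; an empty overlap is
    invalid. Validity requires every mismatch to sit at a position with
    quality >= ``cfg.quality_min``, plus the seed and total mismatch caps.
    """
    n = min(len(insert), len(tile_seq))
    if n == 0:
        return (False, 0, 0)
    seed = total = 0
    valid = True
    for i in range(n):
        if insert[i] != tile_seq[i]:
            total += 1
            if i < cfg.seed_length:
                seed += 1
            if insert_quals[i] < cfg.quality_min:
                valid = False
    if seed > cfg.max_seed_mm or total > cfg.max_total_mm:
        valid = False
    return (valid, seed, total)


def match_read(
    read: ReadRecord,
    library: TileLibrary,
    cfg: MatcherConfig | None = None,
) -> MatchOutcome:
    """Match one read against every tile in the library (exhaustive).

    The unique minimum-mismatch valid tile wins; ties are discarded as
    ambiguous. This is the reference semantics; :func:`count_tiles` uses an
    index that provably yields the same outcomes.
    """
    cfg = cfg or MatcherConfig()
    if len(library) == 0:
        raise ValueError("library is empty")
    pos = find_adapter(read.sequence, cfg.adapter)
    if pos is None:
        return MatchOutcome(STATUS_NO_ADAPTER)
    umi = extract_umi(read.sequence, pos, cfg.umi_length)
    if umi is None:
        return MatchOutcome(STATUS_NO_ADAPTER)
    start = pos + len(cfg.adapter)
    insert = read.sequence[start:]
    quals = read.qualities[start:]

    best: list[tuple[str, int, int]] = []  # (tile_id, seed, total)
    best_total: int | None = None
    for tile in library:
        valid, seed, total = score_candidate(insert, quals, tile.sequence, cfg)
        if not valid:
            continue
        if best_total is None or total < best_total:
            best = [(tile.tile_id, seed, total)]
            best_total = total
        elif total == best_total:
            best.append((tile.tile_id, seed, total))
    if not best:
        return MatchOutcome(STATUS_UNMATCHED, umi=umi)
    if len(best) > 1:
        return MatchOutcome(STATUS_AMBIGUOUS, umi=umi)
    tid, seed, total = best[0]
    return MatchOutcome(STATUS_MATCHED, tile_id=tid, umi=umi,
                        total_mismatches=total, seed_mismatches=seed)


# --------------------------------------------------------- pigeonhole index


class _TileIndex:
    """Exact-piece (pigeonhole) candidate index.

    Each tile's compared region is cut into ``max_total_mm + 1`` contiguous
    pieces; a candidate with at most ``max_total_mm`` mismatches must agree
    exactly on at least one piece, so looking up every piece of the insert
    retrieves a superset of all tiles that can pass the total-mismatch cap.
    Built lazily per distinct insert length (the compared region depends on
    the overlap of insert and tile).
    """

    def __init__(self, library: TileLibrary, cfg: MatcherConfig):
        self.library = library
        self.cfg = cfg
        self._by_len: dict[int, list[tuple[int, int, dict[str, list[str]]]]] = {}

    def _build(self, insert_len: int) -> list[tuple[int, int, dict[str, list[str]]]]:
        npieces = self.cfg.max_total_mm + 1
        # group tiles by compared length so piece boundaries are shared
        groups: dict[int, list[str]] = defaultdict(list)
        seqs = self.library.sequences
        for tid, seq in seqs.items():
            groups[min(insert_len, len(seq))].append(tid)
        index: list[tuple[int, int, dict[str, list[str]]]] = []
        for n, tids in groups.items():
            if n == 0:
                continue
            bounds = [round(k * n / npieces) for k in range(npieces + 1)]
            for k in range(npieces):
                s, e = bounds[k], bounds[k + 1]
                if s == e:
                    continue
                d: dict[str, list[str]] = defaultdict(list)
                for tid in tids:
                    d[seqs[tid][s:e]].append(tid)
                index.append((s, e, dict(d)))
        return index

    def candidates(self, insert: str) -> set[str]:
        idx = self._by_len.get(len(insert))
        if idx is None:
            idx = self._build(len(insert))
            self._by_len[len(insert)] = idx
        out: set[str] = set()
        for s, e, d in idx:
            hit = d.get(insert[s:e])
            if hit:
                out.update(hit)
        return out


def _score_fast(
    insert: str,
    qual_str: str,
    tile_seq: str,
    cfg: MatcherConfig,
) -> tuple[int, int] | None:
    """String-level scorer for the counting hot path.

    Returns (seed_mm, total_mm) for valid candidates, None otherwise.
    Qualities are the raw Phred+33 characters; only mismatch positions are
    decoded. Short-circuits as soon as a cap is exceeded.
    """
    n = len(insert)
    if len(tile_seq) < n:
        n = len(tile_seq)
        insert = insert[:n]
        tile_seq = tile_seq[:n]
    if n == 0:
        return None
    if insert == tile_seq:
        return (0, 0)
    qmin = cfg.quality_min + 33
    seed = total = 0
    for i in range(n):
        if insert[i] != tile_seq[i]:
            if ord(qual_str[i]) < qmin:
                return None
            total += 1
            if total > cfg.max_total_mm:
                return None
            if i < cfg.seed_length:
                seed += 1
                if seed > cfg.max_seed_mm:
                    return None
    return (seed, total)


# ------------------------------------------------------------------ counting


def _open_text(path: str | Path):
    p = str(path)
    if p.endswith(".gz"):
        return gzip.open(p, "rt")
    return open(p)


def iter_fastq(source) -> Iterator[tuple[str, str, str]]:
    """Yield (title, sequence, quality-string) triples.

    *source* is a FASTQ(.gz) path or an iterable of such triples. Malformed
    records raise ValueError with the failing record index.
    """
    if isinstance(source, (str, Path)):
        with _open_text(source) as fh:
            i = 0
            try:
                for tup in FastqGeneralIterator(fh):
                    i += 1
                    yield tup
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ after record {i}: {exc}") from exc
    else:
        for i, tup in enumerate(source, 1):
            if len(tup) != 3 or len(tup[1]) != len(tup[2]):
                raise ValueError(f"malformed FASTQ record {i}")
            yield tup


def count_tiles(
    reads,
    library: TileLibrary,
    cfg: MatcherConfig | None = None,
    sample: str = "sample",
) -> tuple[pd.Series, MatchStats]:
    """Count reads (or distinct UMIs) per tile for one sample.

    *reads* is a FASTQ(.gz) path or an iterable of ``(title, seq, qual)``
    triples. Returns a per-tile count Series named *sample* (every library
    tile present, zero-filled) and per-status :class:`MatchStats` whose
    classes partition the input reads.
    """
    cfg = cfg or MatcherConfig()
    if len(library) == 0:
        raise ValueError("library is empty")
    index = _TileIndex(library, cfg)
    seqs = library.sequences
    adapter = cfg.adapter
    alen = len(adapter)
    ulen = cfg.umi_length
    stats = MatchStats()

    if cfg.count_mode == "umi":
        umis: dict[str, set[str]] = defaultdict(set)
        counts_read: dict[str, int] | None = None
    else:
        umis = None  # type: ignore[assignment]
        counts_read = defaultdict(int)

    for title, seq, qual in iter_fastq(reads):
        pos = seq.find(adapter)
        if pos < 0 or pos < ulen:
            stats.record(STATUS_NO_ADAPTER)
            continue
        start = pos + alen
        insert = seq[start:]
        qstr = qual[start:]
        best_tid: str | None = None
        best_total = -1
        tie = False
        for tid in index.candidates(insert):
            scored = _score_fast(insert, qstr, seqs[tid], cfg)
            if scored is None:
                continue
            total = scored[1]
            if best_tid is None or total < best_total:
                best_tid, best_total, tie = tid, total, False
            elif total == best_total:
                tie = True
        if best_tid is None:
            stats.record(STATUS_UNMATCHED)
        elif tie:
            stats.record(STATUS_AMBIGUOUS)
        else:
            stats.record(STATUS_MATCHED)
            if counts_read is not None:
                counts_read[best_tid] += 1
            else:
                umis[best_tid].add(seq[pos - ulen:pos])

    if counts_read is not None:
        data = {tid: counts_read.get(tid, 0) for tid in library.ids}
    else:
        data = {tid: len(umis.get(tid, ())) for tid in library.ids}
    return pd.Series(data, name=sample, dtype=int), stats


def count_samples(
    fastq_by_sample: dict[str, object],
    library: TileLibrary,
    cfg: MatcherConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count every sample; returns (tile x sample matrix, per-sample stats)."""
    cols, stat_rows = [], []
    for sample, src in fastq_by_sample.items():
        counts, stats = count_tiles(src, library, cfg, sample=sample)
        cols.append(counts)
        stat_rows.append({"sample": sample, **stats.as_dict()})
    matrix = pd.concat(cols, axis=1)
    matrix.index.name = "tile_id"
    return matrix, pd.DataFrame(stat_rows).set_index("sample")
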