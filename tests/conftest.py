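import numpy as np
import pandas as pd
import pytest

from tilefate import (
    MatcherConfig,
    ReadRecord,
    TileLibrary,
    TileRecord,
    generate_tile_library,
)

ADAPTER = MatcherConfig().adapter


@pytest.fixture(scope="session")
def small_library() -> TileLibrary:
    return generate_tile_library(8, 60, (0.3, 0.7), seed=7, id_prefix="t")


@pytest.fixture(scope="session")
def matcher_cfg() -> MatcherConfig:
    return MatcherConfig()


def make_read(
    tile_seq: str,
    umi: str = "ACGTACGTAC",
    adapter: str = ADAPTER,
    qual: int = 40,
    prefix: str = "",
    identifier: str = "r1",
) -> ReadRecord:
    """Assemble a [prefix][UMI][adapter][tile] read with uniform quality."""
    seq = prefix + umi + adapter + tile_seq
    return ReadRecord(identifier, seq, tuple([qual] * len(seq)))


def brute_force_match(read: ReadRecord, library: TileLibrary, cfg: MatcherConfig):
    """Independent exhaustive matcher: score every tile, pick unique argmin.

    Deliberately re-derives the rules from scratch (position loops, no shared
    helpers beyond the data types) so it can act as the oracle for match_read.
    """
    pos = read.sequence.find(cfg.adapter)
    if pos < 0 or pos < cfg.umi_length:
        return ("no_adapter", None)
    start = pos + len(cfg.adapter)
    insert = read.sequence[start:]
    quals = read.qualities[start:]
    scored = []
    for tile in library:
        n = min(len(insert), len(tile.sequence))
        if n == 0:
            continue
        seed = total = 0
        ok = True
        for i in range(n):
            if insert[i] != tile.sequence[i]:
                total += 1
                if i < cfg.seed_length:
                    seed += 1
                if quals[i] < cfg.quality_min:
                    ok = False
        if ok and seed <= cfg.max_seed_mm and total <= cfg.max_total_mm:
            scored.append((total, tile.tile_id))
    if not scored:
        return ("unmatched", None)
    scored.sort()
    best_total = scored[0][0]
    winners = [tid for tot, tid in scored if tot == best_total]
    if len(winners) > 1:
        return ("ambiguous", None)
    return ("matched", winners[0])
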