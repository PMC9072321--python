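"""Adapter/UMI extraction and mismatch-constrained tile matching."""

import numpy as np
import pytest

from tilefate import (
    MatcherConfig,
    ReadRecord,
    TileLibrary,
    TileRecord,
    count_tiles,
    extract_umi,
    find_adapter,
    match_read,
    score_candidate,
)
from tilefate.matching import (
    STATUS_AMBIGUOUS,
    STATUS_MATCHED,
    STATUS_NO_ADAPTER,
    STATUS_UNMATCHED,
)

from conftest import ADAPTER, brute_force_match, make_read


class TestFindAdapter:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAAA" + ADAPTER + "CCGT", 4),
            (ADAPTER + "CCGT", 0),
            ("AAAACCCCGGGGTTTT", None),
        ],
    )
    def test_first_exact_occurrence(self, seq, expected):
        assert find_adapter(seq, ADAPTER) == expected

    def test_empty_adapter_rejected(self):
        with pytest.raises(ValueError):
            find_adapter("ACGT", "")


class TestExtractUmi:
    def test_full_umi_before_adapter(self):
        seq = "ACGTACGTAT" + ADAPTER
        assert extract_umi(seq, 10, 10) == "ACGTACGTAT"

    def test_truncated_umi_is_absent(self):
        assert extract_umi("ACGT" + ADAPTER, 4, 10) is None

    def test_zero_length_umi_is_empty(self):
        assert extract_umi(ADAPTER, 0, 0) == ""


class TestScoreCandidate:
    """The matching-rule battery: quality floor, seed cap, total cap."""

    def setup_method(self):
        self.cfg = MatcherConfig()
        self.tile = "ACGTACGTACGTACGTACGTACGTACGTAC"  # 30 nt

    def _mutate(self, positions):
        s = list(self.tile)
        for p in positions:
            s[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[s[p]]
        return "".join(s)

    def test_identity_all_q40(self):
        valid, seed, total = score_candidate(
            self.tile, [40] * 30, self.tile, self.cfg)
        assert (valid, seed, total) == (True, 0, 0)

    def test_single_high_quality_mismatch_valid(self):
        insert = self._mutate([3])
        valid, seed, total = score_candidate(insert, [40] * 30, self.tile, self.cfg)
        assert (valid, seed, total) == (True, 1, 1)

    def test_mismatch_below_q35_invalidates(self):
        insert = self._mutate([3])
        quals = [40] * 30
        quals[3] = 30
        valid, _, _ = score_candidate(insert, quals, self.tile, self.cfg)
        assert not valid

    def test_three_seed_mismatches_invalid(self):
        insert = self._mutate([1, 5, 9])  # all within the 15-nt seed
        valid, seed, total = score_candidate(insert, [40] * 30, self.tile, self.cfg)
        assert not valid and seed == 3

    def test_five_mismatches_beyond_seed_invalid(self):
        insert = self._mutate([16, 18, 20, 22, 24])
        valid, seed, total = score_candidate(insert, [40] * 30, self.tile, self.cfg)
        assert not valid and seed == 0 and total == 5

    def test_four_total_two_seed_still_valid(self):
        insert = self._mutate([1, 5, 20, 25])
        valid, seed, total = score_candidate(insert, [40] * 30, self.tile, self.cfg)
        assert (valid, seed, total) == (True, 2, 4)

    def test_empty_overlap_invalid(self):
        valid, _, _ = score_candidate("", [], self.tile, self.cfg)
        assert not valid

    def test_overlap_limited_to_shorter_sequence(self):
        # insert shorter than tile: only the overlap is compared
        valid, seed, total = score_candidate(
            self.tile[:12], [40] * 12, self.tile, self.cfg)
        assert (valid, seed, total) == (True, 0, 0)


class TestMatchRead:
    def _library(self):
        a = "AAACAAACAAACAAACAAACAAACAAACAA"
        b = "GGGTGGGTGGGTGGGTGGGTGGGTGGGTGG"
        return TileLibrary([TileRecord("A", a), TileRecord("B", b)]), a, b

    def test_fewest_mismatches_wins(self):
        lib, a, b = self._library()
        # read = tile A with one mismatch at a non-seed position
        insert = a[:20] + ("C" if a[20] == "A" else "A") + a[21:]
        out = match_read(make_read(insert), lib)
        assert out.status == STATUS_MATCHED
        assert out.tile_id == "A"
        assert out.total_mismatches == 1

    def test_tie_is_ambiguous(self):
        lib = TileLibrary([
            TileRecord("A", "AAACAAACAAACAAACAAACAAACAAACAA"),
            TileRecord("B", "AAACAAACAAACAAACAAACAAACAAACTT"),
        ])
        # differs from A at pos 28 and from B at pos 29: one mismatch to each
        insert = "AAACAAACAAACAAACAAACAAACAAACTA"
        out = match_read(make_read(insert), lib)
        assert out.status == STATUS_AMBIGUOUS

    def test_no_adapter(self):
        lib, _, _ = self._library()
        read = ReadRecord("r", "ACGT" * 20, tuple([40] * 80))
        assert match_read(read, lib).status == STATUS_NO_ADAPTER

    def test_truncated_umi_counts_as_no_adapter(self):
        lib, a, _ = self._library()
        out = match_read(make_read(a, umi="ACGT"), lib)  # only 4 nt before adapter
        assert out.status == STATUS_NO_ADAPTER

    def test_nothing_within_thresholds_is_unmatched(self):
        lib, _, _ = self._library()
        out = match_read(make_read("CTCTCTCTCTCTCTCTCTCTCTCTCTCTCT"), lib)
        assert out.status == STATUS_UNMATCHED

    def test_umi_is_reported(self):
        lib, a, _ = self._library()
        out = match_read(make_read(a, umi="TTTTTTTTTT"), lib)
        assert out.umi == "TTTTTTTTTT"


def _random_reads(library, n_reads, error_rate, rng, adapter=ADAPTER, umi_len=10):
    """Simulated reads with qualities straddling Q35 and occasional junk."""
    bases = "ACGT"
    tiles = list(library)
    reads = []
    for i in range(n_reads):
        r = rng.random()
        if r < 0.05:  # adapter-free junk
            seq = "".join(rng.choice(list(bases), size=80))
            reads.append(ReadRecord(f"junk{i}", seq, tuple([40] * len(seq))))
            continue
        tile = tiles[rng.integers(len(tiles))]
        ins = list(tile.sequence)
        for p in range(len(ins)):
            if rng.random() < error_rate:
                ins[p] = bases[(bases.index(ins[p]) + rng.integers(1, 4)) % 4]
        umi = "".join(rng.choice(list(bases), size=umi_len))
        seq = umi + adapter + "".join(ins)
        quals = tuple(int(q) for q in
                      np.clip(np.rint(rng.normal(37, 4, len(seq))), 2, 41))
        reads.append(ReadRecord(f"r{i}", seq, quals))
    return reads


class TestOracleEquivalence:
    def test_match_read_equals_brute_force(self, matcher_cfg):
        """1,000 noisy reads vs a 50-tile library: exhaustive-oracle agreement."""
        rng = np.random.default_rng(42)
        from tilefate import generate_tile_library
        lib = generate_tile_library(50, 60, (0.3, 0.7), seed=9)
        for read in _random_reads(lib, 1000, 0.01, rng):
            expected = brute_force_match(read, lib, matcher_cfg)
            got = match_read(read, lib, matcher_cfg)
            assert (got.status, got.tile_id) == expected

    def test_library_order_invariance(self, matcher_cfg):
        rng = np.random.default_rng(5)
        from tilefate import generate_tile_library
        lib = generate_tile_library(20, 60, (0.3, 0.7), seed=13)
        rev = TileLibrary(list(lib)[::-1])
        for read in _random_reads(lib, 100, 0.02, rng):
            a, b = match_read(read, lib, matcher_cfg), match_read(read, rev, matcher_cfg)
            assert (a.status, a.tile_id) == (b.status, b.tile_id)

    def test_quality_min_monotonicity(self):
        """Raising the quality floor can only lose matches, never gain them."""
        rng = np.random.default_rng(17)
        from tilefate import generate_tile_library
        lib = generate_tile_library(10, 60, (0.3, 0.7), seed=21)
        reads = _random_reads(lib, 200, 0.03, rng)
        lo = MatcherConfig(quality_min=30)
        hi = MatcherConfig(quality_min=38)
        for read in reads:
            s_lo = match_read(read, lib, lo).status
            s_hi = match_read(read, lib, hi).status
            if s_hi == STATUS_MATCHED:
                assert s_lo in (STATUS_MATCHED, STATUS_AMBIGUOUS)


class TestCountTiles:
    def _triples(self, reads):
        return [(r.identifier, r.sequence,
                 "".join(chr(q + 33) for q in r.qualities)) for r in reads]

    def test_constructed_counts(self, matcher_cfg):
        lib = TileLibrary([
            TileRecord("A", "AAACAAACAAACAAACAAACAAACAAACAA"),
            TileRecord("B", "GGGTGGGTGGGTGGGTGGGTGGGTGGGTGG"),
        ])
        rng = np.random.default_rng(1)
        reads = []
        for i in range(30):
            umi = "".join(rng.choice(list("ACGT"), size=10))
            reads.append(make_read(lib["A"].sequence, umi=umi, identifier=f"a{i}"))
        for i in range(70):
            umi = "".join(rng.choice(list("ACGT"), size=10))
            reads.append(make_read(lib["B"].sequence, umi=umi, identifier=f"b{i}"))
        counts, stats = count_tiles(self._triples(reads), lib, matcher_cfg)
        assert counts["A"] == 30 and counts["B"] == 70
        assert stats.matched == 100

    def test_umi_collapse_vs_read_mode(self):
        lib = TileLibrary([TileRecord("A", "AAACAAACAAACAAACAAACAAACAAACAA")])
        reads = [make_read(lib["A"].sequence, umi="ACGTACGTAC", identifier=f"r{i}")
                 for i in range(10)]
        triples = self._triples(reads)
        umi_counts, _ = count_tiles(triples, lib, MatcherConfig(count_mode="umi"))
        read_counts, _ = count_tiles(triples, lib, MatcherConfig(count_mode="read"))
        assert umi_counts["A"] == 1
        assert read_counts["A"] == 10

    @pytest.mark.parametrize("fixture_seed", range(12))
    def test_status_conservation(self, fixture_seed, matcher_cfg):
        """matched + no_adapter + unmatched + ambiguous == total on any input."""
        rng = np.random.default_rng(1000 + fixture_seed)
        from tilefate import generate_tile_library
        lib = generate_tile_library(int(rng.integers(3, 15)), 60, (0.2, 0.8),
                                    seed=fixture_seed)
        reads = _random_reads(lib, int(rng.integers(20, 150)),
                              float(rng.uniform(0, 0.08)), rng)
        counts, stats = count_tiles(self._triples(reads), lib, matcher_cfg)
        assert stats.matched + stats.no_adapter + stats.unmatched + stats.ambiguous \
            == stats.total == len(reads)
        assert counts.sum() <= stats.matched  # UMI collapse can only shrink

    def test_count_tiles_agrees_with_match_read(self, matcher_cfg):
        """The indexed counting path equals per-read exhaustive matching."""
        rng = np.random.default_rng(77)
        from tilefate import generate_tile_library
        lib = generate_tile_library(15, 60, (0.3, 0.7), seed=3)
        reads = _random_reads(lib, 400, 0.02, rng)
        counts, stats = count_tiles(self._triples(reads), lib,
                                    MatcherConfig(count_mode="read"))
        expected: dict[str, int] = {}
        n_matched = 0
        for read in reads:
            out = match_read(read, lib, matcher_cfg)
            if out.status == STATUS_MATCHED:
                n_matched += 1
                expected[out.tile_id] = expected.get(out.tile_id, 0) + 1
        assert stats.matched == n_matched
        for tid in lib.ids:
            assert counts[tid] == expected.get(tid, 0)

    def test_malformed_fastq_raises_with_index(self):
        lib = TileLibrary([TileRecord("A", "AAACAAACAAACAAACAAACAAACAAACAA")])
        bad = [("r1", "ACGT", "!!!")]  # length mismatch
        with pytest.raises(ValueError, match="record 1"):
            count_tiles(bad, lib)
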