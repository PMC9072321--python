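"""Back-splice junction parsing, tolerance assignment, filters, ratios."""

import numpy as np
import pandas as pd
import pytest

from tilefate import (
    CircAnnotation,
    JunctionRecord,
    assign_junctions,
    circ_ratios,
    filter_circs,
    parse_chimeric,
    quantify,
    simulate_chimeric_junctions,
)

ANN = CircAnnotation("circA", "chr1", 1000, 2000, "+", exon_count=2,
                     mature_length=800)


def _line(chrom_d, pos_d, s_d, chrom_a, pos_a, s_a, jtype=1, name="rp1"):
    return f"{chrom_d}\t{pos_d}\t{s_d}\t{chrom_a}\t{pos_a}\t{s_a}\t{jtype}\t0\t0\t{name}\n"


class TestParseChimeric:
    def test_well_formed_backsplice_lines(self, tmp_path):
        p = tmp_path / "j.tsv"
        p.write_text(
            _line("chr1", 2000, "+", "chr1", 1001, "+", name="a")
            + _line("chr1", 2003, "+", "chr1", 999, "+", name="b")
            + _line("chr2", 500, "-", "chr2", 900, "-", name="c")
        )
        records, dropped = parse_chimeric(p)
        assert len(records) == 3
        assert sum(dropped.values()) == 0

    def test_interchromosomal_dropped_and_logged(self, tmp_path):
        p = tmp_path / "j.tsv"
        p.write_text(_line("chr1", 2000, "+", "chr2", 1001, "+"))
        records, dropped = parse_chimeric(p)
        assert records == [] and dropped["interchromosomal"] == 1

    def test_negative_junction_type_dropped(self, tmp_path):
        p = tmp_path / "j.tsv"
        p.write_text(_line("chr1", 2000, "+", "chr1", 1001, "+", jtype=-1))
        records, dropped = parse_chimeric(p)
        assert records == [] and dropped["junction_type"] == 1

    def test_linear_orientation_dropped(self, tmp_path):
        # donor upstream of acceptor on '+' is ordinary linear splicing
        p = tmp_path / "j.tsv"
        p.write_text(_line("chr1", 1001, "+", "chr1", 2000, "+"))
        records, dropped = parse_chimeric(p)
        assert records == [] and dropped["orientation"] == 1

    def test_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "j.tsv"
        p.write_text(_line("chr1", 2000, "+", "chr1", 1001, "+") + "garbage\n")
        with pytest.raises(ValueError, match=":2"):
            parse_chimeric(p)

    def test_roundtrip_with_generator(self, tmp_path):
        anns = [ANN,
                CircAnnotation("circB", "chr2", 5000, 6500, "-", 1, 1200)]
        abundance = {"circA": {"nuc": 40.0}, "circB": {"nuc": 25.0}}
        paths = simulate_chimeric_junctions(anns, abundance, tmp_path,
                                            jitter_sd=0.0, seed=3)
        records, dropped = parse_chimeric(paths["nuc"])
        assert sum(dropped.values()) == 0
        counts, report = assign_junctions(records, anns, tolerance=5)
        # zero jitter: every record assigned, Poisson totals recovered exactly
        assert (report["status"] == "assigned").all()
        assert counts["circA"] + counts["circB"] == len(records)


class TestAssignJunctions:
    # '+' annotation [1000, 2000): acceptor boundary 1001, donor boundary 2000
    @pytest.mark.parametrize("offset", [0, 1, 3, 5])
    def test_offsets_within_tolerance_assigned(self, offset):
        rec = JunctionRecord("chr1", 2000 + offset, 1001, "+", "rp")
        counts, report = assign_junctions([rec], [ANN], tolerance=5)
        assert counts["circA"] == 1

    def test_offset_six_rejected(self):
        rec = JunctionRecord("chr1", 2006, 1001, "+", "rp")
        counts, report = assign_junctions([rec], [ANN], tolerance=5)
        assert counts["circA"] == 0
        assert report["status"].iloc[0] == "unmatched"

    def test_both_boundaries_must_be_close(self):
        rec = JunctionRecord("chr1", 2000, 1010, "+", "rp")  # acceptor off by 9
        counts, _ = assign_junctions([rec], [ANN], tolerance=5)
        assert counts["circA"] == 0

    def test_strand_mismatch_rejected_dot_matches(self):
        rec_minus = JunctionRecord("chr1", 1001, 2000, "-", "rp")
        counts, _ = assign_junctions([rec_minus], [ANN], tolerance=5)
        assert counts["circA"] == 0
        rec_dot = JunctionRecord("chr1", 2000, 1001, ".", "rp")
        counts, _ = assign_junctions([rec_dot], [ANN], tolerance=5)
        assert counts["circA"] == 1

    def test_nearest_annotation_wins(self):
        near = CircAnnotation("near", "chr1", 1000, 2000, "+", 1, 800)
        far = CircAnnotation("far", "chr1", 1003, 2003, "+", 1, 800)
        rec = JunctionRecord("chr1", 2001, 1002, "+", "rp")
        counts, report = assign_junctions([rec], [near, far], tolerance=5)
        assert counts["near"] == 1 and counts["far"] == 0

    def test_exact_tie_counts_both_and_flags(self):
        a = CircAnnotation("a", "chr1", 1000, 2000, "+", 1, 800)
        b = CircAnnotation("b", "chr1", 1002, 2002, "+", 1, 800)
        rec = JunctionRecord("chr1", 2001, 1002, "+", "rp")
        counts, report = assign_junctions([rec], [a, b], tolerance=5)
        assert counts["a"] == 1 and counts["b"] == 1
        assert report["tied"].iloc[0]

    def test_tolerance_monotonicity(self):
        rng = np.random.default_rng(9)
        anns = [CircAnnotation(f"c{i}", "chr1", 1000 * (i + 1), 1000 * (i + 1) + 700,
                               "+", 1, 500) for i in range(5)]
        recs = []
        for i in range(200):
            ann = anns[rng.integers(5)]
            recs.append(JunctionRecord(
                "chr1", ann.end + int(rng.integers(-8, 9)),
                ann.start + 1 + int(rng.integers(-8, 9)), "+", f"rp{i}"))
        prev = None
        for tol in (0, 2, 4, 6, 8):
            counts, _ = assign_junctions(recs, anns, tolerance=tol)
            if prev is not None:
                assert (counts >= prev).all()
            prev = counts

    def test_partition_of_input_records(self):
        rng = np.random.default_rng(10)
        recs = [JunctionRecord("chr1", int(rng.integers(1990, 2015)),
                               int(rng.integers(990, 1015)), "+", f"rp{i}")
                for i in range(100)]
        counts, report = assign_junctions(recs, [ANN], tolerance=5)
        assert len(report) == 100
        assert set(report["status"]) <= {"assigned", "unmatched"}
        n_assigned = (report["status"] == "assigned").sum()
        assert counts["circA"] == n_assigned  # single annotation, no ties


class TestFilterCircs:
    ANNS = [
        CircAnnotation("keep", "chr1", 100, 3100, "+", 4, 3000),
        CircAnnotation("low", "chr1", 5000, 6000, "+", 1, 900),
        CircAnnotation("exons", "chr1", 9000, 12000, "+", 6, 2500),
        CircAnnotation("long", "chr1", 20000, 26000, "+", 3, 5001),
    ]

    def _counts(self):
        return pd.DataFrame({
            "nuc": {"keep": 12, "low": 9, "exons": 50, "long": 50},
            "cyto": {"keep": 3, "low": 9, "exons": 50, "long": 50},
        })

    def test_canonical_filter_examples(self):
        out = filter_circs(self._counts(), self.ANNS)
        assert list(out.index) == ["keep"]

    def test_idempotent(self):
        once = filter_circs(self._counts(), self.ANNS)
        twice = filter_circs(once, self.ANNS)
        pd.testing.assert_frame_equal(once, twice)

    def test_missing_annotation_fails(self):
        counts = pd.DataFrame({"nuc": {"mystery": 50}})
        with pytest.raises(ValueError, match="mystery"):
            filter_circs(counts, self.ANNS)

    def test_boundary_values_kept(self):
        anns = [CircAnnotation("edge", "chr1", 100, 5100, "+", 5, 5000)]
        counts = pd.DataFrame({"nuc": {"edge": 10}, "cyto": {"edge": 0}})
        assert list(filter_circs(counts, anns).index) == ["edge"]


class TestCircRatios:
    def test_equal_counts_zero_ratio(self):
        counts = pd.DataFrame({"nuc": {"a": 50, "b": 10}, "cyto": {"a": 50, "b": 10}})
        r = circ_ratios(counts, "nuc", "cyto")
        assert np.allclose(r, 0.0)

    def test_antisymmetry_under_fraction_swap(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame({"nuc": rng.integers(0, 300, 10),
                               "cyto": rng.integers(0, 300, 10)})
        assert np.allclose(circ_ratios(counts, "nuc", "cyto"),
                           -circ_ratios(counts, "cyto", "nuc"))

    def test_missing_fraction_fails(self):
        counts = pd.DataFrame({"nuc": {"a": 5}})
        with pytest.raises(ValueError, match="cyto"):
            circ_ratios(counts, "nuc", "cyto")

    def test_simulated_twofold_enrichment_recovered(self, tmp_path):
        """2x cytoplasmic abundance recovered within Poisson error at 1,000."""
        anns = [CircAnnotation("c1", "chr1", 1000, 2500, "+", 2, 1200),
                CircAnnotation("bg", "chr1", 9000, 10500, "+", 2, 1200)]
        abundance = {"c1": {"nuc": 1000.0, "cyto": 2000.0},
                     "bg": {"nuc": 1000.0, "cyto": 1000.0}}
        paths = simulate_chimeric_junctions(anns, abundance, tmp_path,
                                            jitter_sd=1.0, seed=4)
        counts = quantify(paths, anns, tolerance=5)
        ratios = circ_ratios(counts, "nuc", "cyto")
        # CPM normalization makes ratios relative; the c1-vs-bg difference
        # carries the 2-fold cytoplasmic enrichment (log2 ~ -1)
        delta = ratios["c1"] - ratios["bg"]
        assert delta == pytest.approx(-1.0, abs=0.2)

    def test_poisson_abundance_ratio(self, tmp_path):
        anns = [CircAnnotation("hi", "chr1", 1000, 2500, "+", 2, 1200),
                CircAnnotation("lo", "chr1", 9000, 10500, "+", 2, 1200)]
        abundance = {"hi": {"nuc": 1000.0}, "lo": {"nuc": 100.0}}
        paths = simulate_chimeric_junctions(anns, abundance, tmp_path,
                                            jitter_sd=0.0, seed=8)
        counts = quantify(paths, anns)
        ratio = counts.loc["hi", "nuc"] / counts.loc["lo", "nuc"]
        assert ratio == pytest.approx(10.0, rel=0.35)  # ~3 sigma Poisson slack
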