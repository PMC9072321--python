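"""End-to-end orchestration of the synthetic demo pipeline.

``run_pipeline`` executes the stages in dependency order — simulate, count,
localize, stability, circquant, annotate — on generated data with known
ground truth, writing plain TSV tables (diffable, byte-stable for a fixed
seed) plus a run log that echoes the full configuration. Every threshold
default is the value used throughout the package: adapter
TAGGAGGCCTCATCTGACTG, Q35 mismatch-quality floor, 15-nt seed with <= 2
mismatches, <= 4 total mismatches, >= 20 reads per tile, pseudocount 0.5,
+/- 0.3 log2 call threshold at P < 0.05, 5-nt junction tolerance, >= 10 read
pairs / <= 5 exons / <= 5 kb circRNA filters, eCLIP P < 0.01 with >= 2-fold
enrichment.
"""

from __future__ import annotations

import copy
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann_mod
from . import circ as circ_mod
from . import localization as loc_mod
from . import stability as stab_mod
from . import synthetic as syn_mod
from .library import TileLibrary
from .matching import MatcherConfig, count_samples

logger = logging.getLogger(__name__)

ALL_STAGES = ["simulate", "count", "localize", "stability", "circquant", "annotate"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "tilefate_run",
    "stages": list(ALL_STAGES),
    "simulate": {
        "n_tiles": 40,
        "tile_length": 110,
        "gc_range": [0.3, 0.7],
        "n_replicates": 3,
        "depth": 300.0,
        "error_rate": 0.002,
        "umi_length": 10,
        "shift_levels": [-1.0, 0.0, 1.0],
        "motif": {"name": "purine_rich", "pattern": "GGAGGA"},
        "motif_shift": 0.8,
    },
    "matcher": {
        "adapter": "TAGGAGGCCTCATCTGACTG",
        "umi_length": 10,
        "quality_min": 35,
        "seed_length": 15,
        "max_seed_mm": 2,
        "max_total_mm": 4,
        "min_reads": 20,
        "count_mode": "umi",
    },
    "localize": {"pseudocount": 0.5, "threshold": 0.3, "alpha": 0.05},
    "stability": {
        "timepoints": [0.0, 2.0, 4.0, 8.0],
        "half_life_levels": [1.0, 2.0, 4.0, 8.0],
        "noise_cv": 0.1,
        "n_replicates": 3,
    },
    "circ": {
        "n_circs": 12,
        "tolerance": 5,
        "min_pairs": 10,
        "max_exons": 5,
        "max_length": 5000,
        "jitter_sd": 1.0,
        "pseudocount": 0.5,
    },
    "annotate": {"bins": [0, 1], "eclip": {"p_max": 0.01, "min_fold": 2.0}},
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    loaded = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}

    def merge(dst, src):
        for k, v in src.items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict):
                merge(dst[k], v)
            else:
                dst[k] = v

    merge(cfg, loaded)
    if overrides:
        merge(cfg, overrides)
    return cfg


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.6g")


def _demo_annotations(n_circs: int, rng) -> list[circ_mod.CircAnnotation]:
    anns = []
    pos = 10_000
    for i in range(n_circs):
        length = int(rng.integers(300, 7000))
        exons = int(rng.integers(1, 8))
        anns.append(circ_mod.CircAnnotation(
            circ_id=f"circ{i:02d}", chrom="chr1", start=pos, end=pos + length,
            strand="+" if i % 2 == 0 else "-",
            exon_count=exons, mature_length=length,
        ))
        pos += length + int(rng.integers(5_000, 20_000))
    return anns


def run_pipeline(config: dict, log_level: int = logging.INFO) -> dict:
    """Run the configured stages; returns a dict of in-memory results.

    A stage failure raises :class:`StageError` naming the stage; outputs of
    completed stages remain on disk.
    """
    cfg = load_config(overrides=config) if config is not DEFAULT_CONFIG else config
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    stages = cfg["stages"]

    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("tilefate")
    root.addHandler(handler)
    root.setLevel(log_level)
    results: dict = {"config": cfg}
    try:
        root.info("configuration:\n%s", yaml.safe_dump(cfg, sort_keys=True))
        with open(out_dir / "config_echo.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)

        sim = cfg["simulate"]
        mc = MatcherConfig(**cfg["matcher"])

        current = "simulate"
        library = truth = fastqs = None
        if "simulate" in stages or "count" in stages:
            try:
                library = syn_mod.generate_tile_library(
                    sim["n_tiles"], sim["tile_length"], tuple(sim["gc_range"]),
                    seed=seed,
                )
                rng = np.random.default_rng(seed + 1)
                motif = ann_mod.MotifDef(**sim["motif"])
                shifts, motif_counts = {}, {}
                levels = sim["shift_levels"]
                for i, tid in enumerate(library.ids):
                    mcount = ann_mod.scan_motif(library[tid].sequence, motif)
                    motif_counts[tid] = mcount
                    shifts[tid] = levels[i % len(levels)] + sim["motif_shift"] * min(mcount, 2)
                truth = syn_mod.GroundTruth(shifts=shifts, motif_counts=motif_counts,
                                            seed=seed)
                design = pd.DataFrame([
                    {"sample_id": f"{frac}_rep{r}", "fraction": frac}
                    for r in range(1, sim["n_replicates"] + 1)
                    for frac in ("nuc", "cyto", "wce")
                ])
                fastqs, truth = syn_mod.simulate_fragment_reads(
                    library, design, out_dir / "fastq", shifts=truth,
                    adapter=mc.adapter, umi_length=sim["umi_length"],
                    depth=sim["depth"], error_rate=sim["error_rate"],
                    seed=seed + 2,
                )
                library.to_tsv(out_dir / "library.tsv")
                truth.to_tsv(out_dir / "ground_truth.tsv")
                design.to_csv(out_dir / "sample_sheet.tsv", sep="\t", index=False)
                results.update(library=library, truth=truth, fastqs=fastqs)
                root.info("simulate: %d tiles, %d samples", len(library), len(design))
            except Exception as exc:
                raise StageError(current, exc) from exc

        counts = None
        if "count" in stages:
            current = "count"
            try:
                counts, stats = count_samples(fastqs, library, mc)
                _write(counts, out_dir / "counts.tsv")
                _write(stats, out_dir / "match_stats.tsv")
                results.update(counts=counts, match_stats=stats)
                root.info("count: status totals\n%s", stats.to_string())
            except Exception as exc:
                raise StageError(current, exc) from exc

        summary = None
        if "localize" in stages and counts is not None:
            current = "localize"
            try:
                loc = cfg["localize"]
                nreps = sim["n_replicates"]
                pairing = [(f"nuc_rep{r}", f"cyto_rep{r}") for r in range(1, nreps + 1)]
                ratios = loc_mod.compute_ratios(
                    counts, pairing, pseudocount=loc["pseudocount"],
                    min_reads=mc.min_reads,
                    pair_names=[f"rep{r}" for r in range(1, nreps + 1)],
                )
                summary = loc_mod.call_localized_tiles(
                    loc_mod.summarize_ratios(ratios),
                    threshold=loc["threshold"], alpha=loc["alpha"],
                )
                _write(ratios, out_dir / "ratios_per_replicate.tsv")
                _write(summary, out_dir / "localization.tsv")
                results.update(ratios=ratios, localization=summary)
                root.info("localize: %s",
                          summary["localization"].value_counts().to_dict())
            except Exception as exc:
                raise StageError(current, exc) from exc

        if "stability" in stages and library is not None:
            current = "stability"
            try:
                st = cfg["stability"]
                hls = {tid: st["half_life_levels"][i % len(st["half_life_levels"])]
                       for i, tid in enumerate(library.ids)}
                mat, tmap = syn_mod.simulate_decay_series(
                    library, hls, timepoints=st["timepoints"],
                    noise_cv=st["noise_cv"], n_replicates=st["n_replicates"],
                    seed=seed + 3,
                )
                normed = stab_mod.spike_normalize(mat, ["spike_hi", "spike_lo"])
                fits = stab_mod.fit_all(normed, tmap)
                fits["true_half_life_h"] = pd.Series(hls)
                _write(fits, out_dir / "half_lives.tsv")
                results.update(decay_fits=fits, true_half_lives=hls)
                root.info("stability: fitted %d tiles", len(fits))
            except Exception as exc:
                raise StageError(current, exc) from exc

        if "circquant" in stages:
            current = "circquant"
            try:
                cc = cfg["circ"]
                rng = np.random.default_rng(seed + 4)
                anns = _demo_annotations(cc["n_circs"], rng)
                abundance = {
                    a.circ_id: {
                        "nuc": float(rng.integers(5, 200)),
                        "cyto": float(rng.integers(5, 200)),
                    }
                    for a in anns
                }
                jfiles = syn_mod.simulate_chimeric_junctions(
                    anns, abundance, out_dir / "junctions",
                    jitter_sd=cc["jitter_sd"], seed=seed + 5,
                )
                cmat = circ_mod.quantify(jfiles, anns, tolerance=cc["tolerance"])
                kept = circ_mod.filter_circs(
                    cmat, anns, min_pairs=cc["min_pairs"],
                    max_exons=cc["max_exons"], max_length=cc["max_length"],
                )
                out = kept.copy()
                out["log2_nuc_cyto"] = circ_mod.circ_ratios(
                    kept, "nuc", "cyto", pseudocount=cc["pseudocount"])
                _write(cmat, out_dir / "circ_counts_all.tsv")
                _write(out, out_dir / "circ_quant.tsv")
                results.update(circ_counts=cmat, circ_quant=out,
                               circ_annotations=anns, circ_truth=abundance)
                root.info("circquant: %d/%d circRNAs pass filters",
                          len(kept), len(cmat))
            except Exception as exc:
                raise StageError(current, exc) from exc

        if "annotate" in stages and summary is not None:
            current = "annotate"
            try:
                an = cfg["annotate"]
                motif = ann_mod.MotifDef(**sim["motif"])
                mcounts = ann_mod.count_motifs(library.sequences, [motif])
                strat = ann_mod.stratify(
                    summary["median_log2_ratio"], mcounts[motif.name],
                    bins=tuple(an["bins"]),
                )
                _write(strat["summary"], out_dir / "motif_strata.tsv")
                pw = pd.DataFrame(
                    [(a, b, p) for (a, b), p in strat["pairwise_p"].items()],
                    columns=["bin_a", "bin_b", "wilcoxon_p"],
                )
                pw.to_csv(out_dir / "motif_strata_tests.tsv", sep="\t", index=False)
                gc = pd.Series({tid: loc_mod.gc_content(s)
                                for tid, s in library.sequences.items()},
                               name="gc_fraction")
                dg = ann_mod.fold_energies(library.sequences)
                annot = pd.concat(
                    [mcounts, gc] + ([dg] if dg is not None else []), axis=1)
                _write(annot, out_dir / "tile_annotations.tsv")
                results.update(motif_counts=mcounts, stratification=strat,
                               annotations=annot)
                root.info("annotate: strata\n%s", strat["summary"].to_string())
            except Exception as exc:
                raise StageError(current, exc) from exc
        root.info("pipeline complete: stages %s", stages)
    finally:
        root.removeHandler(handler)
        handler.close()
    return results
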