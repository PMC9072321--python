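"""Synthetic inputs with known ground truth for every pipeline stage.

Emulates the experiment end to end: a designed tile library; single-end R1
amplicon reads laid out as ``[UMI][adapter][tile insert]`` with substitution
errors and Phred qualities; nuclear vs cytoplasmic read allocation skewed by
a known per-tile log2 shift; transcription-shutoff decay series carrying
known half-lives, a per-sample scale factor, and spike-ins that make the
scale factor recoverable; and chimeric junction records jittered around
annotated circRNA boundaries with Poisson-distributed support.

Everything is driven by a single integer seed and is bit-reproducible. The
generator emulates the *measurement* process (allocation, sampling noise,
base-call errors), not the biology that produced the true parameters: true
shifts and half-lives are inputs, not emergent quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .library import TileLibrary, TileRecord
from .matching import DEFAULT_ADAPTER

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class GroundTruth:
    """True per-feature parameters the pipeline should recover."""

    shifts: dict[str, float] = field(default_factory=dict)        # log2 Nuc/Cyto
    half_lives: dict[str, float] = field(default_factory=dict)    # hours
    motif_counts: dict[str, int] = field(default_factory=dict)
    circ_abundance: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int = 0

    def validate(self, library: TileLibrary | None = None) -> None:
        if any(h <= 0 for h in self.half_lives.values()):
            raise ValueError("half-lives must be > 0")
        for per_frac in self.circ_abundance.values():
            if any(a < 0 for a in per_frac.values()):
                raise ValueError("abundances must be >= 0")
        if library is not None:
            for d in (self.shifts, self.half_lives, self.motif_counts):
                unknown = [t for t in d if t not in library]
                if unknown:
                    raise ValueError(f"ground-truth ids not in library: {unknown}")

    def to_tsv(self, path: str | Path) -> None:
        keys = sorted(set(self.shifts) | set(self.half_lives) | set(self.motif_counts))
        with open(path, "w") as fh:
            fh.write("tile_id\tshift_log2\thalf_life_h\tmotif_count\n")
            for k in keys:
                fh.write(
                    f"{k}\t{self.shifts.get(k, '')}\t{self.half_lives.get(k, '')}"
                    f"\t{self.motif_counts.get(k, '')}\n"
                )


# ------------------------------------------------------------------ library


def generate_tile_library(
    n_tiles: int,
    tile_length: int = 140,
    gc_range: tuple[float, float] = (0.3, 0.7),
    seed: int = 0,
    id_prefix: str = "tile",
) -> TileLibrary:
    """Random tile library with per-tile G/C fraction inside *gc_range*.

    Each tile draws a G/C base count uniformly from the feasible integer
    range, places those bases at random positions, and fills the rest with
    A/T. Raises when no integer G/C count is compatible with *gc_range* at
    the given length (never silently clips).
    """
    if n_tiles < 1:
        raise ValueError("n_tiles must be >= 1")
    if tile_length < 30:
        raise ValueError("tile_length must be >= 30")
    lo, hi = gc_range
    if not (0 <= lo <= hi <= 1):
        raise ValueError(f"invalid gc_range {gc_range}")
    kmin = int(np.ceil(lo * tile_length - 1e-9))
    kmax = int(np.floor(hi * tile_length + 1e-9))
    if kmin > kmax:
        raise ValueError(
            f"gc_range {gc_range} infeasible at length {tile_length}: "
            f"no integer G/C count in [{lo * tile_length:.2f}, {hi * tile_length:.2f}]"
        )
    rng = np.random.default_rng(seed)
    lib = TileLibrary()
    seen: set[str] = set()
    width = len(str(n_tiles - 1)) if n_tiles > 1 else 1
    i = 0
    attempts = 0
    while i < n_tiles:
        attempts += 1
        if attempts > 50 * n_tiles + 100:
            raise RuntimeError("could not generate enough unique tiles")
        k = int(rng.integers(kmin, kmax + 1))
        arr = np.empty(tile_length, dtype=np.uint8)
        gc_pos = rng.choice(tile_length, size=k, replace=False)
        mask = np.zeros(tile_length, dtype=bool)
        mask[gc_pos] = True
        arr[mask] = np.where(rng.random(k) < 0.5, ord("G"), ord("C"))
        arr[~mask] = np.where(rng.random(tile_length - k) < 0.5, ord("A"), ord("T"))
        seq = arr.tobytes().decode()
        if seq in seen:
            continue
        seen.add(seq)
        lib.add(TileRecord(f"{id_prefix}{i:0{width}d}", seq, gene=f"gene{i % 7}"))
        i += 1
    return lib


# -------------------------------------------------------------- read maker


def _fraction_weight(fraction: str, shift: float) -> float:
    """Symmetric split: nuc x cyto expectation ratio = 2**shift."""
    if fraction == "nuc":
        return 2.0 ** (shift / 2.0)
    if fraction == "cyto":
        return 2.0 ** (-shift / 2.0)
    return 1.0  # wce / input / total


def _phred_qualities(rng, shape, mean=37.0, sd=4.0, lo=2, hi=41):
    q = np.rint(rng.normal(mean, sd, size=shape))
    return np.clip(q, lo, hi).astype(np.uint8)


def simulate_fragment_reads(
    library: TileLibrary,
    design: pd.DataFrame,
    out_dir: str | Path,
    shifts: GroundTruth | dict[str, float] | None = None,
    adapter: str = DEFAULT_ADAPTER,
    umi_length: int = 10,
    depth: float = 200.0,
    error_rate: float = 0.001,
    indel_rate: float = 0.0,
    read_length: int = 150,
    quality_mean: float = 37.0,
    quality_sd: float = 4.0,
    seed: int = 0,
) -> tuple[dict[str, Path], GroundTruth]:
    """Write one FASTQ per sample row of *design*; return paths + ground truth.

    *design* needs columns ``sample_id`` and ``fraction`` (``nuc``, ``cyto``
    or anything else for whole-cell/input). Per tile and sample the read
    count is Poisson with mean ``depth * w``, where w = 2**(shift/2) in the
    nuclear and 2**(-shift/2) in the cytoplasmic fraction, so the expected
    Nuc/Cyto count ratio is 2**shift. Reads are
    ``[UMI][adapter][insert]`` truncated to *read_length*; substitution
    errors at *error_rate* hit insert bases only, and every base gets a
    Phred score from a rounded normal(quality_mean, quality_sd) truncated to
    [2, 41] (straddling the Q35 matching rule). An optional *indel_rate*
    deletes one random insert base from that fraction of reads (the gapless
    matcher should route such reads to the unmatched class).
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if not (0 <= error_rate < 0.5):
        raise ValueError("error_rate must be in [0, 0.5)")
    if not (0 <= indel_rate <= 1):
        raise ValueError("indel_rate must be in [0, 1]")
    for col in ("sample_id", "fraction"):
        if col not in design.columns:
            raise ValueError(f"design missing column {col!r}")
    if isinstance(shifts, GroundTruth):
        truth = shifts
    else:
        truth = GroundTruth(shifts=dict(shifts or {}), seed=seed)
    truth.validate(library)
    shift_of = {tid: truth.shifts.get(tid, 0.0) for tid in library.ids}

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    tile_ids = library.ids
    insert_cap = read_length - umi_length - len(adapter)
    if insert_cap <= 0:
        raise ValueError("read_length too short for UMI + adapter + insert")
    # tile inserts as a base-index matrix, padded rows for shorter tiles
    max_ins = min(insert_cap, max(len(library[t].sequence) for t in tile_ids))
    lut = np.full(256, -1, dtype=np.int8)
    for b, i in zip(b"ACGT", range(4)):
        lut[b] = i
    tile_mat = np.zeros((len(tile_ids), max_ins), dtype=np.int8)
    tile_len = np.empty(len(tile_ids), dtype=int)
    for r, tid in enumerate(tile_ids):
        s = library[tid].sequence[:max_ins]
        tile_len[r] = len(s)
        tile_mat[r, :len(s)] = lut[np.frombuffer(s.encode(), dtype=np.uint8)]

    adapter_arr = np.frombuffer(adapter.encode(), dtype=np.uint8)
    paths: dict[str, Path] = {}
    for row in design.itertuples():
        sample = str(row.sample_id)
        frac = str(row.fraction)
        weights = np.array([_fraction_weight(frac, shift_of[t]) for t in tile_ids])
        n_per_tile = rng.poisson(depth * weights)
        n = int(n_per_tile.sum())
        tidx = np.repeat(np.arange(len(tile_ids)), n_per_tile)
        rng.shuffle(tidx)

        inserts = tile_mat[tidx].copy()
        if error_rate > 0:
            err = rng.random(inserts.shape) < error_rate
            # errors only within each tile's real length
            err &= np.arange(max_ins) < tile_len[tidx][:, None]
            k = int(err.sum())
            inserts[err] = (inserts[err] + rng.integers(1, 4, size=k)) % 4

        umi = _BASES[rng.integers(0, 4, size=(n, umi_length))]
        seq = np.empty((n, umi_length + len(adapter) + max_ins), dtype=np.uint8)
        seq[:, :umi_length] = umi
        seq[:, umi_length:umi_length + len(adapter)] = adapter_arr
        seq[:, umi_length + len(adapter):] = _BASES[inserts]
        qual = _phred_qualities(rng, seq.shape, quality_mean, quality_sd) + 33

        if indel_rate > 0:
            has_del = rng.random(n) < indel_rate
            del_pos = rng.integers(0, np.maximum(tile_len[tidx], 1))
        else:
            has_del = np.zeros(n, dtype=bool)
            del_pos = None

        path = out_dir / f"{sample}.fastq"
        paths[sample] = path
        width = seq.shape[1]
        offset = umi_length + len(adapter)
        seq_str = seq.tobytes().decode()
        qual_str = qual.astype(np.uint8).tobytes().decode()
        with open(path, "w") as fh:
            chunk: list[str] = []
            for i in range(n):
                tl = tile_len[tidx[i]]
                end = offset + tl
                base = i * width
                s = seq_str[base:base + end]
                q = qual_str[base:base + end]
                if has_del[i] and tl > 0:
                    cut = offset + int(del_pos[i])
                    s = s[:cut] + s[cut + 1:]
                    q = q[:cut] + q[cut + 1:]
                chunk.append(f"@{sample}:{i}\n{s}\n+\n{q}\n")
                if len(chunk) >= 20000:
                    fh.write("".join(chunk))
                    chunk = []
            fh.write("".join(chunk))
    return paths, truth


# ------------------------------------------------------------- decay series


def simulate_decay_series(
    library: TileLibrary,
    half_lives: dict[str, float],
    timepoints: list[float] = (0.0, 2.0, 4.0, 8.0),
    spike_ids: tuple[str, ...] = ("spike_hi", "spike_lo"),
    spike_level: float = 1000.0,
    spike_ratio: float = 10.0,
    noise_cv: float = 0.0,
    baseline: float = 10000.0,
    n_replicates: int = 1,
    scale_factors: dict | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Tile x sample level matrix for a transcription-shutoff time course.

    Expected tile signal at time t is ``baseline * 2**(-t / half_life)``
    multiplied by a per-sample scale factor that the spike-in rows also carry
    (so spike normalization is identifiable); two spike species at a
    *spike_ratio* : 1 input ratio are emitted. Multiplicative lognormal noise
    with coefficient of variation *noise_cv* applies to tiles and spikes.
    Sample columns are named ``t{hours}h_rep{r}``. Returns (matrix,
    timepoint-of-sample mapping).
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if 0.0 not in [float(t) for t in timepoints]:
        raise ValueError("timepoints must include 0")
    if any(h <= 0 for h in half_lives.values()):
        raise ValueError("half-lives must be > 0")
    unknown = [t for t in half_lives if t not in library]
    if unknown:
        raise ValueError(f"half-life ids not in library: {unknown}")
    rng = np.random.default_rng(seed)
    tiles = library.ids
    hl = np.array([half_lives.get(t, 4.0) for t in tiles])
    sigma = np.sqrt(np.log1p(noise_cv**2)) if noise_cv > 0 else 0.0

    spike_in = np.array([spike_level * spike_ratio, spike_level][:len(spike_ids)])
    cols, tmap = {}, {}
    for t in timepoints:
        for r in range(1, n_replicates + 1):
            name = f"t{t:g}h_rep{r}"
            if scale_factors and name in scale_factors:
                scale = float(scale_factors[name])
            else:
                scale = float(rng.uniform(0.5, 2.0))
            signal = baseline * 2.0 ** (-float(t) / hl) * scale
            spikes = spike_in * scale
            if sigma > 0:
                signal = signal * rng.lognormal(-sigma**2 / 2, sigma, len(signal))
                spikes = spikes * rng.lognormal(-sigma**2 / 2, sigma, len(spikes))
            cols[name] = np.concatenate([signal, spikes])
            tmap[name] = float(t)
    mat = pd.DataFrame(cols, index=tiles + list(spike_ids))
    mat.index.name = "tile_id"
    return mat, tmap


# -------------------------------------------------------- chimeric records


def simulate_chimeric_junctions(
    annotations,
    abundance: dict[str, dict[str, float]],
    out_dir: str | Path,
    jitter_sd: float = 0.0,
    fixed_jitter: int | None = None,
    seed: int = 0,
) -> dict[str, Path]:
    """Write one junction-record file per fraction sample.

    *abundance* maps circ_id -> {sample: expected read pairs}; per circRNA
    and sample the emitted record count is Poisson around that expectation,
    and each record's donor/acceptor positions are the annotated boundaries
    plus independent rounded-normal jitter with SD *jitter_sd* nt (or a
    constant offset when *fixed_jitter* is given, for boundary studies).
    """
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    from .circ import _boundaries_1based  # single source for the convention

    ann_by_id = {a.circ_id: a for a in annotations}
    unknown = [c for c in abundance if c not in ann_by_id]
    if unknown:
        raise ValueError(f"abundance for unannotated circRNA(s): {unknown}")
    samples = sorted({s for per in abundance.values() for s in per})
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for sample in samples:
        lines = []
        for cid, per_sample in abundance.items():
            lam = per_sample.get(sample, 0.0)
            n = int(rng.poisson(lam))
            ann = ann_by_id[cid]
            b_acc, b_don = _boundaries_1based(ann)
            if fixed_jitter is not None:
                j_d = j_a = np.full(n, int(fixed_jitter))
            elif jitter_sd > 0:
                j_d = np.rint(rng.normal(0, jitter_sd, n)).astype(int)
                j_a = np.rint(rng.normal(0, jitter_sd, n)).astype(int)
            else:
                j_d = j_a = np.zeros(n, dtype=int)
            for i in range(n):
                don = max(1, b_don + int(j_d[i]))
                acc = max(1, b_acc + int(j_a[i]))
                lines.append(
                    f"{ann.chrom}\t{don}\t{ann.strand}\t{ann.chrom}\t{acc}\t"
                    f"{ann.strand}\t1\t0\t0\t{sample}:{cid}:{i}\n"
                )
        rng.shuffle(lines)
        path = out_dir / f"{sample}.junctions.tsv"
        paths[sample] = path
        with open(path, "w") as fh:
            fh.writelines(lines)
    return paths
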