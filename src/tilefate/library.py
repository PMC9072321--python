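"""Tile library container and IO.

A *tile* is a short designed sequence fragment (typically 110 or 140 nt)
inserted into a reporter backbone; the tile library is the unit against which
every downstream statistic (localization ratio, half-life, motif count) is
computed. Libraries are read and written as FASTA or as a three-column TSV
(``tile_id``, ``gene``, ``sequence``).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class TileRecord:
    """One designed insert sequence."""

    tile_id: str
    sequence: str
    gene: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("U", "T")
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - VALID_BASES
        if bad:
            raise ValueError(
                f"tile {self.tile_id!r} contains non-ACGT characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


class TileLibrary:
    """Ordered, id-unique collection of :class:`TileRecord`."""

    def __init__(self, tiles: list[TileRecord] | None = None):
        self._tiles: dict[str, TileRecord] = {}
        for t in tiles or []:
            self.add(t)

    def add(self, tile: TileRecord) -> None:
        if tile.tile_id in self._tiles:
            raise ValueError(f"duplicate tile id {tile.tile_id!r}")
        self._tiles[tile.tile_id] = tile

    def __len__(self) -> int:
        return len(self._tiles)

    def __iter__(self) -> Iterator[TileRecord]:
        return iter(self._tiles.values())

    def __contains__(self, tile_id: str) -> bool:
        return tile_id in self._tiles

    def __getitem__(self, tile_id: str) -> TileRecord:
        return self._tiles[tile_id]

    @property
    def ids(self) -> list[str]:
        return list(self._tiles)

    @property
    def sequences(self) -> dict[str, str]:
        return {tid: t.sequence for tid, t in self._tiles.items()}

    # ------------------------------------------------------------------ IO

    @classmethod
    def from_fasta(cls, path: str | Path) -> "TileLibrary":
        lib = cls()
        for rec in SeqIO.parse(str(path), "fasta"):
            gene = rec.description.split(maxsplit=1)[1] if " " in rec.description else ""
            lib.add(TileRecord(rec.id, str(rec.seq), gene=gene))
        if len(lib) == 0:
            raise ValueError(f"no FASTA records in {path}")
        return lib

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TileLibrary":
        lib = cls()
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            try:
                i_id = header.index("tile_id")
                i_gene = header.index("gene")
                i_seq = header.index("sequence")
            except ValueError as exc:
                raise ValueError(
                    f"{path}: expected columns tile_id, gene, sequence; got {header}"
                ) from exc
            for line in fh:
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                lib.add(TileRecord(parts[i_id], parts[i_seq], gene=parts[i_gene]))
        return lib

    @classmethod
    def load(cls, path: str | Path) -> "TileLibrary":
        """Load FASTA (.fa/.fasta) or TSV by extension."""
        p = Path(path)
        if p.suffix.lower() in {".fa", ".fasta", ".fna"}:
            return cls.from_fasta(p)
        return cls.from_tsv(p)

    def to_fasta(self, path: str | Path) -> None:
        recs = [
            SeqRecord(Seq(t.sequence), id=t.tile_id, description=t.gene)
            for t in self
        ]
        SeqIO.write(recs, str(path), "fasta")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("tile_id\tgene\tsequence\n")
            for t in self:
                fh.write(f"{t.tile_id}\t{t.gene}\t{t.sequence}\n")
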