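"""Readers and writers for the standard formats the pipeline touches.

Genomes are held in two layers: an *unmasked* layer with every base
upper-cased, and a *masked* layer in which soft-masked (lowercase) bases
have been hardened to ``N``.  All coordinates are 0-based, half-open;
minus-strand requests return the reverse complement of the plus-strand
slice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "GenomeSource",
    "PslHit",
    "ParseError",
    "revcomp",
    "read_fasta",
    "write_fasta",
    "read_tss_table",
    "write_tss_table",
    "read_psl",
    "read_axt",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ParseError(ValueError):
    """A malformed record in an input file."""


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase A/C/G/T/N sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeSource:
    """Per-chromosome sequence access with masked and unmasked layers."""

    unmasked: dict[str, str] = field(default_factory=dict)
    masked: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_sequences(cls, seqs: dict[str, str]) -> "GenomeSource":
        """Build from raw sequences; lowercase letters are soft-masked."""
        g = cls()
        for name, raw in seqs.items():
            g.add(name, raw)
        return g

    def add(self, name: str, raw: str) -> None:
        unmasked = []
        masked = []
        for ch in raw:
            up = ch.upper()
            if up not in "ACGT":
                up = "N"
            unmasked.append(up)
            masked.append("N" if ch.islower() else up)
        self.unmasked[name] = "".join(unmasked)
        self.masked[name] = "".join(masked)

    def chromosomes(self) -> list[str]:
        return list(self.unmasked)

    def length(self, chrom: str) -> int:
        return len(self.unmasked[chrom])

    def fetch(
        self, chrom: str, start: int, end: int, strand: str = "+", layer: str = "unmasked"
    ) -> str:
        """Sequence of ``[start, end)`` on ``chrom``; minus strand is
        the reverse complement of the plus-strand slice."""
        if layer not in ("masked", "unmasked"):
            raise ValueError(f"unknown layer {layer!r}")
        if chrom not in self.unmasked:
            raise KeyError(f"unknown chromosome {chrom!r}")
        seq = self.masked[chrom] if layer == "masked" else self.unmasked[chrom]
        if start < 0 or end > len(seq) or start > end:
            raise IndexError(
                f"window [{start}, {end}) outside {chrom!r} of length {len(seq)}"
            )
        sub = seq[start:end]
        return revcomp(sub) if strand == "-" else sub


def read_fasta(path: str | Path) -> GenomeSource:
    """Parse FASTA into a :class:`GenomeSource`.

    Lowercase letters are treated as soft-masked; letters outside
    A/C/G/T (e.g. ambiguity codes) become ``N`` in both layers.
    """
    genome = GenomeSource()
    name: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    genome.add(name, "".join(chunks))
                name = line[1:].split()[0] if line[1:].split() else ""
                if not name:
                    raise ParseError(f"{path}: empty FASTA header at line {lineno}")
                chunks = []
            else:
                if name is None:
                    raise ParseError(
                        f"{path}: sequence before first header at line {lineno}"
                    )
                chunks.append(line.strip())
    if name is not None:
        genome.add(name, "".join(chunks))
    return genome


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, max(len(seq), 1), width):
                fh.write(seq[i : i + width] + "\n")


def read_tss_table(path: str | Path, min_clones: int = 0):
    """Read a TSS table (chrom, position, strand, gene, clone count).

    Records supported by fewer than ``min_clones`` clones are removed;
    input order is preserved.
    """
    from .promoters import TSSRecord

    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ParseError(
                    f"{path}: expected 5 tab-separated columns at line {lineno}"
                )
            chrom, pos_s, strand, gene, clones_s = parts
            try:
                pos = int(pos_s)
                clones = int(clones_s)
            except ValueError as exc:
                raise ParseError(
                    f"{path}: non-integer position or clone count at line {lineno}"
                ) from exc
            if strand not in "+-":
                raise ParseError(f"{path}: bad strand {strand!r} at line {lineno}")
            if clones >= min_clones:
                records.append(TSSRecord(chrom, pos, strand, gene, clones))
    return records


def write_tss_table(records, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.position}\t{r.strand}\t{r.gene}\t{r.clones}\n")


@dataclass(frozen=True)
class PslHit:
    """One BLAT hit in PSL format (0-based, half-open coordinates)."""

    matches: int
    strand: str
    q_name: str
    q_size: int
    q_start: int
    q_end: int
    t_name: str
    t_size: int
    t_start: int
    t_end: int
    block_sizes: tuple[int, ...]
    q_starts: tuple[int, ...]
    t_starts: tuple[int, ...]

    @property
    def span(self) -> int:
        """Target span in bases."""
        return self.t_end - self.t_start

    @property
    def identity(self) -> float:
        """Matching bases over the target span."""
        return self.matches / self.span


def _csv_ints(field_: str) -> tuple[int, ...]:
    return tuple(int(x) for x in field_.rstrip(",").split(",") if x)


def read_psl(path: str | Path) -> list[PslHit]:
    """Parse PSL (with or without the 5-line header)."""
    hits: list[PslHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            first = line.split("\t")[0]
            if not first or not first[0].isdigit():
                continue  # header / separator lines
            parts = line.split("\t")
            if len(parts) != 21:
                raise ParseError(
                    f"{path}: expected 21 PSL columns at line {lineno}, got {len(parts)}"
                )
            try:
                hits.append(
                    PslHit(
                        matches=int(parts[0]),
                        strand=parts[8],
                        q_name=parts[9],
                        q_size=int(parts[10]),
                        q_start=int(parts[11]),
                        q_end=int(parts[12]),
                        t_name=parts[13],
                        t_size=int(parts[14]),
                        t_start=int(parts[15]),
                        t_end=int(parts[16]),
                        block_sizes=_csv_ints(parts[18]),
                        q_starts=_csv_ints(parts[19]),
                        t_starts=_csv_ints(parts[20]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}: bad PSL field at line {lineno}") from exc
    return hits


def write_psl(hits: Sequence[PslHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            nblocks = len(h.block_sizes)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.matches, 0, 0, 0, 0, 0, 0, 0,
                        h.strand, h.q_name, h.q_size, h.q_start, h.q_end,
                        h.t_name, h.t_size, h.t_start, h.t_end, nblocks,
                        ",".join(map(str, h.block_sizes)) + ",",
                        ",".join(map(str, h.q_starts)) + ",",
                        ",".join(map(str, h.t_starts)) + ",",
                    )
                )
                + "\n"
            )


def read_axt(path: str | Path) -> list[tuple[str, str]]:
    """Read axt blocks into (row A, row B) pairs of equal length.

    Used as background alignments for the divergence-spectrum stage.
    """
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line or line.startswith("#"):
            i += 1
            continue
        # header line, then two sequence rows
        if i + 2 >= len(lines):
            raise ParseError(f"{path}: truncated axt block at line {i + 1}")
        a = lines[i + 1].strip().upper()
        b = lines[i + 2].strip().upper()
        if len(a) != len(b):
            raise ParseError(
                f"{path}: row-length mismatch in axt block at line {i + 1}"
            )
        pairs.append((a, b))
        i += 3
    return pairs


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
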