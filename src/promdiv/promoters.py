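"""TSS-anchored promoter windows.

A promoter window is excised around a transcription start site in
transcript orientation: index ``upstream`` holds the +1 base (the
traditional "position 0"), smaller indices are biologically upstream.
For minus-strand TSSs the window is the reverse complement of the
plus-strand slice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io import GenomeSource

logger = logging.getLogger(__name__)

PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")


@dataclass(frozen=True)
class TSSRecord:
    """One transcription start site.

    ``position`` is the 0-based genomic index of the +1 base.
    """

    chrom: str
    position: int
    strand: str
    gene: str
    clones: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.clones < 0:
            raise ValueError("clone count must be non-negative")


@dataclass(frozen=True)
class PromoterWindow:
    """A transcript-oriented sequence window anchored on a TSS."""

    sequence: str
    anchor: TSSRecord
    upstream: int
    downstream: int
    species: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) != self.upstream + 1 + self.downstream:
            raise ValueError(
                f"window length {len(self.sequence)} != "
                f"{self.upstream} + 1 + {self.downstream}"
            )

    @property
    def tss_index(self) -> int:
        return self.upstream

    @property
    def tss_base(self) -> str:
        return self.sequence[self.upstream]

    def header(self) -> str:
        a = self.anchor
        return f"{self.species}|{a.gene}|{a.chrom}|{a.position}|{a.strand}"

    def trim(self, upstream: int, downstream: int) -> "PromoterWindow":
        """A narrower window around the same TSS (e.g. the 34/5 logo
        window from a 300/300 one)."""
        if upstream > self.upstream or downstream > self.downstream:
            raise ValueError("cannot trim beyond the existing flanks")
        i = self.upstream
        seq = self.sequence[i - upstream : i + downstream + 1]
        return PromoterWindow(seq, self.anchor, upstream, downstream, self.species)


class WindowBoundsError(IndexError):
    """The requested window extends beyond the chromosome."""


def extract_window(
    genome: GenomeSource,
    tss: TSSRecord,
    upstream: int,
    downstream: int,
    layer: str = "unmasked",
    species: str = "",
) -> PromoterWindow:
    """Excise ``upstream + 1 + downstream`` bases around the TSS,
    oriented along the transcript."""
    n = genome.length(tss.chrom)
    if tss.strand == "+":
        start, end = tss.position - upstream, tss.position + downstream + 1
    else:
        start, end = tss.position - downstream, tss.position + upstream + 1
    if start < 0 or end > n:
        raise WindowBoundsError(
            f"window [{start}, {end}) for {tss.gene} exceeds {tss.chrom} (len {n})"
        )
    seq = genome.fetch(tss.chrom, start, end, strand=tss.strand, layer=layer)
    return PromoterWindow(seq, tss, upstream, downstream, species)


def check_yr(window: PromoterWindow) -> bool:
    """True iff the initiator signature holds: a pyrimidine at -1 and a
    purine at the start site.  ``N`` at either position fails."""
    i = window.tss_index
    if i < 1:
        raise ValueError("window has no upstream base at -1")
    return window.sequence[i - 1] in PYRIMIDINES and window.sequence[i] in PURINES


def refseq_dbtss_offsets(
    refseq_5ends: Mapping[str, Sequence[int]],
    dbtss: Mapping[str, TSSRecord],
) -> dict[str, int]:
    """Transcript-oriented distance of the nearest RefSeq 5' end from the
    experimentally supported TSS, per gene.

    The raw distance is RefSeq position minus TSS position; on the minus
    strand the sign is flipped, so negative always means the RefSeq end
    lies upstream of the TSS in transcript orientation.  Among a gene's
    transcript variants the one nearest the TSS is kept.  Genes absent
    from either input are skipped (counted in the log).
    """
    offsets: dict[str, int] = {}
    skipped = 0
    for gene, tss in dbtss.items():
        ends = refseq_5ends.get(gene)
        if not ends:
            skipped += 1
            continue
        sign = 1 if tss.strand == "+" else -1
        best = min((sign * (e - tss.position) for e in ends), key=lambda d: (abs(d), d))
        offsets[gene] = best
    skipped += sum(1 for g in refseq_5ends if g not in dbtss)
    if skipped:
        logger.info("refseq_dbtss_offsets: %d genes absent from one input", skipped)
    return offsets


def windows_to_fasta_records(windows: Iterable[PromoterWindow]):
    for w in windows:
        yield w.header(), w.sequence
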