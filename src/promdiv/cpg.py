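"""G+C content, CpG score, and CpG-island promoter classification.

The CpG score is the Gardiner-Garden & Frommer observed/expected ratio
``n_CpG * N / (n_C * n_G)``.  A 601-nt promoter window is called a
CpG-island promoter when G+C content >= 0.5 and CpG score >= 0.6
(thresholds inclusive, configurable).  The two thresholds partition
promoters into four quadrants; orthologous pairs are grouped by the two
island flags (hCmC, hCmN, hNmC, hNmN).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .io import revcomp

__all__ = [
    "CpGStats",
    "PromoterClass",
    "PairGroup",
    "cpg_stats",
    "classify",
    "count_type_changes",
    "island_gain_copy_number",
]


@dataclass(frozen=True)
class CpGStats:
    length: int
    n_cpg: int
    n_c: int
    n_g: int
    gc: float
    score: float


def cpg_stats(sequence: str) -> CpGStats:
    """Base and CpG statistics of an uppercase A/C/G/T/N sequence.

    ``N`` bases are excluded from the C/G/CpG counts but the denominator
    stays the full window length.  The score is defined as 0 when
    ``n_C * n_G`` is 0.
    """
    n = len(sequence)
    if n == 0:
        raise ValueError("cpg_stats of an empty sequence is undefined")
    n_c = sequence.count("C")
    n_g = sequence.count("G")
    n_cpg = sequence.count("CG")
    gc = (n_c + n_g) / n
    score = (n_cpg * n) / (n_c * n_g) if n_c and n_g else 0.0
    return CpGStats(n, n_cpg, n_c, n_g, gc, score)


class PromoterClass(enum.Enum):
    """The four quadrants of the (G+C content, CpG score) plane."""

    LOW_GC_HIGH_CPG = "low-GC/high-CpG"
    HIGH_GC_HIGH_CPG = "high-GC/high-CpG"   # CpG-island promoters
    LOW_GC_LOW_CPG = "low-GC/low-CpG"
    HIGH_GC_LOW_CPG = "high-GC/low-CpG"

    @property
    def is_island(self) -> bool:
        return self is PromoterClass.HIGH_GC_HIGH_CPG


QUADRANT_ORDER = [
    PromoterClass.LOW_GC_HIGH_CPG,
    PromoterClass.HIGH_GC_HIGH_CPG,
    PromoterClass.LOW_GC_LOW_CPG,
    PromoterClass.HIGH_GC_LOW_CPG,
]


def classify(
    stats: CpGStats, gc_threshold: float = 0.5, score_threshold: float = 0.6
) -> PromoterClass:
    """Quadrant of a promoter; island iff gc >= 0.5 and score >= 0.6."""
    high_gc = stats.gc >= gc_threshold
    high_cpg = stats.score >= score_threshold
    if high_cpg:
        return PromoterClass.HIGH_GC_HIGH_CPG if high_gc else PromoterClass.LOW_GC_HIGH_CPG
    return PromoterClass.HIGH_GC_LOW_CPG if high_gc else PromoterClass.LOW_GC_LOW_CPG


class PairGroup(enum.Enum):
    """Island status of an orthologous pair: human (h) x macaque (m)."""

    hCmC = "hCmC"
    hCmN = "hCmN"
    hNmC = "hNmC"
    hNmN = "hNmN"

    @classmethod
    def from_flags(cls, human_island: bool, macaque_island: bool) -> "PairGroup":
        return {
            (True, True): cls.hCmC,
            (True, False): cls.hCmN,
            (False, True): cls.hNmC,
            (False, False): cls.hNmN,
        }[(human_island, macaque_island)]


def count_type_changes(
    pairs: Iterable[tuple[PromoterClass, PromoterClass]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quadrant-transition counts between the two species.

    Returns the 4x4 quadrant matrix (rows: species A, columns:
    species B) and the 2x2 island/non-island collapse.  The 4x4 matrix
    sums to the number of pairs.
    """
    labels = [q.value for q in QUADRANT_ORDER]
    quad = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    island = pd.DataFrame(
        0, index=["island", "non-island"], columns=["island", "non-island"], dtype=int
    )
    for a, b in pairs:
        quad.loc[a.value, b.value] += 1
        island.loc[
            "island" if a.is_island else "non-island",
            "island" if b.is_island else "non-island",
        ] += 1
    return quad, island


def strand_symmetric_stats(sequence: str) -> tuple[CpGStats, CpGStats]:
    """Stats of a sequence and its reverse complement (gc and score are
    identical because CG is its own reverse complement)."""
    return cpg_stats(sequence), cpg_stats(revcomp(sequence))


def island_gain_copy_number(
    sequence: str,
    motif: str = "TCGGC",
    insert_at: int | None = None,
    gc_threshold: float = 0.5,
    score_threshold: float = 0.6,
    max_copies: int = 500,
) -> tuple[int, list[CpGStats]]:
    """Number of tandem ``motif`` copies whose insertion first turns a
    non-island sequence into a CpG-island promoter.

    Successive copies are inserted contiguously at ``insert_at``
    (default: the sequence midpoint), emulating island gain through
    expansion of a CpG-containing repeat unit.  Returns the first copy
    number at which both thresholds hold, together with the stats track
    for copies 0..k.
    """
    if insert_at is None:
        insert_at = len(sequence) // 2
    track = [cpg_stats(sequence)]
    for k in range(1, max_copies + 1):
        expanded = sequence[:insert_at] + motif * k + sequence[insert_at:]
        st = cpg_stats(expanded)
        track.append(st)
        if classify(st, gc_threshold, score_threshold).is_island:
            return k, track
    raise RuntimeError(f"no island gain within {max_copies} copies of {motif!r}")
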