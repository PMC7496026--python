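"""Orthologous promoter location and refined global pairwise alignment.

BLAT-style hits (PSL) are filtered for identity and span, the human TSS
column is mapped through the hit's block structure onto the counterpart
genome, and the candidate is extended to a 601-nt window centred on the
initiator dinucleotide.  Pairs are then globally aligned under an
affine-gap model and filtered on a 0-100 alignment score, defined as
percent matching columns over the shorter ungapped sequence.
"""

from __future__ import annotations

import functools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .io import GenomeSource, PslHit
from .promoters import PromoterWindow, TSSRecord, WindowBoundsError, check_yr, extract_window

logger = logging.getLogger(__name__)

ALPHABET = "ACGTN"


@dataclass(frozen=True)
class AlignParams:
    """Affine-gap scoring: a gap of length L costs open + (L-1)*extend.

    N scores as a mismatch against everything, including N.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = 10.0
    gap_extend: float = 0.2
    min_score: float = 90.0

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")


@dataclass
class PairwiseAlignment:
    """Two gapped rows of equal length plus per-column match structure."""

    row_a: str
    row_b: str
    dp_score: float = 0.0
    a_tss: int | None = None   # ungapped index of the TSS base in A
    b_tss: int | None = None
    pair_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.row_a) != len(self.row_b):
            raise ValueError("alignment rows must have equal length")
        if any(a == "-" and b == "-" for a, b in zip(self.row_a, self.row_b)):
            raise ValueError("column with gaps in both rows")

    @property
    def ungapped_a(self) -> str:
        return self.row_a.replace("-", "")

    @property
    def ungapped_b(self) -> str:
        return self.row_b.replace("-", "")

    def column_classes(self) -> list[str]:
        """Per column: match, mismatch, gap_a (gap in A) or gap_b."""
        out = []
        for a, b in zip(self.row_a, self.row_b):
            if a == "-":
                out.append("gap_a")
            elif b == "-":
                out.append("gap_b")
            elif a == b and a != "N":
                out.append("match")
            else:
                out.append("mismatch")
        return out

    @property
    def n_matches(self) -> int:
        return sum(
            1
            for a, b in zip(self.row_a, self.row_b)
            if a == b and a != "-" and a != "N"
        )

    def column_of(self, row: str, ungapped_index: int) -> int:
        """Alignment column holding ungapped base ``ungapped_index`` of
        the given row ('A' or 'B')."""
        seq = self.row_a if row == "A" else self.row_b
        seen = -1
        for col, ch in enumerate(seq):
            if ch != "-":
                seen += 1
                if seen == ungapped_index:
                    return col
        raise IndexError(f"ungapped index {ungapped_index} beyond row {row}")


def alignment_score(aln: PairwiseAlignment) -> float:
    """100 x match columns / min(ungapped length A, ungapped length B)."""
    denom = min(len(aln.ungapped_a), len(aln.ungapped_b))
    if denom == 0:
        raise ValueError("alignment of empty sequences")
    return 100.0 * aln.n_matches / denom


@functools.lru_cache(maxsize=32)
def _aligner(params: AlignParams) -> Align.PairwiseAligner:
    matrix = substitution_matrices.Array(ALPHABET, dims=2)
    for x in ALPHABET:
        for y in ALPHABET:
            matrix[x, y] = (
                params.match if (x == y and x != "N") else params.mismatch
            )
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def global_align(
    a: str, b: str, params: AlignParams | None = None, pair_id: str = ""
) -> PairwiseAlignment:
    """Optimal global alignment under affine-gap scoring.

    The first alignment in the aligner's canonical enumeration order is
    returned, making the output deterministic for fixed inputs.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    params = params or AlignParams()
    aligner = _aligner(params)
    aln = aligner.align(a, b)[0]
    return PairwiseAlignment(
        row_a=str(aln[0]), row_b=str(aln[1]), dp_score=aln.score, pair_id=pair_id
    )


def select_candidate(
    hits: Sequence[PslHit], min_identity: float = 0.90, min_span: int = 200
) -> PslHit | None:
    """The longest hit (by target span) passing both the identity and
    span filters; None if no hit passes."""
    passing = [h for h in hits if h.identity >= min_identity and h.span >= min_span]
    if not passing:
        return None
    return max(passing, key=lambda h: (h.span, h.matches))


def map_query_to_target(hit: PslHit, q_pos: int) -> int | None:
    """Target coordinate aligned to forward-query position ``q_pos``,
    or None if the position falls between blocks.

    For minus-strand hits the PSL block coordinates refer to the
    reverse-complemented query, per the PSL convention.
    """
    p = q_pos if hit.strand == "+" else hit.q_size - 1 - q_pos
    for size, qs, ts in zip(hit.block_sizes, hit.q_starts, hit.t_starts):
        if qs <= p < qs + size:
            return ts + (p - qs)
    return None


def anchor_and_extend(
    hit: PslHit,
    genome: GenomeSource,
    tss_offset_in_query: int = 300,
    half_width: int = 300,
    species: str = "macaque",
) -> tuple[PromoterWindow | None, str | None]:
    """Map the human TSS through the hit and extend to a fixed-length
    window centred on the initiator dinucleotide.

    Returns ``(window, None)`` on success or ``(None, reason)`` with
    reason ``"unmapped"`` (TSS column not covered by a block),
    ``"no-YR"`` (mapped dinucleotide is not pyrimidine-purine), or
    ``"gap"`` (window crosses a contig edge or contains N).
    """
    t_pos = map_query_to_target(hit, tss_offset_in_query)
    if t_pos is None:
        return None, "unmapped"
    strand = "+" if hit.strand == "+" else "-"
    tss = TSSRecord(hit.t_name, t_pos, strand, hit.q_name)
    try:
        window = extract_window(
            genome, tss, half_width, half_width, layer="unmasked", species=species
        )
    except WindowBoundsError:
        return None, "gap"
    if not check_yr(window):
        return None, "no-YR"
    if "N" in window.sequence:
        return None, "gap"
    return window, None


def filter_pairs(
    alignments: Iterable[PairwiseAlignment],
    min_score: float = 90.0,
    require_yr_match: bool = True,
) -> list[PairwiseAlignment]:
    """Keep pairs scoring at least ``min_score`` whose initiator
    dinucleotide is identical across species at the anchored columns."""
    kept = []
    n_score = n_yr = 0
    for aln in alignments:
        if alignment_score(aln) < min_score:
            n_score += 1
            continue
        if require_yr_match:
            if aln.a_tss is None:
                raise ValueError("YR-match filter needs the TSS column (a_tss)")
            ok = True
            for idx in (aln.a_tss - 1, aln.a_tss):
                col = aln.column_of("A", idx)
                a_ch, b_ch = aln.row_a[col], aln.row_b[col]
                if a_ch != b_ch or a_ch in "-N":
                    ok = False
                    break
            if not ok:
                n_yr += 1
                continue
        kept.append(aln)
    logger.info(
        "filter_pairs: kept %d, dropped %d below score %.4g, %d YR mismatches",
        len(kept), n_score, min_score, n_yr,
    )
    return kept
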