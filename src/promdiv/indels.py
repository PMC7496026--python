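"""Indel detection and characterization in refined promoter alignments.

Each maximal gap run in one alignment row is one indel site; the row
with bases is the *carrier*.  Sites are filtered on conservation of the
10 alignment columns flanking the run (>=8 matches on both sides by
default), characterized by length, single-nucleotide base, and the
signed change in CpG count attributable to the indel (junction-spanning
CpGs included via one flanking base on each side), and, when fragment
presence is known for outgroup primates, polarized into insertion or
deletion by single-event parsimony on the accepted species tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .align import PairwiseAlignment
from .cpg import PairGroup

__all__ = [
    "IndelSite",
    "detect_indels",
    "flank_filter",
    "indel_length_histogram",
    "single_nt_bias",
    "cpg_delta",
    "left_normalize",
    "polarize_indel",
    "PRIMATE_TREE",
    "DEFAULT_LENGTH_CLASSES",
]


@dataclass
class IndelSite:
    """One maximal gap run in a pairwise alignment."""

    aln_id: str
    start_col: int
    end_col: int            # half-open column interval of the gap run
    carrier: str            # row holding bases: "A" or "B"
    sequence: str
    left_matches: int = 0
    right_matches: int = 0
    left_truncated: bool = False
    right_truncated: bool = False
    cpg_delta: int = 0

    @property
    def length(self) -> int:
        return self.end_col - self.start_col

    @property
    def base(self) -> str | None:
        """The inserted/deleted nucleotide, for single-nt sites."""
        return self.sequence if self.length == 1 else None

    @property
    def edge_truncated(self) -> bool:
        return self.left_truncated or self.right_truncated


def _flank_matches(
    aln: PairwiseAlignment, cols: range, width: int
) -> tuple[int, bool]:
    """Match count over up to ``width`` columns; gap columns count as
    mismatches.  Truncated when fewer than ``width`` columns exist."""
    matches = 0
    n = 0
    for c in cols:
        n += 1
        a, b = aln.row_a[c], aln.row_b[c]
        if a == b and a not in "-N":
            matches += 1
    return matches, n < width


def detect_indels(
    aln: PairwiseAlignment, flank_width: int = 10, aln_id: str | None = None
) -> list[IndelSite]:
    """One :class:`IndelSite` per maximal gap run in either row.

    Adjacent runs separated by at least one non-gap column are distinct
    sites.  Flank match counts are computed on the ``flank_width``
    alignment columns each side of the run; runs touching an alignment
    edge are reported with the available columns only and flagged
    truncated.
    """
    aln_id = aln_id if aln_id is not None else aln.pair_id
    sites: list[IndelSite] = []
    ncol = len(aln.row_a)
    for gap_row, carrier in (("A", "B"), ("B", "A")):
        gapped = aln.row_a if gap_row == "A" else aln.row_b
        carrier_row = aln.row_b if gap_row == "A" else aln.row_a
        col = 0
        while col < ncol:
            if gapped[col] != "-":
                col += 1
                continue
            start = col
            while col < ncol and gapped[col] == "-":
                col += 1
            end = col
            left, left_trunc = _flank_matches(
                aln, range(max(0, start - flank_width), start), flank_width
            )
            right, right_trunc = _flank_matches(
                aln, range(end, min(ncol, end + flank_width)), flank_width
            )
            site = IndelSite(
                aln_id=aln_id,
                start_col=start,
                end_col=end,
                carrier=carrier,
                sequence=carrier_row[start:end],
                left_matches=left,
                right_matches=right,
                left_truncated=left_trunc,
                right_truncated=right_trunc,
            )
            site.cpg_delta = cpg_delta(site, aln)
            sites.append(site)
    sites.sort(key=lambda s: (s.start_col, s.carrier))
    return sites


def flank_filter(site: IndelSite, min_match: int = 8) -> bool:
    """Keep iff both 10-column flanks show ``min_match`` or more matches
    and neither flank is edge-truncated."""
    return (
        not site.edge_truncated
        and site.left_matches >= min_match
        and site.right_matches >= min_match
    )


def cpg_delta(site: IndelSite, aln: PairwiseAlignment, junction: int = 1) -> int:
    """Signed CpG-count change attributable to the indel.

    CpGs are counted on both rows over the gap-run columns extended by
    ``junction`` columns on each side (ungapped), so CpGs spanning the
    indel junctions are included; the delta is carrier minus
    counterpart.
    """
    start = max(0, site.start_col - junction)
    end = min(len(aln.row_a), site.end_col + junction)
    carrier_row = aln.row_a if site.carrier == "A" else aln.row_b
    other_row = aln.row_b if site.carrier == "A" else aln.row_a
    carrier_seg = carrier_row[start:end].replace("-", "")
    other_seg = other_row[start:end].replace("-", "")
    return carrier_seg.count("CG") - other_seg.count("CG")


DEFAULT_LENGTH_CLASSES: tuple[tuple[int, int | None], ...] = (
    (1, 1), (2, 4), (5, 9), (10, 19), (20, None),
)


def indel_length_histogram(
    sites: Iterable[IndelSite],
    classes: Sequence[tuple[int, int | None]] = DEFAULT_LENGTH_CLASSES,
) -> dict[str, int]:
    """Site counts by length class (default 1, 2-4, 5-9, 10-19, 20+)."""
    def label(lo: int, hi: int | None) -> str:
        if hi is None:
            return f"{lo}+"
        return str(lo) if lo == hi else f"{lo}-{hi}"

    hist = {label(lo, hi): 0 for lo, hi in classes}
    for s in sites:
        for lo, hi in classes:
            if s.length >= lo and (hi is None or s.length <= hi):
                hist[label(lo, hi)] += 1
                break
    return hist


def single_nt_bias(
    sites: Sequence[IndelSite], pair_groups: Sequence[PairGroup]
) -> pd.DataFrame:
    """Fractions of A/C/G/T among single-nucleotide indels, per pair
    group.  Groups with no single-nt site get an all-NaN row."""
    if len(sites) != len(pair_groups):
        raise ValueError("sites and pair_groups must be parallel")
    counts = pd.DataFrame(
        0, index=[g.value for g in PairGroup], columns=list("ACGT"), dtype=float
    )
    for site, group in zip(sites, pair_groups):
        base = site.base
        if base is not None and base in "ACGT":
            counts.loc[group.value, base] += 1
    totals = counts.sum(axis=1)
    return counts.div(totals.where(totals > 0), axis=0)


def left_normalize(carrier_seq: str, pos: int, length: int) -> tuple[int, str]:
    """Canonical leftmost-equivalent placement of an indel.

    ``carrier_seq`` is the ungapped sequence of the row that carries the
    extra bases; the indel occupies ``carrier_seq[pos:pos+length]``.
    Shifting left by one is allowed whenever the base entering the
    window equals the base leaving it, which leaves both sequences of
    the pair unchanged — the standard left-alignment used for variant
    normalization.
    """
    while pos > 0 and carrier_seq[pos - 1] == carrier_seq[pos + length - 1]:
        pos -= 1
    return pos, carrier_seq[pos : pos + length]


def carrier_position(site: IndelSite, aln: PairwiseAlignment) -> int:
    """Index of the indel's first base in the carrier's ungapped
    sequence."""
    row = aln.row_a if site.carrier == "A" else aln.row_b
    return sum(1 for c in row[: site.start_col] if c != "-")


# Accepted primate phylogeny over the six species compared.
PRIMATE_TREE = (
    ((("human", "chimpanzee"), "gorilla"), ("macaque", "baboon")),
    "marmoset",
)


def _clades(tree) -> list[frozenset[str]]:
    if isinstance(tree, str):
        return [frozenset([tree])]
    out: list[frozenset[str]] = []
    leaves: set[str] = set()
    for child in tree:
        sub = _clades(child)
        out.extend(sub)
        leaves |= set().union(*sub)
    out.append(frozenset(leaves))
    return out


def polarize_indel(
    presence: Mapping[str, bool], tree=PRIMATE_TREE
) -> tuple[str, frozenset[str] | None]:
    """Classify a fragment's presence/absence pattern as an insertion or
    deletion by single-event parsimony on the fixed species tree.

    A placement is a branch whose descendant leaves (restricted to
    species with known state) carry one state while all other known
    species carry the other.  If every placement implies the same event
    type, that type is returned with the smallest implicated clade;
    otherwise — two or more events required, or tied placements of
    opposite type (e.g. a change on either side of the root) — the call
    is ``ambiguous``.
    """
    known = {sp: bool(st) for sp, st in presence.items()}
    if len(known) < 3 or len(set(known.values())) < 2:
        return "ambiguous", None
    all_clades = _clades(tree)
    full = max(all_clades, key=len)
    placements: dict[tuple[frozenset[str], str], frozenset[str]] = {}
    for clade in all_clades:
        if clade == full:
            continue
        inside = {sp for sp in known if sp in clade}
        outside = {sp for sp in known if sp not in clade}
        if not inside or not outside:
            continue
        in_states = {known[sp] for sp in inside}
        out_states = {known[sp] for sp in outside}
        if len(in_states) != 1 or len(out_states) != 1 or in_states == out_states:
            continue
        event = "insertion" if in_states == {True} else "deletion"
        key = (frozenset(inside), event)
        if key not in placements or len(clade) < len(placements[key]):
            placements[key] = clade
    if not placements:
        return "ambiguous", None
    types = {event for (_, event) in placements}
    if len(types) != 1:
        return "ambiguous", None
    event = types.pop()
    clade = min(placements.values(), key=len)
    return event, clade
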