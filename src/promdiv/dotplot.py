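"""Harr plots (dot plots) and repeat association of indel neighborhoods.

A dot at (i, j) marks an exact match between the ``window``-length
word starting at i in sequence A and the word at j in sequence B
(direct orientation) or its reverse complement (reverse-complement
orientation).  Windows containing N never match.  Off-diagonal dots of
a self-plot that intersect an indel interval indicate a tandem repeat
(direct) or an inverted repeat (reverse complement).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from .align import PairwiseAlignment
from .indels import IndelSite, carrier_position
from .io import revcomp

__all__ = ["DotPlot", "harr_plot", "repeat_association"]


@dataclass
class DotPlot:
    window: int
    stride: int
    orientation: str                  # "direct" | "revcomp"
    dots: frozenset[tuple[int, int]]  # (i in A, j in B)
    n_a: int
    n_b: int


def harr_plot(
    a: str,
    b: str,
    window: int = 5,
    stride: int = 1,
    orientation: str = "direct",
) -> DotPlot:
    """Exact-match dot set between two sequences.

    In reverse-complement orientation a window of A dots against
    position j of B when it equals the reverse complement of B's window
    at j.
    """
    if orientation not in ("direct", "revcomp"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if len(a) < window or len(b) < window:
        raise ValueError("sequence shorter than the dot-plot window")
    index: dict[str, list[int]] = defaultdict(list)
    for j in range(0, len(b) - window + 1, stride):
        word = b[j : j + window]
        if "N" in word:
            continue
        if orientation == "revcomp":
            word = revcomp(word)
        index[word].append(j)
    dots = set()
    for i in range(0, len(a) - window + 1, stride):
        word = a[i : i + window]
        if "N" in word:
            continue
        for j in index.get(word, ()):
            dots.add((i, j))
    return DotPlot(window, stride, orientation, frozenset(dots), len(a), len(b))


def _intersects(i: int, window: int, lo: int, hi: int) -> bool:
    """Does window [i, i+window) overlap interval [lo, hi)?"""
    return i < hi and i + window > lo


def repeat_association(
    site: IndelSite,
    aln: PairwiseAlignment,
    neighborhood: int = 25,
    window: int = 5,
) -> dict[str, bool]:
    """Tandem/inverted-repeat association of an indel site.

    The carrier-row region spanning the indel plus ``neighborhood``
    bases each side is self-plotted.  ``tandem`` is true when the
    direct plot has an off-diagonal dot whose window intersects the
    indel interval; ``inverted`` likewise for the reverse-complement
    plot.
    """
    if site.length < window:
        raise ValueError(
            f"repeat association needs an indel of length >= {window}"
        )
    row = aln.row_a if site.carrier == "A" else aln.row_b
    pos = carrier_position(site, aln)
    carrier_seq = row.replace("-", "")
    lo = max(0, pos - neighborhood)
    hi = min(len(carrier_seq), pos + site.length + neighborhood)
    region = carrier_seq[lo:hi]
    ind_lo, ind_hi = pos - lo, pos - lo + site.length
    result = {}
    for key, orientation in (("tandem", "direct"), ("inverted", "revcomp")):
        plot = harr_plot(region, region, window=window, orientation=orientation)
        result[key] = any(
            i != j
            and (
                _intersects(i, window, ind_lo, ind_hi)
                or _intersects(j, window, ind_lo, ind_hi)
            )
            for i, j in plot.dots
        )
    return result
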