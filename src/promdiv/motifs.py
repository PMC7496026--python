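"""Position frequency matrices for logo windows and TATAAA scanning.

The logo window spans 34 nt upstream to 5 nt downstream of the TSS
(positions -34 .. +5, 40 nt).  Information content per position is
2 - H in bits, with H the Shannon entropy of the base frequencies;
frequencies are computed over non-N observations without small-sample
correction — matrices, not rendered images, are the contract here.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .promoters import PromoterWindow

BASES = list("ACGT")


@dataclass
class LogoMatrix:
    """Per-position base frequencies and information content."""

    frequencies: pd.DataFrame     # positions x ACGT
    information: pd.Series        # bits, in [0, 2]
    counts: pd.DataFrame
    empty_positions: list[int]    # positions with zero non-N observations

    @property
    def positions(self) -> list[int]:
        return list(self.frequencies.index)


def position_frequency_matrix(windows: Sequence[PromoterWindow]) -> LogoMatrix:
    """Frequencies/information over equal-length, equally anchored
    windows; N bases are excluded per position."""
    if not windows:
        raise ValueError("no windows given")
    length = len(windows[0].sequence)
    upstream = windows[0].upstream
    for w in windows:
        if len(w.sequence) != length or w.upstream != upstream:
            raise ValueError("windows must share length and TSS offset")
    counts = np.zeros((length, 4), dtype=int)
    base_index = {b: k for k, b in enumerate(BASES)}
    for w in windows:
        for i, ch in enumerate(w.sequence):
            k = base_index.get(ch)
            if k is not None:
                counts[i, k] += 1
    positions = [i - upstream for i in range(length)]
    counts_df = pd.DataFrame(counts, index=positions, columns=BASES)
    totals = counts.sum(axis=1)
    empty = [positions[i] for i in np.nonzero(totals == 0)[0]]
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = counts / totals[:, None]
        plogp = np.where(freq > 0, freq * np.log2(freq), 0.0)
    info = 2.0 + plogp.sum(axis=1)
    info[totals == 0] = np.nan
    freq_df = pd.DataFrame(freq, index=positions, columns=BASES)
    return LogoMatrix(freq_df, pd.Series(info, index=positions), counts_df, empty)


def tataaa_scan(
    windows: Iterable[PromoterWindow],
    scan_width: int = 40,
    motif: str = "TATAAA",
) -> Counter[int]:
    """Histogram of TATAAA 5'-end positions within the upstream scan
    region.

    Only occurrences lying wholly within positions [-scan_width, -1]
    relative to the TSS contribute; overlapping occurrences are all
    counted.  Keys are TSS-relative 5'-end positions.
    """
    hist: Counter[int] = Counter()
    m = len(motif)
    for w in windows:
        up = w.upstream
        if up < scan_width:
            raise ValueError(
                f"window has {up} upstream bases, scan needs {scan_width}"
            )
        lo = up - scan_width            # window index of position -scan_width
        hi = up - m                     # last admissible start (ends at -1)
        region = w.sequence
        for i in range(lo, hi + 1):
            if region[i : i + m] == motif:
                hist[i - up] += 1
    return hist
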