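"""Naive reference implementations used to validate the fast paths.

These are deliberately brute-force — exhaustive enumeration of all
gapped alignments, all-pairs window comparison, literal motif counting
— and share no code with the implementations they check.  They are
only feasible at tiny problem sizes.
"""

from __future__ import annotations

from .align import AlignParams

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def brute_force_align_score(a: str, b: str, params: AlignParams | None = None) -> float:
    """Optimal global alignment score by exhaustive enumeration of all
    gapped alignments (affine gap cost: open + (L-1) * extend).

    Exponential in len(a) + len(b); intended for lengths <= ~8.
    """
    params = params or AlignParams()
    best = [float("-inf")]

    def recurse(i: int, j: int, score: float, last: str) -> None:
        if i == len(a) and j == len(b):
            if score > best[0]:
                best[0] = score
            return
        if i < len(a) and j < len(b):
            s = params.match if (a[i] == b[j] and a[i] != "N") else params.mismatch
            recurse(i + 1, j + 1, score + s, "M")
        if i < len(a):
            cost = params.gap_extend if last == "D" else params.gap_open
            recurse(i + 1, j, score - cost, "D")
        if j < len(b):
            cost = params.gap_extend if last == "I" else params.gap_open
            recurse(i, j + 1, score - cost, "I")

    recurse(0, 0, 0.0, "")
    return best[0]


def brute_force_dots(
    a: str, b: str, window: int = 5, orientation: str = "direct"
) -> set[tuple[int, int]]:
    """All-pairs exact window comparison; windows containing N never
    match."""
    dots = set()
    for i in range(len(a) - window + 1):
        wa = a[i : i + window]
        if "N" in wa:
            continue
        for j in range(len(b) - window + 1):
            wb = b[j : j + window]
            if "N" in wb:
                continue
            if orientation == "revcomp":
                wb = "".join(_COMPLEMENT[ch] for ch in reversed(wb))
            if wa == wb:
                dots.add((i, j))
    return dots


def brute_force_motif_count(sequences, motif: str = "TATAAA") -> int:
    """Total overlapping occurrences of a literal motif."""
    total = 0
    for seq in sequences:
        for i in range(len(seq) - len(motif) + 1):
            if seq[i : i + len(motif)] == motif:
                total += 1
    return total
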