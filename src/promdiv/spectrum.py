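"""Dinucleotide divergence spectra between aligned promoters.

For a chosen source row, every overlapping dinucleotide of the ungapped
source sequence is classified as conserved or altered against its
aligned counterpart: a dinucleotide counts as altered when either
counterpart base differs, is a gap, is N, or when inserted counterpart
bases fall between the two source positions.  Source CpG sites are
additionally classified by their fate (CpG, TpG, CpA, other, or
gap-containing), separating deamination products from other changes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .align import PairwiseAlignment

DINUCLEOTIDES = ["".join(p) for p in itertools.product("ACGT", repeat=2)]

FATES = ["CpG", "TpG", "CpA", "other", "gap"]


@dataclass
class DinucSpectrum:
    """Totals, altered counts and rates for the 16 dinucleotides,
    pooled over all alignments in a group."""

    totals: dict[str, int]
    altered: dict[str, int]

    @property
    def rates(self) -> dict[str, float]:
        return {
            d: (self.altered[d] / self.totals[d]) if self.totals[d] else float("nan")
            for d in DINUCLEOTIDES
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "total": pd.Series(self.totals),
                "altered": pd.Series(self.altered),
                "rate": pd.Series(self.rates),
            }
        ).loc[DINUCLEOTIDES]


@dataclass
class CpGFate:
    """Counts of source CpG sites by aligned counterpart."""

    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> dict[str, float]:
        t = self.total
        return {f: (self.counts[f] / t if t else float("nan")) for f in FATES}


def _rows(aln: PairwiseAlignment, source: str) -> tuple[str, str]:
    if source == "A":
        return aln.row_a, aln.row_b
    if source == "B":
        return aln.row_b, aln.row_a
    raise ValueError("source must be 'A' or 'B'")


def _iter_source_dinucs(aln: PairwiseAlignment, source: str):
    """Yield (source dinucleotide, counterpart dinucleotide or None).

    The counterpart is None when it involves a gap, an N, or inserted
    counterpart bases between the two source columns.
    """
    src, other = _rows(aln, source)
    cols = [i for i, ch in enumerate(src) if ch != "-"]
    for c1, c2 in zip(cols, cols[1:]):
        d = src[c1] + src[c2]
        if "N" in d:
            continue  # not one of the 16 dinucleotides
        clean = (
            c2 == c1 + 1
            and other[c1] not in "-N"
            and other[c2] not in "-N"
        )
        yield d, (other[c1] + other[c2]) if clean else None


def dinuc_alteration_rates(
    alignments: Iterable[PairwiseAlignment], source: str = "A"
) -> DinucSpectrum:
    """Alteration rate of each of the 16 dinucleotides of the source
    species, pooled over alignments."""
    totals = {d: 0 for d in DINUCLEOTIDES}
    altered = {d: 0 for d in DINUCLEOTIDES}
    for aln in alignments:
        for d, counterpart in _iter_source_dinucs(aln, source):
            totals[d] += 1
            if counterpart is None or counterpart != d:
                altered[d] += 1
    return DinucSpectrum(totals, altered)


def cpg_fate_spectrum(
    alignments: Iterable[PairwiseAlignment], source: str = "A"
) -> CpGFate:
    """Classify every source CpG site by its aligned counterpart."""
    counts = {f: 0 for f in FATES}
    for aln in alignments:
        for d, counterpart in _iter_source_dinucs(aln, source):
            if d != "CG":
                continue
            if counterpart is None:
                counts["gap"] += 1
            elif counterpart == "CG":
                counts["CpG"] += 1
            elif counterpart == "TG":
                counts["TpG"] += 1
            elif counterpart == "CA":
                counts["CpA"] += 1
            else:
                counts["other"] += 1
    return CpGFate(counts)


def deamination_enrichment(
    group_changed: Sequence[PairwiseAlignment],
    group_conserved: Sequence[PairwiseAlignment],
    source: str = "A",
) -> float:
    """Ratio of per-CpG deamination-product frequencies (CpG aligned to
    TpG or CpA) between a type-change group and a conserved-island
    group.  Returns ``inf`` when the conserved group shows no
    transitions; raises when either group has no source CpG."""
    freqs = []
    for group in (group_changed, group_conserved):
        fate = cpg_fate_spectrum(group, source)
        if fate.total == 0:
            raise ValueError("group contains no source CpG site")
        freqs.append((fate.counts["TpG"] + fate.counts["CpA"]) / fate.total)
    changed, conserved = freqs
    if conserved == 0.0:
        return math.inf
    return changed / conserved


def estimate_deamination_multiplier(
    alignments: Iterable[PairwiseAlignment], source: str = "A"
) -> float:
    """Recover the CpG transition multiplier from aligned output.

    Per-site estimator.  Conditioning on a CpG in the *source* row
    means the source branch did not mutate there, so the mismatch rate
    of source CpG-context bases measures the counterpart branch alone
    (m x r per site).  The background mismatch rate sees both branches
    (1 - (1-r)^2), so it is converted to a per-branch rate before the
    ratio.  Source positions that could be deamination products of the
    source branch (the T of a TpG, the A of a CpA) are excluded from
    the background, since their counterpart carries the ancestral CpG
    at an elevated rate; this is also why a dinucleotide-level ratio of
    spectrum rows would be biased low.  Columns whose counterpart is a
    gap or N are excluded throughout, so indels do not contribute.
    """
    ctx_total = ctx_mm = bg_total = bg_mm = 0
    for aln in alignments:
        src, other = _rows(aln, source)
        cols = [i for i, ch in enumerate(src) if ch != "-"]
        ungapped = "".join(src[c] for c in cols)
        n = len(ungapped)
        for k, c in enumerate(cols):
            s = ungapped[k]
            if s == "N" or other[c] in "-N":
                continue
            nxt = ungapped[k + 1] if k + 1 < n else ""
            prv = ungapped[k - 1] if k > 0 else ""
            in_ctx = (s == "C" and nxt == "G") or (s == "G" and prv == "C")
            product = (s == "T" and nxt == "G") or (s == "A" and prv == "C")
            mm = other[c] != s
            if in_ctx:
                ctx_total += 1
                ctx_mm += mm
            elif not product:
                bg_total += 1
                bg_mm += mm
    if ctx_total == 0 or bg_total == 0 or bg_mm == 0:
        raise ValueError("insufficient aligned sites to estimate the multiplier")
    ctx_rate = ctx_mm / ctx_total
    per_branch_bg = 1.0 - math.sqrt(max(0.0, 1.0 - bg_mm / bg_total))
    if per_branch_bg == 0.0:
        raise ValueError("background divergence is zero")
    return ctx_rate / per_branch_bg
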