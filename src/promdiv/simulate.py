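"""Synthetic orthologous promoter-pair cohorts with complete ground truth.

One ancestral 601-nt promoter per pair is drawn in one of two
composition classes — CpG-island-like (G+C ~ 0.60, CpG obs/exp ~ 0.8)
or non-island (G+C ~ 0.42, CpG obs/exp ~ 0.25) — with a central
pyrimidine-purine initiator dinucleotide, then evolved independently on
two branches ("human" and "macaque") under:

* per-site substitutions, with C->T at CpG sites (and G->A for the
  complementary strand context) elevated by a configurable multiplier
  over the base rate, emulating deamination of methylated cytosine;
* homopolymer slippage indels (one base gained or lost at a run);
* tandem duplication/deletion of short units (5-10 nt, or a pool motif
  such as TCGGC) adjacent to an existing copy.

Every event is logged; replaying the log on the ancestor reproduces the
derived sequence exactly, so each pipeline stage can be tested against
known truth.  The central initiator dinucleotide is exempt from
mutation by default so that the YR-match filter does not confound
recovery tests; ``protect_center=False`` lifts the exemption.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

from .cpg import PairGroup, PromoterClass, classify, cpg_stats
from .io import write_fasta
from .promoters import PromoterWindow, TSSRecord

BASES = "ACGT"
_COMP = {"C": "T", "G": "A"}  # deamination products by strand context


@dataclass(frozen=True)
class SimConfig:
    n_pairs: int = 100
    island_fraction: float = 0.5
    length: int = 601
    island_gc: float = 0.60
    island_cpg_score: float = 0.80
    nonisland_gc: float = 0.42
    nonisland_cpg_score: float = 0.25
    composition_tolerance: float = 0.05
    sub_rate: float = 0.01            # per site, per branch
    cpg_multiplier: float = 10.0      # deamination rate factor at CpG
    slip_rate: float = 0.1            # expected slippage events per branch
    tandem_rate: float = 0.05         # expected tandem dup/del per branch
    motif_pool: tuple[str, ...] = ("TCGGC",)
    motif_prob: float = 0.25          # tandem event uses a pool motif
    protect_center: bool = True
    edge_margin: int = 15             # indels keep clear of sequence ends
    min_indel_spacing: int = 30       # and of each other / the centre
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("cohort size must be >= 1")
        if self.length % 2 == 0:
            raise ValueError("length must be odd so a central TSS exists")
        if self.cpg_multiplier < 1:
            raise ValueError("CpG multiplier must be >= 1")
        for name in ("island_fraction", "sub_rate", "motif_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class Substitution:
    position: int        # ancestor coordinate
    from_base: str
    to_base: str
    cpg_context: bool


@dataclass(frozen=True)
class IndelEvent:
    position: int        # ancestor coordinate (post-substitution)
    kind: str            # "insertion" | "deletion"
    sequence: str
    mechanism: str       # "slippage" | "tandem-dup" | "tandem-del"
    derived_position: int = -1


@dataclass
class MutationLog:
    """Ground truth for one branch: replaying it on the ancestor
    reproduces the derived sequence exactly."""

    substitutions: list[Substitution] = field(default_factory=list)
    indels: list[IndelEvent] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "substitutions": [dataclasses.asdict(s) for s in self.substitutions],
            "indels": [dataclasses.asdict(e) for e in self.indels],
        }


def replay(ancestor: str, log: MutationLog) -> str:
    """Apply a mutation log to the ancestor: substitutions first, then
    indels in left-to-right order."""
    seq = list(ancestor)
    for s in log.substitutions:
        if seq[s.position] != s.from_base:
            raise ValueError(f"log mismatch at {s.position}")
        seq[s.position] = s.to_base
    base = "".join(seq)
    out = []
    cursor = 0
    for ev in sorted(log.indels, key=lambda e: e.position):
        out.append(base[cursor : ev.position])
        if ev.kind == "insertion":
            out.append(ev.sequence)
            cursor = ev.position
        else:
            segment = base[ev.position : ev.position + len(ev.sequence)]
            if segment != ev.sequence:
                raise ValueError(f"log deletion mismatch at {ev.position}")
            cursor = ev.position + len(ev.sequence)
    out.append(base[cursor:])
    return "".join(out)


def map_to_derived(log: MutationLog, pos: int) -> int:
    """Derived-sequence coordinate of ancestor position ``pos``."""
    offset = 0
    for ev in sorted(log.indels, key=lambda e: e.position):
        n = len(ev.sequence)
        if ev.kind == "insertion":
            if ev.position <= pos:
                offset += n
        else:
            if ev.position + n <= pos:
                offset -= n
            elif ev.position <= pos:
                raise ValueError(f"ancestor position {pos} was deleted")
    return pos + offset


def _transition_matrix(gc: float, score: float) -> np.ndarray:
    """First-order chain whose stationary composition is near the G+C
    target and whose CpG observed/expected ratio is near ``score``:
    the C->G transition is down-weighted to score * p(G), the removed
    mass redistributed proportionally."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    mat = np.tile(p, (4, 1))
    c, g = 1, 2
    row = p.copy()
    row[g] = score * p[g]
    others = [0, 1, 3]
    row[others] *= (1 - row[g]) / (1 - p[g])
    mat[c] = row / row.sum()
    return mat


def simulate_ancestor(
    promoter_class: str,
    config: SimConfig,
    rng: np.random.Generator,
    max_retries: int = 500,
) -> str:
    """Draw an ancestral promoter of the requested class ("island" or
    "nonisland") with a central YR dinucleotide; rejection-sample until
    G+C and CpG score are within the composition tolerance of the
    class targets."""
    if promoter_class == "island":
        gc_t, score_t = config.island_gc, config.island_cpg_score
    elif promoter_class == "nonisland":
        gc_t, score_t = config.nonisland_gc, config.nonisland_cpg_score
    else:
        raise ValueError(f"unknown class {promoter_class!r}")
    mat = _transition_matrix(gc_t, score_t)
    cum = np.cumsum(mat, axis=1)
    p0 = np.array([(1 - gc_t) / 2, gc_t / 2, gc_t / 2, (1 - gc_t) / 2])
    cum0 = np.cumsum(p0)
    n = config.length
    center = (n - 1) // 2
    tol = config.composition_tolerance
    for _ in range(max_retries):
        u = rng.random(n)
        idx = np.empty(n, dtype=np.int64)
        idx[0] = np.searchsorted(cum0, u[0])
        for i in range(1, n):
            idx[i] = np.searchsorted(cum[idx[i - 1]], u[i])
        seq = list("".join(BASES[k] for k in idx))
        seq[center - 1] = "CT"[rng.integers(2)]
        seq[center] = "AG"[rng.integers(2)]
        seq = "".join(seq)
        st = cpg_stats(seq)
        if abs(st.gc - gc_t) <= tol and abs(st.score - score_t) <= tol:
            return seq
    raise RuntimeError(
        f"could not reach composition targets ({gc_t}, {score_t}) "
        f"in {max_retries} attempts"
    )


def _protected(config: SimConfig, length: int) -> set[int]:
    if not config.protect_center:
        return set()
    center = (length - 1) // 2
    return {center - 1, center}


def _apply_substitutions(
    seq: str, config: SimConfig, rng: np.random.Generator
) -> tuple[str, list[Substitution]]:
    n = len(seq)
    protected = _protected(config, n)
    cpg_context = [False] * n
    for i in range(n - 1):
        if seq[i] == "C" and seq[i + 1] == "G":
            cpg_context[i] = cpg_context[i + 1] = True
    u = rng.random(n)
    pick = rng.integers(0, 3, size=n)
    out = list(seq)
    subs: list[Substitution] = []
    p_cpg = min(1.0, config.cpg_multiplier * config.sub_rate)
    for i, ch in enumerate(seq):
        if i in protected or ch == "N":
            continue
        if cpg_context[i]:
            if u[i] < p_cpg:
                to = _COMP[ch]
                out[i] = to
                subs.append(Substitution(i, ch, to, True))
        elif u[i] < config.sub_rate:
            alternatives = [b for b in BASES if b != ch]
            to = alternatives[pick[i]]
            out[i] = to
            subs.append(Substitution(i, ch, to, False))
    return "".join(out), subs


def _homopolymer_runs(seq: str, min_len: int = 3) -> list[tuple[int, int, str]]:
    runs = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len and seq[i] != "N":
            runs.append((i, j - i, seq[i]))
        i = j
    return runs


def _anchor_ok(
    pos: int, span: int, taken: list[tuple[int, int]], config: SimConfig, length: int
) -> bool:
    if pos < config.edge_margin or pos + span > length - config.edge_margin:
        return False
    if config.protect_center:
        center = (length - 1) // 2
        if abs(pos - center) < config.min_indel_spacing or abs(
            pos + span - center
        ) < config.min_indel_spacing:
            return False
    return all(
        pos + span + config.min_indel_spacing <= lo
        or pos >= hi + config.min_indel_spacing
        for lo, hi in taken
    )


def _draw_indels(
    seq: str, config: SimConfig, rng: np.random.Generator
) -> list[IndelEvent]:
    n = len(seq)
    events: list[IndelEvent] = []
    taken: list[tuple[int, int]] = []

    def claim(pos: int, span: int) -> bool:
        if _anchor_ok(pos, span, taken, config, n):
            taken.append((pos, pos + span))
            return True
        return False

    n_slip = rng.poisson(config.slip_rate)
    n_tandem = rng.poisson(config.tandem_rate)

    for _ in range(n_slip):
        runs = _homopolymer_runs(seq)
        rng.shuffle(runs)
        for start, run_len, base in runs:
            if not claim(start, 1):
                continue
            if rng.random() < 0.5:
                events.append(IndelEvent(start, "insertion", base, "slippage"))
            else:
                events.append(IndelEvent(start, "deletion", base, "slippage"))
            break

    for _ in range(n_tandem):
        use_motif = rng.random() < config.motif_prob and config.motif_pool
        duplicate = rng.random() < 0.5
        placed = False
        if use_motif:
            motif = config.motif_pool[int(rng.integers(len(config.motif_pool)))]
            occ = _occurrences(seq, motif)
            if duplicate or not occ:
                # insert a copy adjacent to an existing one, or seed the
                # first copy at a random admissible position
                candidates = occ or list(
                    rng.integers(config.edge_margin, n - config.edge_margin, size=20)
                )
                rng.shuffle(candidates)
                for p in candidates:
                    p = int(p)
                    if claim(p, 0):
                        events.append(IndelEvent(p, "insertion", motif, "tandem-dup"))
                        placed = True
                        break
            else:
                adjacent = [p for p in occ if seq[p + len(motif) : p + 2 * len(motif)] == motif]
                rng.shuffle(adjacent)
                for p in adjacent:
                    if claim(p, len(motif)):
                        events.append(IndelEvent(p, "deletion", motif, "tandem-del"))
                        placed = True
                        break
        if placed or use_motif:
            continue
        k = int(rng.integers(5, 11))
        if duplicate:
            for _ in range(20):
                p = int(rng.integers(config.edge_margin, n - config.edge_margin - k))
                unit = seq[p : p + k]
                if "N" not in unit and claim(p, 0):
                    events.append(IndelEvent(p, "insertion", unit, "tandem-dup"))
                    break
        else:
            pairs = [
                p
                for p in range(config.edge_margin, n - config.edge_margin - 2 * k)
                if seq[p : p + k] == seq[p + k : p + 2 * k] and "N" not in seq[p : p + k]
            ]
            rng.shuffle(pairs)
            for p in pairs:
                if claim(p, k):
                    events.append(IndelEvent(p, "deletion", seq[p : p + k], "tandem-del"))
                    break

    events.sort(key=lambda e: e.position)
    out = []
    offset = 0
    for ev in events:
        out.append(dataclasses.replace(ev, derived_position=ev.position + offset))
        offset += len(ev.sequence) if ev.kind == "insertion" else -len(ev.sequence)
    return out


def _occurrences(seq: str, motif: str) -> list[int]:
    out = []
    start = 0
    while True:
        p = seq.find(motif, start)
        if p == -1:
            return out
        out.append(p)
        start = p + 1


def evolve(
    seq: str, config: SimConfig, rng: np.random.Generator, **overrides
) -> tuple[str, MutationLog]:
    """Evolve one branch: substitutions (CpG-context transitions at
    ``cpg_multiplier`` times the base rate), then slippage and tandem
    indels.  Keyword overrides replace config fields for this branch
    only (e.g. ``sub_rate=0``)."""
    if overrides:
        config = dataclasses.replace(config, **overrides)
    mutated, subs = _apply_substitutions(seq, config, rng)
    indels = _draw_indels(mutated, config, rng)
    log = MutationLog(subs, indels)
    derived = replay(seq, log)
    return derived, log


@dataclass
class PairTruth:
    pair_id: str
    ancestor: str
    ancestral_class: str
    log_human: MutationLog
    log_macaque: MutationLog
    human_class: PromoterClass
    macaque_class: PromoterClass
    expected_group: PairGroup
    refseq_offset: int


@dataclass
class Cohort:
    config: SimConfig
    pairs: list[tuple[PromoterWindow, PromoterWindow]]
    truths: list[PairTruth]

    def write(self, out_dir: str | Path) -> None:
        """Cohort FASTA plus a JSON truth bundle (generation parameters
        echoed for provenance)."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        records = []
        for h, m in self.pairs:
            records.append((h.header(), h.sequence))
            records.append((m.header(), m.sequence))
        write_fasta(records, out_dir / "cohort.fasta")
        bundle = {
            "config": dataclasses.asdict(self.config),
            "pairs": [
                {
                    "pair_id": t.pair_id,
                    "ancestor": t.ancestor,
                    "ancestral_class": t.ancestral_class,
                    "human_class": t.human_class.value,
                    "macaque_class": t.macaque_class.value,
                    "expected_group": t.expected_group.value,
                    "refseq_offset": t.refseq_offset,
                    "log_human": t.log_human.to_dict(),
                    "log_macaque": t.log_macaque.to_dict(),
                }
                for t in self.truths
            ],
        }
        with open(out_dir / "truth.json", "w") as fh:
            json.dump(bundle, fh, indent=1, sort_keys=True)
            fh.write("\n")


def _window(seq: str, center: int, pair_id: str, species: str) -> PromoterWindow:
    anchor = TSSRecord(chrom=pair_id, position=center, strand="+", gene=pair_id, clones=3)
    return PromoterWindow(seq, anchor, upstream=center,
                          downstream=len(seq) - center - 1, species=species)


def generate_cohort(
    config: SimConfig,
    branch_overrides: tuple[dict, dict] | None = None,
) -> Cohort:
    """Generate ``n_pairs`` orthologous pairs: one ancestor per pair,
    evolved independently on the human and macaque branches.

    ``branch_overrides`` optionally supplies per-branch config
    overrides (human, macaque), e.g. to plant indels on one branch
    only.  Deterministic for a fixed config seed.
    """
    rng = np.random.default_rng(config.seed)
    over_h, over_m = branch_overrides or ({}, {})
    n_island = round(config.n_pairs * config.island_fraction)
    center = (config.length - 1) // 2
    pairs = []
    truths = []
    for i in range(config.n_pairs):
        cls = "island" if i < n_island else "nonisland"
        pair_id = f"sim{i:04d}"
        ancestor = simulate_ancestor(cls, config, rng)
        derived_h, log_h = evolve(ancestor, config, rng, **over_h)
        derived_m, log_m = evolve(ancestor, config, rng, **over_m)
        win_h = _window(derived_h, map_to_derived(log_h, center), pair_id, "human")
        win_m = _window(derived_m, map_to_derived(log_m, center), pair_id, "macaque")
        class_h = classify(cpg_stats(derived_h))
        class_m = classify(cpg_stats(derived_m))
        # RefSeq-style 5' ends sit mostly upstream of the capped TSS
        if rng.random() < 0.92:
            offset = -int(rng.geometric(1.0 / 80.0))
        else:
            offset = int(rng.geometric(1.0 / 10.0)) - 1
        truths.append(
            PairTruth(
                pair_id=pair_id,
                ancestor=ancestor,
                ancestral_class=cls,
                log_human=log_h,
                log_macaque=log_m,
                human_class=class_h,
                macaque_class=class_m,
                expected_group=PairGroup.from_flags(
                    class_h.is_island, class_m.is_island
                ),
                refseq_offset=offset,
            )
        )
        pairs.append((win_h, win_m))
    return Cohort(config, pairs, truths)


def expected_indel_set(truth: PairTruth) -> list[tuple[str, int, str]]:
    """Planted indels as (carrier row, left-normalized position in the
    carrier's derived sequence, left-normalized sequence).

    An insertion on a branch is carried by that branch's row; a
    deletion is carried by the opposite row.  Positions for the
    opposite row are mapped through that branch's own log, which is
    exact as long as the other branch left the segment untouched (the
    recovery-test configuration guarantees this).
    """
    from .indels import left_normalize

    derived = {
        "A": replay(truth.ancestor, truth.log_human),
        "B": replay(truth.ancestor, truth.log_macaque),
    }
    logs = {"A": truth.log_human, "B": truth.log_macaque}
    out = []
    for row, other in (("A", "B"), ("B", "A")):
        for ev in logs[row].indels:
            if ev.kind == "insertion":
                carrier, pos = row, ev.derived_position
            else:
                carrier, pos = other, map_to_derived(logs[other], ev.position)
            npos, nseq = left_normalize(derived[carrier], pos, len(ev.sequence))
            out.append((carrier, npos, nseq))
    return sorted(out)
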