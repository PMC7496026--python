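"""End-to-end orchestration: from promoter pairs to report bundle.

Inputs are either a synthetic cohort (see :mod:`promdiv.simulate`) or
real data (genomes + TSS table + PSL hits).  Stages: pairwise global
alignment, CpG classification and quadrant transitions, score/YR
filtering, dinucleotide divergence spectra and CpG fates, indel
detection with flank filtering and repeat association, TATAAA
scanning, and RefSeq-vs-TSS offset histograms.  Eight TSV reports plus
one JSON summary are written; per-stage survivor counts are logged and
echoed into the summary so filter attrition is auditable.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .align import (
    AlignParams,
    PairwiseAlignment,
    alignment_score,
    anchor_and_extend,
    filter_pairs,
    global_align,
    select_candidate,
)
from .config import PipelineConfig
from .cpg import PairGroup, classify, count_type_changes, cpg_stats
from .dotplot import repeat_association
from .indels import detect_indels, flank_filter, indel_length_histogram, single_nt_bias
from .io import GenomeSource, PslHit, write_json
from .motifs import tataaa_scan
from .promoters import PromoterWindow, TSSRecord, WindowBoundsError, extract_window
from .simulate import Cohort
from .spectrum import (
    cpg_fate_spectrum,
    deamination_enrichment,
    dinuc_alteration_rates,
)

logger = logging.getLogger(__name__)

REPORT_FILES = (
    "classification.tsv",
    "type_transitions.tsv",
    "dinuc_rates.tsv",
    "cpg_fate.tsv",
    "indels.tsv",
    "single_nt_bias.tsv",
    "tata_histogram.tsv",
    "offset_histogram.tsv",
)


class ConfigurationError(ValueError):
    """A requested stage is missing its input."""


@dataclass
class ReportBundle:
    out_dir: Path
    classification: pd.DataFrame
    quadrant_transitions: pd.DataFrame
    island_transitions: pd.DataFrame
    dinuc_rates: pd.DataFrame
    cpg_fate: pd.DataFrame
    indels: pd.DataFrame
    single_nt: pd.DataFrame
    tata_histogram: pd.Series
    offset_histogram: pd.Series
    summary: dict = field(default_factory=dict)


def pairs_from_real_inputs(
    config: PipelineConfig,
    human_genome: GenomeSource,
    macaque_genome: GenomeSource,
    tss_records: Sequence[TSSRecord],
    psl_hits: Sequence[PslHit],
) -> tuple[list[tuple[PromoterWindow, PromoterWindow]], dict]:
    """Locate counterpart promoters from BLAT hits and build pairs."""
    half = config.window_half_width
    hits_by_query: dict[str, list[PslHit]] = {}
    for h in psl_hits:
        hits_by_query.setdefault(h.q_name, []).append(h)
    counts = Counter()
    pairs = []
    for tss in tss_records:
        if tss.clones < config.min_clone_support:
            counts["low_clone_support"] += 1
            continue
        try:
            win_h = extract_window(
                human_genome, tss, half, half, layer="unmasked", species="human"
            )
        except WindowBoundsError:
            counts["edge_window"] += 1
            continue
        hit = select_candidate(
            hits_by_query.get(tss.gene, []),
            min_identity=config.min_hit_identity,
            min_span=config.min_hit_span,
        )
        if hit is None:
            counts["no_hit"] += 1
            continue
        win_m, reason = anchor_and_extend(
            hit, macaque_genome, tss_offset_in_query=half, half_width=half
        )
        if win_m is None:
            counts[f"rejected_{reason}"] += 1
            continue
        pairs.append((win_h, win_m))
        counts["paired"] += 1
    return pairs, dict(counts)


def _align_pairs(
    pairs: Sequence[tuple[PromoterWindow, PromoterWindow]], params: AlignParams
) -> list[PairwiseAlignment]:
    alignments = []
    for win_h, win_m in pairs:
        aln = global_align(
            win_h.sequence, win_m.sequence, params, pair_id=win_h.anchor.gene
        )
        aln.a_tss = win_h.upstream
        aln.b_tss = win_m.upstream
        alignments.append(aln)
    return alignments


def _spectrum_groups(alignments, islands):
    """Fig-style grouping: source species x counterpart island flag."""
    groups = {
        "human_vs_mC": [], "human_vs_mN": [], "macaque_vs_hC": [], "macaque_vs_hN": [],
    }
    for aln in alignments:
        h_island, m_island = islands[aln.pair_id]
        groups["human_vs_mC" if m_island else "human_vs_mN"].append(aln)
        groups["macaque_vs_hC" if h_island else "macaque_vs_hN"].append(aln)
    return groups


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    cohort: Cohort | None = None,
    human_genome: GenomeSource | None = None,
    macaque_genome: GenomeSource | None = None,
    tss_records: Sequence[TSSRecord] | None = None,
    psl_hits: Sequence[PslHit] | None = None,
    refseq_offsets: dict[str, int] | None = None,
    axt_pairs: Sequence[tuple[str, str]] | None = None,
) -> ReportBundle:
    """Run every stage and write the report bundle to ``out_dir``."""
    if cohort is None:
        missing = [
            name
            for name, val in (
                ("human_genome", human_genome),
                ("macaque_genome", macaque_genome),
                ("tss_records", tss_records),
                ("psl_hits", psl_hits),
            )
            if val is None
        ]
        if missing:
            raise ConfigurationError(
                "need a synthetic cohort or real inputs; missing: " + ", ".join(missing)
            )

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stage_counts": {}}
    counts = summary["stage_counts"]

    if cohort is not None:
        pairs = cohort.pairs
        offsets = {t.pair_id: t.refseq_offset for t in cohort.truths}
    else:
        pairs, attrition = pairs_from_real_inputs(
            config, human_genome, macaque_genome, tss_records, psl_hits
        )
        counts["candidate_attrition"] = attrition
        offsets = refseq_offsets or {}
    counts["pairs_in"] = len(pairs)
    logger.info("pipeline: %d promoter pairs", len(pairs))

    # --- classification ------------------------------------------------
    rows = []
    islands: dict[str, tuple[bool, bool]] = {}
    quad_pairs = []
    for win_h, win_m in pairs:
        st_h, st_m = cpg_stats(win_h.sequence), cpg_stats(win_m.sequence)
        cls_h = classify(st_h, config.gc_threshold, config.cpg_score_threshold)
        cls_m = classify(st_m, config.gc_threshold, config.cpg_score_threshold)
        group = PairGroup.from_flags(cls_h.is_island, cls_m.is_island)
        pid = win_h.anchor.gene
        islands[pid] = (cls_h.is_island, cls_m.is_island)
        quad_pairs.append((cls_h, cls_m))
        for species, st, cls in (("human", st_h, cls_h), ("macaque", st_m, cls_m)):
            rows.append(
                {
                    "pair_id": pid,
                    "species": species,
                    "gc": round(st.gc, 6),
                    "cpg_score": round(st.score, 6),
                    "quadrant": cls.value,
                    "island": cls.is_island,
                    "pair_group": group.value,
                }
            )
    classification = pd.DataFrame(
        rows,
        columns=["pair_id", "species", "gc", "cpg_score", "quadrant", "island", "pair_group"],
    )
    quad_mat, island_mat = count_type_changes(quad_pairs)

    # --- alignment and filtering ---------------------------------------
    params = AlignParams(min_score=config.min_alignment_score)
    alignments = _align_pairs(pairs, params)
    counts["aligned"] = len(alignments)
    refined = filter_pairs(
        alignments, min_score=config.min_alignment_score, require_yr_match=True
    )
    counts["passed_score_and_yr"] = len(refined)

    # --- divergence spectra --------------------------------------------
    groups = _spectrum_groups(refined, islands)
    rate_cols, fate_cols = {}, {}
    for name, alns in groups.items():
        source = "A" if name.startswith("human") else "B"
        rate_cols[name] = dinuc_alteration_rates(alns, source).to_frame()["rate"]
        fate = cpg_fate_spectrum(alns, source)
        fate_cols[name] = pd.Series(fate.fractions)
    if axt_pairs:
        bg = [PairwiseAlignment(a, b) for a, b in axt_pairs]
        rate_cols["background_AB"] = dinuc_alteration_rates(bg, "A").to_frame()["rate"]
        fate_cols["background_AB"] = pd.Series(cpg_fate_spectrum(bg, "A").fractions)
    dinuc_rates = pd.DataFrame(rate_cols)
    cpg_fate = pd.DataFrame(fate_cols)

    # deamination enrichment: type-change pairs vs conserved islands
    enrichment = {}
    for direction, source in (("human", "A"), ("macaque", "B")):
        changed = [
            a for a in refined
            if islands[a.pair_id] in ((True, False), (False, True))
        ]
        conserved = [a for a in refined if islands[a.pair_id] == (True, True)]
        try:
            ratio = deamination_enrichment(changed, conserved, source)
            enrichment[direction] = ratio if math.isfinite(ratio) else "inf"
        except ValueError:
            enrichment[direction] = None
    summary["deamination_enrichment"] = enrichment

    # --- indels ---------------------------------------------------------
    indel_stage = filter_pairs(
        alignments, min_score=config.indel_min_alignment_score, require_yr_match=True
    )
    counts["indel_stage_pairs"] = len(indel_stage)
    indel_rows = []
    kept_sites = []
    kept_groups = []
    for aln in indel_stage:
        group = PairGroup.from_flags(*islands[aln.pair_id])
        for site in detect_indels(aln, flank_width=config.flank_width):
            keep = flank_filter(site, min_match=config.min_flank_matches)
            tandem = inverted = None
            if keep and site.length >= config.dotplot_window:
                assoc = repeat_association(
                    site, aln, window=config.dotplot_window
                )
                tandem, inverted = assoc["tandem"], assoc["inverted"]
            indel_rows.append(
                {
                    "pair_id": aln.pair_id,
                    "carrier": site.carrier,
                    "start_col": site.start_col,
                    "end_col": site.end_col,
                    "length": site.length,
                    "sequence": site.sequence,
                    "left_matches": site.left_matches,
                    "right_matches": site.right_matches,
                    "edge_truncated": site.edge_truncated,
                    "cpg_delta": site.cpg_delta,
                    "kept": keep,
                    "pair_group": group.value,
                    "tandem": tandem,
                    "inverted": inverted,
                }
            )
            if keep:
                kept_sites.append(site)
                kept_groups.append(group)
    indel_table = pd.DataFrame(
        indel_rows,
        columns=[
            "pair_id", "carrier", "start_col", "end_col", "length", "sequence",
            "left_matches", "right_matches", "edge_truncated", "cpg_delta",
            "kept", "pair_group", "tandem", "inverted",
        ],
    )
    counts["indel_sites_detected"] = len(indel_rows)
    counts["indel_sites_kept"] = len(kept_sites)
    summary["indel_length_histogram"] = indel_length_histogram(kept_sites)
    single_nt = single_nt_bias(kept_sites, kept_groups)

    # --- motifs and offsets ---------------------------------------------
    tata = tataaa_scan(
        [h for h, _ in pairs], scan_width=config.tata_scan_width
    ) if pairs else Counter()
    tata_series = pd.Series(dict(sorted(tata.items())), dtype=int, name="count")
    tata_series.index.name = "position"
    offset_counter = Counter(offsets.values())
    offset_series = pd.Series(dict(sorted(offset_counter.items())), dtype=int, name="count")
    offset_series.index.name = "offset"

    # --- write reports ---------------------------------------------------
    classification.to_csv(out_dir / "classification.tsv", sep="\t", index=False)
    with open(out_dir / "type_transitions.tsv", "w") as fh:
        fh.write("# quadrant transitions (rows: human, columns: macaque)\n")
        quad_mat.to_csv(fh, sep="\t")
        fh.write("# island transitions\n")
        island_mat.to_csv(fh, sep="\t")
    dinuc_rates.to_csv(out_dir / "dinuc_rates.tsv", sep="\t", float_format="%.6f")
    cpg_fate.to_csv(out_dir / "cpg_fate.tsv", sep="\t", float_format="%.6f")
    indel_table.to_csv(out_dir / "indels.tsv", sep="\t", index=False)
    single_nt.to_csv(out_dir / "single_nt_bias.tsv", sep="\t", float_format="%.6f")
    tata_series.to_csv(out_dir / "tata_histogram.tsv", sep="\t")
    offset_series.to_csv(out_dir / "offset_histogram.tsv", sep="\t")

    summary["config"] = dataclasses.asdict(config)
    summary["mean_alignment_score"] = (
        round(sum(alignment_score(a) for a in alignments) / len(alignments), 4)
        if alignments else None
    )
    write_json(summary, out_dir / "summary.json")
    logger.info("pipeline: wrote %d reports to %s", len(REPORT_FILES) + 1, out_dir)

    return ReportBundle(
        out_dir=out_dir,
        classification=classification,
        quadrant_transitions=quad_mat,
        island_transitions=island_mat,
        dinuc_rates=dinuc_rates,
        cpg_fate=cpg_fate,
        indels=indel_table,
        single_nt=single_nt,
        tata_histogram=tata_series,
        offset_histogram=offset_series,
        summary=summary,
    )
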