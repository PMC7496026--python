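"""Pipeline configuration: every fixed analysis parameter in one place.

The defaults are the parameters of the comparative promoter analysis
this package implements: 601-nt TSS-centred windows, 0.5/0.6 island
thresholds, 90%/200-bp BLAT-hit filters, 90 (80 for the indel stage)
alignment-score cutoffs, 10-bp flanks with >=8 matches, a 5-bp dot-plot
window, and a minimum of 3 supporting clones per TSS.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path


@dataclass
class PipelineConfig:
    window_half_width: int = 300          # upstream = downstream = 300 -> 601 nt
    logo_upstream: int = 34               # 40-nt logo window: -34 .. +5
    logo_downstream: int = 5
    tata_scan_width: int = 40             # TATAAA searched within 40 bp upstream
    gc_threshold: float = 0.5             # island iff gc >= 0.5 and score >= 0.6
    cpg_score_threshold: float = 0.6
    min_hit_identity: float = 0.90
    min_hit_span: int = 200
    min_alignment_score: float = 90.0
    indel_min_alignment_score: float = 80.0
    flank_width: int = 10
    min_flank_matches: int = 8
    dotplot_window: int = 5
    dotplot_stride: int = 1
    min_clone_support: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "window_half_width", "logo_upstream", "logo_downstream",
            "tata_scan_width", "min_hit_span", "flank_width",
            "dotplot_window", "dotplot_stride",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("gc_threshold", "cpg_score_threshold", "min_hit_identity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.min_flank_matches < 0 or self.min_flank_matches > self.flank_width:
            raise ValueError("min_flank_matches must be in [0, flank_width]")

    def to_file(self, path: str | Path) -> None:
        """Write as flat ``key = value`` text."""
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        kwargs = {}
        casts = {f.name: (float if "float" in str(f.type) else int)
                 for f in dataclasses.fields(cls)}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}: expected 'key = value' at line {lineno}")
                key, _, value = line.partition("=")
                key = key.strip()
                if key not in casts:
                    raise ValueError(f"{path}: unknown parameter {key!r} at line {lineno}")
                kwargs[key] = casts[key](value.strip())
        return cls(**kwargs)
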