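"""Pipeline configuration.

Every numeric threshold used anywhere in the pipeline lives in
:class:`PipelineConfig` so that a run is fully described by one object.
Defaults follow the conventional plant miRNA annotation rules: a mature
miRNA is 20-24 nt, sits in a hairpin whose miRNA/miRNA* duplex has 2-nt
3' overhangs, at most four mismatched miRNA bases and at most one small
(<=2 nt) asymmetric bulge, and the mature tag must dominate (>=70% of)
the reads within +-20 nt of its 5' end.  High-copy tags (more than 500
perfect genomic hits) and tags matching annotated non-miRNA ncRNA/repeat
decoys are excluded before folding.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
import yaml


@dataclass
class PipelineConfig:
    """Thresholds and knobs for the whole discovery/annotation pipeline."""

    # genomic mapping / repeat filtering
    max_genome_hits: int = 500          # drop tags with strictly more hits
    map_len: tuple[int, int] = (18, 26)  # tag lengths mapped to the genome
    # mature miRNA candidate gates
    mature_len: tuple[int, int] = (20, 24)
    min_reads_one_lib: int = 20          # strict >, in at least one library
    min_reads_either: int = 5            # strict >, in at least one library
    # hairpin duplex criteria
    max_duplex_mismatch: int = 4
    overhang: int = 2                    # required 3' overhang, both strands
    max_bulge_len: int = 2
    max_bulge_events: int = 1
    # read-stack dominance
    dominance_min: float = 0.70
    dominance_window: int = 20           # +- nt around the mature 5' end
    # candidate window extraction
    flank_lengths: tuple[int, ...] = (50, 100, 150, 200)
    # degradome target calling
    target_score_max: float = 4.5
    min_degradome_reads: int = 5
    orf_min_aa: int = 70
    max_target_gaps: int = 1
    # catalog / conservation
    variant_max_mismatch: int = 2
    conservation_flank: int = 200
    cross_species_mismatch: int = 0
    # preprocessing
    summary_len: tuple[int, int] = (18, 30)  # as-sequenced length range
    adapter_min_overlap: int = 8
    # folding engine: "vienna", "nussinov" or "auto" (vienna if importable)
    fold_engine: str = "auto"
    max_fold_len: int = 1000
    # expression thresholds (tissue-preferential calls)
    expr_on_threshold: float = 10.0      # RP10M
    expr_off_threshold: float = 1.0      # RP10M
    expr_fold: float = 10.0

    def __post_init__(self) -> None:
        for name in ("max_genome_hits", "min_reads_one_lib", "min_reads_either",
                     "overhang", "max_bulge_len", "dominance_window",
                     "min_degradome_reads", "orf_min_aa"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.dominance_min <= 1.0:
            raise ValueError("dominance_min must be in [0, 1]")
        lo, hi = self.mature_len
        if not (0 < lo <= hi):
            raise ValueError("mature_len bounds must satisfy 0 < lo <= hi")

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in d:
                continue
            val = d[f.name]
            if isinstance(val, list):
                val = tuple(val)
            kwargs[f.name] = val
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
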