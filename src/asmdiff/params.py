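"""Stage parameter sets.

Defaults are the thresholds the pipeline was designed around: alignment
filtering at 98% identity / 1 kb, the 100 kb / 300 kb / 700 kb / 1 Mb
inversion merge-filter ladder, 80% / 95% / 50% correspondence cutoffs,
the 3 kb read-intron guard, the >50% / >=4-read methylation call, the
4,000-score / 1 kb / 100 kb gap-placement criteria, and 100-kb windows.

Parameters load from a flat YAML mapping; unknown keys are rejected so
a typo in a config file cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .core import ParameterError

__all__ = [
    "LmiParams",
    "CorrespondenceParams",
    "SplicingParams",
    "GapPlacementParams",
    "MethylationParams",
    "ParamSet",
]


def _check_nonneg(obj, names):
    for n in names:
        if getattr(obj, n) < 0:
            raise ParameterError(f"{n} must be >= 0, got {getattr(obj, n)}")


def _check_pct(obj, names):
    for n in names:
        v = getattr(obj, n)
        if not 0 <= v <= 100:
            raise ParameterError(f"{n} must be in [0, 100], got {v}")


@dataclass
class LmiParams:
    """Thresholds for large misassembled-inversion detection."""

    min_identity: float = 98.0
    min_block_length: int = 1_000
    gap1: int = 100_000
    min_size1: int = 100_000
    gap2: int = 300_000
    min_size2: int = 700_000
    gap3: int = 1_000_000

    def __post_init__(self):
        _check_pct(self, ["min_identity"])
        _check_nonneg(self, ["min_block_length", "gap1", "min_size1", "gap2", "min_size2", "gap3"])


@dataclass
class CorrespondenceParams:
    """Thresholds for the two gene-correspondence methods.

    M1 enriches reciprocal-best anchors with hits above 80% identity and
    80% coverage of either the query or the target, placed by synteny.
    M2 keeps reciprocal hits at >=95% identity with an alignment length
    of at least half the query protein.
    """

    m1_min_identity: float = 80.0      # strict >
    m1_min_coverage: float = 0.80      # strict >, of query OR target
    m2_min_identity: float = 95.0      # inclusive >=
    m2_min_coverage: float = 0.50      # inclusive >=, of query length
    m2_accept_unplaced: bool = True
    min_anchors_per_chrom: int = 2
    end_anchor_max_distance: int = 5_000_000

    def __post_init__(self):
        _check_pct(self, ["m1_min_identity", "m2_min_identity"])
        for n in ("m1_min_coverage", "m2_min_coverage"):
            if not 0 <= getattr(self, n) <= 1:
                raise ParameterError(f"{n} must be in [0, 1]")
        _check_nonneg(self, ["min_anchors_per_chrom", "end_anchor_max_distance"])


@dataclass
class SplicingParams:
    """Long-read alignment retention and event-calling thresholds."""

    min_read_coverage: float = 0.80
    min_identity: float = 95.0
    event_min_identity: float = 90.0   # relaxed preset for event calling
    max_read_intron: int = 3_000       # exon-skipping guard, strict <
    es_guard_on: str = "read_intron"   # or "exon"
    shortread_depths: tuple[int, ...] = (10, 8, 5)

    def __post_init__(self):
        _check_pct(self, ["min_identity", "event_min_identity"])
        if not 0 <= self.min_read_coverage <= 1:
            raise ParameterError("min_read_coverage must be in [0, 1]")
        _check_nonneg(self, ["max_read_intron"])
        if self.es_guard_on not in ("read_intron", "exon"):
            raise ParameterError("es_guard_on must be 'read_intron' or 'exon'")


@dataclass
class GapPlacementParams:
    """Criteria for placing another assembly's gap flanks on a reference."""

    min_score: float = 4_000.0         # strict >
    min_aligned_length: int = 1_000    # inclusive >=
    max_span: int = 100_000            # strict <

    def __post_init__(self):
        _check_nonneg(self, ["min_aligned_length", "max_span"])
        if self.min_score < 0:
            raise ParameterError("min_score must be >= 0")


@dataclass
class MethylationParams:
    """CpG methylation call thresholds: frequency strictly above 50%
    and at least 4 supporting reads."""

    min_frequency: float = 0.50        # strict >
    min_depth: int = 4                 # inclusive >=
    window_width: int = 100_000

    def __post_init__(self):
        if not 0 <= self.min_frequency <= 1:
            raise ParameterError("min_frequency must be in [0, 1]")
        _check_nonneg(self, ["min_depth"])
        if self.window_width <= 0:
            raise ParameterError("window_width must be > 0")


@dataclass
class ParamSet:
    """All stage parameters plus the global window width and seed."""

    lmi: LmiParams = field(default_factory=LmiParams)
    correspondence: CorrespondenceParams = field(default_factory=CorrespondenceParams)
    splicing: SplicingParams = field(default_factory=SplicingParams)
    gaps: GapPlacementParams = field(default_factory=GapPlacementParams)
    methylation: MethylationParams = field(default_factory=MethylationParams)
    window_width: int = 100_000
    min_gap_run: int = 1
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ParamSet":
        """Load overrides from a flat ``stage.key: value`` YAML mapping."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ParameterError(f"parameter file must be a mapping: {path}")
        ps = cls()
        stage_fields = {f.name: f for f in dataclasses.fields(cls)}
        for key, value in raw.items():
            if "." in key:
                stage, sub = key.split(".", 1)
                if stage not in stage_fields or not dataclasses.is_dataclass(getattr(ps, stage)):
                    raise ParameterError(f"unknown parameter group {stage!r} in {key!r}")
                group = getattr(ps, stage)
                if sub not in {f.name for f in dataclasses.fields(group)}:
                    raise ParameterError(f"unknown parameter {key!r}")
                setattr(group, sub, value)
                group.__post_init__()
            else:
                if key not in stage_fields or dataclasses.is_dataclass(getattr(ps, key)):
                    raise ParameterError(f"unknown parameter {key!r}")
                setattr(ps, key, value)
        return ps

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
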