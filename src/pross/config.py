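"""Tunable thresholds of the segment-calling procedure.

All numeric rules of the method live here so a run is fully described by one
object: the length cut below which an annotation can qualify, the number of
predictor votes a residue needs to be consensus-disordered, the fraction of
an annotation's residues that must fall inside consensus disorder, and the
keyword/negation vocabulary used to pick binding-associated descriptions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping


@dataclass(frozen=True)
class ThresholdConfig:
    """Parameters of one analysis run.

    max_feature_length
        Largest qualifying annotation, in residues.  The default 29 encodes
        "shorter than 30 residues".
    min_predictor_votes
        Predictors that must call a residue disordered for it to enter the
        consensus (default 2 of the 3 tracks).
    idr_coverage_threshold
        Fraction of an annotation's residues that must lie inside consensus
        disorder for the annotation to be called (default 1.0 = full
        containment).
    positive_keywords_region / positive_keywords_mutagenesis
        Description keywords (matched case-insensitively at word starts)
        that mark a "region of interest" / "mutagenesis site" annotation as
        binding-associated.
    negation_tokens
        Whole words whose presence discards a mutagenesis-site description
        ("no", "not"); "Loss of interaction ..." is deliberately kept.
    enrichment_log_base
        Base of the localization log ratio-of-ratios (default 2).
    """

    max_feature_length: int = 29
    min_predictor_votes: int = 2
    idr_coverage_threshold: float = 1.0
    positive_keywords_region: frozenset[str] = field(
        default_factory=lambda: frozenset({"interact", "bind", "motif"})
    )
    positive_keywords_mutagenesis: frozenset[str] = field(
        default_factory=lambda: frozenset({"interact", "bind"})
    )
    negation_tokens: frozenset[str] = field(
        default_factory=lambda: frozenset({"no", "not"})
    )
    enrichment_log_base: float = 2.0
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.max_feature_length < 1:
            raise ValueError("max_feature_length must be >= 1")
        if not (1 <= self.min_predictor_votes <= 3):
            raise ValueError("min_predictor_votes must be in 1..3")
        if not (0 < self.idr_coverage_threshold <= 1):
            raise ValueError("idr_coverage_threshold must be in (0, 1]")
        if self.enrichment_log_base <= 0 or self.enrichment_log_base == 1:
            raise ValueError("enrichment_log_base must be positive and != 1")
        # keyword sets may legitimately be empty only for the negation list
        if not self.positive_keywords_region or not self.positive_keywords_mutagenesis:
            raise ValueError("positive keyword sets must be non-empty")
        object.__setattr__(
            self, "positive_keywords_region", frozenset(k.lower() for k in self.positive_keywords_region)
        )
        object.__setattr__(
            self,
            "positive_keywords_mutagenesis",
            frozenset(k.lower() for k in self.positive_keywords_mutagenesis),
        )
        object.__setattr__(
            self, "negation_tokens", frozenset(t.lower() for t in self.negation_tokens)
        )

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {}
        for f in fields(self):
            value = getattr(self, f.name)
            out[f.name] = sorted(value) if isinstance(value, frozenset) else value
        return out

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ThresholdConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        for key in ("positive_keywords_region", "positive_keywords_mutagenesis", "negation_tokens"):
            if key in kwargs:
                kwargs[key] = frozenset(kwargs[key])
        return cls(**kwargs)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ThresholdConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
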