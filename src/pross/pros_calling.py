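"""Calling possible protean segments (pProSs).

A selected binding-associated annotation becomes a pProS when the fraction
of its residues lying inside consensus disorder reaches
``idr_coverage_threshold`` (default 1.0: full containment).  Each qualifying
annotation yields exactly one call; overlapping annotations remain separate
calls because they can describe distinct binding events, while residue
accounting (`union_residue_count`, `pros_residues_per_protein`) is always
non-redundant — annotations at 360-365 and 360-362 together cover six
residues, not nine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .config import ThresholdConfig
from .feature_selection import SelectedFeature, SelectionReason
from .idr_consensus import ConsensusIDR
from .intervals import IntervalSet
from .records_io import FeatureAnnotation, FeatureType


@dataclass(frozen=True)
class PProS:
    """One called segment, with provenance back to its annotation."""

    accession: str
    feature_id: str
    feature_type: FeatureType
    intervals: IntervalSet
    idr_coverage: float
    reason: SelectionReason


def feature_idr_coverage(feature: FeatureAnnotation, consensus: ConsensusIDR) -> float:
    """Fraction of the feature's residues inside consensus disorder."""
    inside = feature.location.intersection(consensus.intervals).total_length
    return inside / feature.length


def call_pros(
    accession: str,
    selected: Sequence[SelectedFeature],
    consensus: ConsensusIDR,
    config: ThresholdConfig,
) -> list[PProS]:
    """Intersect selected features with consensus disorder.

    The call's intervals are the feature's own intervals — a call never
    extends or trims the annotation it came from.
    """
    calls: list[PProS] = []
    for sel in selected:
        coverage = feature_idr_coverage(sel.feature, consensus)
        if coverage >= config.idr_coverage_threshold:
            calls.append(
                PProS(
                    accession=accession,
                    feature_id=sel.feature.feature_id,
                    feature_type=sel.feature.feature_type,
                    intervals=sel.feature.location,
                    idr_coverage=coverage,
                    reason=sel.reason,
                )
            )
    return calls


def intersect_features_with_idrs(
    features: Iterable[FeatureAnnotation], consensus: ConsensusIDR
) -> list[tuple[FeatureAnnotation, float]]:
    """Generic feature-vs-disorder coverage report, no keyword filtering.

    Used for surveys over other annotation classes — disease variants,
    phosphorylation sites — where the question is simply how often the
    class falls inside consensus disorder.
    """
    return [(feat, feature_idr_coverage(feat, consensus)) for feat in features]


def union_residue_count(interval_sets: Iterable[IntervalSet]) -> int:
    """Non-redundant residue count of a union of spans on one protein."""
    return IntervalSet.union(interval_sets).total_length


def pros_residues_per_protein(pros_list: Sequence[PProS]) -> int:
    """Non-redundant residues covered by a protein's pProS calls."""
    return union_residue_count(p.intervals for p in pros_list)
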