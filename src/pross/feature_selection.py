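"""Selection of candidate binding-associated feature annotations.

Two filters run in sequence.  First the length rule: an annotation
qualifies only if its non-redundant residue count is at most
``max_feature_length`` (default 29, i.e. shorter than 30 residues, the size
range that holds >80% of experimentally verified protean segments).  Then a
per-class keyword rule picks binding-associated descriptions:

* ``short_sequence_motif`` — always selected (the class is functional by
  construction);
* ``region_of_interest`` — selected if the description contains any of
  {interact, bind, motif};
* ``mutagenesis_site`` — selected if the description contains any of
  {interact, bind} and none of the negation words {no, not}.

Keywords match case-insensitively at word starts, so "interact" hits
"Interaction with USP7" and "bind" hits "binding".  Negation words match as
whole words only: "Loss of interaction with MDM2" is kept ("loss" is not a
negation), while "Does not abolish binding to X" is discarded.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from typing import Iterable, Sequence

from .config import ThresholdConfig
from .records_io import FeatureAnnotation, FeatureType


class SelectionReason(str, Enum):
    motif_class = "motif_class"
    keyword_region = "keyword_region"
    keyword_mutagenesis = "keyword_mutagenesis"


@dataclass(frozen=True)
class SelectedFeature:
    feature: FeatureAnnotation
    reason: SelectionReason


@lru_cache(maxsize=64)
def _word_start_pattern(keywords: frozenset[str]) -> re.Pattern[str]:
    alts = "|".join(re.escape(k) for k in sorted(keywords))
    return re.compile(rf"\b(?:{alts})", re.IGNORECASE)


@lru_cache(maxsize=64)
def _whole_word_pattern(tokens: frozenset[str]) -> re.Pattern[str]:
    alts = "|".join(re.escape(t) for t in sorted(tokens))
    return re.compile(rf"\b(?:{alts})\b", re.IGNORECASE)


def contains_keyword(description: str, keywords: frozenset[str]) -> bool:
    """True if any keyword occurs at a word start (case-insensitive)."""
    return bool(_word_start_pattern(keywords).search(description))


def contains_negation(description: str, tokens: frozenset[str]) -> bool:
    """True if any negation token occurs as a whole word."""
    if not tokens:
        return False
    return bool(_whole_word_pattern(tokens).search(description))


def is_short(feature: FeatureAnnotation, config: ThresholdConfig) -> bool:
    """Length rule: non-redundant residue count <= max_feature_length."""
    return feature.length <= config.max_feature_length


def selection_reason(
    feature: FeatureAnnotation, config: ThresholdConfig
) -> SelectionReason | None:
    """Keyword rule for one feature; None when the feature is not binding-associated."""
    if feature.feature_type is FeatureType.short_sequence_motif:
        return SelectionReason.motif_class
    if feature.feature_type is FeatureType.region_of_interest:
        if contains_keyword(feature.description, config.positive_keywords_region):
            return SelectionReason.keyword_region
        return None
    if feature.feature_type is FeatureType.mutagenesis_site:
        if contains_keyword(
            feature.description, config.positive_keywords_mutagenesis
        ) and not contains_negation(feature.description, config.negation_tokens):
            return SelectionReason.keyword_mutagenesis
        return None
    return None


def select_binding_features(
    features: Iterable[FeatureAnnotation], config: ThresholdConfig
) -> list[SelectedFeature]:
    """Apply the length rule then the keyword rule; pure in its inputs.

    Overlapping annotations stay separate selected features — they may
    describe different binding events on the same residues.
    """
    out: list[SelectedFeature] = []
    for feature in features:
        if not is_short(feature, config):
            continue
        reason = selection_reason(feature, config)
        if reason is not None:
            out.append(SelectedFeature(feature, reason))
    return out
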