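"""Subcellular-location classes and log ratio-of-ratios enrichment.

Proteins are sorted into four location classes from their plain-text
location terms: N (nucleus only), C (cytoplasm only), M (membrane only),
and CN (both cytoplasm and nucleus — the shuttling class); anything else is
`other`.  Over-representation of a protein group (e.g. the pProS-containing
disease proteins) against a background (e.g. all proteins) is the log of
the ratio of the two class fractions; a zero fraction on either side is
flagged rather than reported as a number.
"""

from __future__ import annotations

import math
from collections import Counter
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .config import ThresholdConfig
from .records_io import ProteinRecord


class LocationClass(str, Enum):
    N = "N"
    C = "C"
    M = "M"
    CN = "CN"
    other = "other"


LOCATION_CLASSES = tuple(LocationClass)

_NUCLEUS = "nucleus"
_CYTOPLASM = "cytoplasm"
_MEMBRANE = "membrane"


def normalize_term(term: str) -> str:
    return term.strip().lower()


def classify_location(terms: Iterable[str]) -> LocationClass:
    """Deterministic class from a protein's location terms.

    A protein with both cytoplasm and nucleus terms is CN regardless of
    additional terms; N/C/M require that single recognized term and no
    other recognized one.
    """
    normalized = {normalize_term(t) for t in terms}
    recognized = normalized & {_NUCLEUS, _CYTOPLASM, _MEMBRANE}
    if {_CYTOPLASM, _NUCLEUS} <= recognized:
        return LocationClass.CN
    if recognized == {_NUCLEUS}:
        return LocationClass.N
    if recognized == {_CYTOPLASM}:
        return LocationClass.C
    if recognized == {_MEMBRANE}:
        return LocationClass.M
    return LocationClass.other


def class_fractions(records: Sequence[ProteinRecord]) -> dict[LocationClass, float]:
    """Fraction of the records in each location class (sums to 1)."""
    if not records:
        raise ValueError("class_fractions requires a non-empty record set")
    counts = Counter(classify_location(r.location_terms) for r in records)
    n = len(records)
    return {cls: counts.get(cls, 0) / n for cls in LOCATION_CLASSES}


def enrichment(
    group_records: Sequence[ProteinRecord],
    background_records: Sequence[ProteinRecord],
    config: ThresholdConfig,
    group: str = "group",
    category: str = "all",
) -> pd.DataFrame:
    """Log ratio-of-ratios of the group's class fractions over the background's.

    One row per location class with both fractions, the log ratio (base
    ``config.enrichment_log_base``), and a flag column: empty when the value
    is defined, otherwise the reason no number is emitted.
    """
    gf = class_fractions(group_records)
    bf = class_fractions(background_records)
    rows = []
    for cls in LOCATION_CLASSES:
        g, b = gf[cls], bf[cls]
        if g > 0 and b > 0:
            value = math.log(g / b, config.enrichment_log_base)
            flag = ""
        else:
            value = float("nan")
            flag = "zero_group_fraction" if g == 0 else "zero_background_fraction"
            if g == 0 and b == 0:
                flag = "zero_both_fractions"
        rows.append(
            {
                "category": category,
                "group": group,
                "location_class": cls.value,
                "group_fraction": g,
                "background_fraction": b,
                "log_ratio": value,
                "flag": flag,
            }
        )
    return pd.DataFrame(rows)


def term_tally(records: Sequence[ProteinRecord]) -> pd.DataFrame:
    """Counts of every normalized location term (covers the long tail of
    terms outside the four classes, e.g. non-membrane organelles)."""
    counts = Counter(
        normalize_term(t) for r in records for t in r.location_terms
    )
    rows = [
        {"term": term, "n_proteins_terms": n}
        for term, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["term", "n_proteins_terms"])
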