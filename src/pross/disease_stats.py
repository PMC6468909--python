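"""Per-disease-category statistics over pProS calls.

Three report tables:

* the cohort summary (protein counts, short-annotation counts per candidate
  feature class, and the fraction of each that qualified as pProS);
* the per-category table — a protein assigned to diseases in k categories
  contributes to each of the k rows, once per category no matter how many
  of that category's diseases it has, while the redundant pProS count
  multiplies a protein's calls by its number of disease assignments in the
  category (the ratio unique/redundant is the category's pProS redundancy);
* the residue ranking — proteins ordered by their non-redundant pProS
  residue count.

Printed-style percentages and ratios are rounded half-up to one decimal;
the integer columns they derive from are always emitted alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from .config import ThresholdConfig
from .feature_selection import is_short
from .pros_calling import PProS, pros_residues_per_protein
from .records_io import (
    CANDIDATE_FEATURE_TYPES,
    CATEGORY_CODES,
    FeatureType,
    ProteinRecord,
)

ProsByAccession = Mapping[str, Sequence[PProS]]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (2.55 -> 2.6), as printed tables use."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def coverage_pct(n_with: int, n_total: int) -> float:
    """Percentage n_with/n_total, half-up to one decimal; 0.0 when empty."""
    if n_total == 0:
        return 0.0
    return round_half_up(100.0 * n_with / n_total)


def average_annotations(n_unique: int, n_with: int) -> float:
    """Unique pProS per pProS-containing protein, half-up to one decimal.

    Reported as 0.0 when the category has no pProS-containing protein.
    """
    if n_with == 0:
        return 0.0
    return round_half_up(n_unique / n_with)


def _n_pros(pros_by_acc: ProsByAccession, acc: str) -> int:
    return len(pros_by_acc.get(acc, ()))


def table1_stats(
    records: Sequence[ProteinRecord],
    pros_by_acc: ProsByAccession,
    config: ThresholdConfig,
) -> pd.DataFrame:
    """Cohort annotation summary.

    Rows: proteins; short annotations pooled over the three candidate
    classes; then each class.  Columns: all-protein count, disease-related
    count, pProS count (within disease-related proteins), and the pProS
    percentage of the disease-related count.
    """
    disease = [r for r in records if r.is_disease_related]

    def short_count(recs: Sequence[ProteinRecord], ftype: FeatureType | None) -> int:
        total = 0
        for r in recs:
            for f in r.features:
                if f.feature_type in CANDIDATE_FEATURE_TYPES and is_short(f, config):
                    if ftype is None or f.feature_type is ftype:
                        total += 1
        return total

    def pros_count(ftype: FeatureType | None) -> int:
        total = 0
        for r in disease:
            for p in pros_by_acc.get(r.accession, ()):
                if ftype is None or p.feature_type is ftype:
                    total += 1
        return total

    n_pros_proteins = sum(1 for r in disease if _n_pros(pros_by_acc, r.accession) > 0)
    rows = [
        {
            "row": "proteins",
            "all_proteins": len(records),
            "disease_related": len(disease),
            "pros": n_pros_proteins,
            "pros_pct": coverage_pct(n_pros_proteins, len(disease)),
        }
    ]
    for label, ftype in [
        ("short_annotations", None),
        ("region_of_interest", FeatureType.region_of_interest),
        ("mutagenesis_site", FeatureType.mutagenesis_site),
        ("short_sequence_motif", FeatureType.short_sequence_motif),
    ]:
        n_all = short_count(records, ftype)
        n_dis = short_count(disease, ftype)
        n_pros = pros_count(ftype)
        rows.append(
            {
                "row": label,
                "all_proteins": n_all,
                "disease_related": n_dis,
                "pros": n_pros,
                "pros_pct": coverage_pct(n_pros, n_dis),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CategoryStats:
    category: str
    n_unique_pros: int
    n_proteins_with_pros: int
    n_proteins: int
    coverage_pct: float
    avg_annotations: float
    pros_counts_redundant: int
    pros_redundancy: float
    empty_category: bool


def category_stats(
    records: Sequence[ProteinRecord], pros_by_acc: ProsByAccession
) -> list[CategoryStats]:
    """Per-category counts and derived ratios, in canonical category order."""
    out: list[CategoryStats] = []
    for cat in CATEGORY_CODES:
        members = [r for r in records if cat in r.categories]
        if not members:
            continue
        with_pros = [r for r in members if _n_pros(pros_by_acc, r.accession) > 0]
        n_unique = sum(_n_pros(pros_by_acc, r.accession) for r in with_pros)
        # redundant count: each pProS once per disease assignment in this category
        n_redundant = sum(
            _n_pros(pros_by_acc, r.accession)
            * sum(1 for d in r.diseases if d.category == cat)
            for r in with_pros
        )
        out.append(
            CategoryStats(
                category=cat,
                n_unique_pros=n_unique,
                n_proteins_with_pros=len(with_pros),
                n_proteins=len(members),
                coverage_pct=coverage_pct(len(with_pros), len(members)),
                avg_annotations=average_annotations(n_unique, len(with_pros)),
                pros_counts_redundant=n_redundant,
                pros_redundancy=(n_unique / n_redundant) if n_redundant else 0.0,
                empty_category=len(with_pros) == 0,
            )
        )
    return out


def category_table(
    records: Sequence[ProteinRecord], pros_by_acc: ProsByAccession
) -> pd.DataFrame:
    rows = [
        {
            "category": s.category,
            "n_unique_pros": s.n_unique_pros,
            "n_proteins_with_pros": s.n_proteins_with_pros,
            "n_proteins": s.n_proteins,
            "coverage_pct": s.coverage_pct,
            "avg_annotations": s.avg_annotations,
            "pros_counts_redundant": s.pros_counts_redundant,
            "pros_redundancy": s.pros_redundancy,
            "empty_category": s.empty_category,
        }
        for s in category_stats(records, pros_by_acc)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "category", "n_unique_pros", "n_proteins_with_pros", "n_proteins",
            "coverage_pct", "avg_annotations", "pros_counts_redundant",
            "pros_redundancy", "empty_category",
        ],
    )


def rank_by_pros_residues(
    records: Sequence[ProteinRecord],
    pros_by_acc: ProsByAccession,
    top_n: int | None = None,
) -> pd.DataFrame:
    """Proteins ranked by non-redundant pProS residue count.

    Sorted descending on residue count, ties broken by accession.  Both
    distinct-disease and distinct disease-category-pair counts are emitted
    (they differ when one disease id is assigned under several categories).
    """
    rows = []
    for rec in records:
        pros = pros_by_acc.get(rec.accession, ())
        if not pros:
            continue
        rows.append(
            {
                "accession": rec.accession,
                "pros_residues": pros_residues_per_protein(list(pros)),
                "n_pros": len(pros),
                "n_diseases": len(rec.disease_ids),
                "n_disease_category_pairs": len(
                    {(d.disease_id, d.category) for d in rec.diseases}
                ),
                "categories": ",".join(
                    c for c in CATEGORY_CODES if c in rec.categories
                ),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "accession", "pros_residues", "n_pros", "n_diseases",
            "n_disease_category_pairs", "categories",
        ],
    )
    df = df.sort_values(
        ["pros_residues", "accession"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    if top_n is not None:
        df = df.head(top_n)
    return df
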