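"""Category statistics, redundancy accounting, ranking and rounding."""

import numpy as np
import pandas as pd
import pytest

from pross.disease_stats import (
    average_annotations,
    category_stats,
    category_table,
    coverage_pct,
    rank_by_pros_residues,
    round_half_up,
    table1_stats,
)
from pross.config import ThresholdConfig
from pross.feature_selection import SelectionReason
from pross.intervals import IntervalSet
from pross.pros_calling import PProS
from pross.records_io import DiseaseAssignment, FeatureType, ProteinRecord

CFG = ThresholdConfig()


def _pros(acc, n):
    return [
        PProS(acc, f"F{i:02d}", FeatureType.short_sequence_motif,
              IntervalSet([(10 * i + 1, 10 * i + 5)]), 1.0, SelectionReason.motif_class)
        for i in range(n)
    ]


def _record(acc, diseases, length=500):
    return ProteinRecord(accession=acc, length=length, diseases=diseases)


@pytest.mark.parametrize(
    "x, expected",
    [(2.55, 2.6), (2.64999, 2.6), (2.65, 2.7), (11.901, 11.9), (0.05, 0.1), (1.0, 1.0)],
)
def test_round_half_up(x, expected):
    assert round_half_up(x) == expected


def test_printed_style_ratios_from_integers():
    assert coverage_pct(57, 204) == 27.9
    assert average_annotations(147, 57) == 2.6
    assert coverage_pct(0, 10) == 0.0
    assert average_annotations(5, 0) == 0.0  # empty category reported as 0
    assert coverage_pct(1, 0) == 0.0


def test_category_counting_rules():
    # P1: two cancer diseases + one cardiovascular, 3 segments
    # P2: one cancer disease, no segments
    records = [
        _record("P1", [DiseaseAssignment("D1", "Can"), DiseaseAssignment("D2", "Can"),
                       DiseaseAssignment("D3", "Car")]),
        _record("P2", [DiseaseAssignment("D4", "Can")]),
    ]
    pros = {"P1": _pros("P1", 3)}
    stats = {s.category: s for s in category_stats(records, pros)}

    can = stats["Can"]
    assert can.n_proteins == 2
    assert can.n_proteins_with_pros == 1
    assert can.n_unique_pros == 3
    # P1 has two cancer assignments: each counts its 3 segments again
    assert can.pros_counts_redundant == 6
    assert can.pros_redundancy == pytest.approx(0.5)
    assert can.coverage_pct == 50.0
    assert can.avg_annotations == 3.0

    car = stats["Car"]
    assert car.n_proteins == 1 and car.n_unique_pros == 3
    assert car.pros_counts_redundant == 3
    assert car.pros_redundancy == 1.0  # single assignment in category


def test_multi_category_proteins_counted_per_category():
    records = [
        _record("P1", [DiseaseAssignment("D1", "Can"), DiseaseAssignment("D2", "Ner")]),
        _record("P2", [DiseaseAssignment("D3", "Ner")]),
    ]
    table = category_table(records, {})
    assert table["n_proteins"].sum() >= 2  # 3 category memberships for 2 proteins
    assert table["n_proteins"].sum() == 3


def test_category_table_matches_recount_oracle(rng):
    from pross.records_io import CATEGORY_CODES

    records, pros = [], {}
    for i in range(120):
        acc = f"P{i:03d}"
        n_dis = int(rng.integers(0, 5))
        diseases = [
            DiseaseAssignment(f"D{int(rng.integers(0, 40)):03d}",
                              CATEGORY_CODES[int(rng.integers(0, 15))])
            for _ in range(n_dis)
        ]
        records.append(_record(acc, diseases))
        n_pros = int(rng.integers(0, 4))
        if n_pros:
            pros[acc] = _pros(acc, n_pros)
    table = category_table(records, pros).set_index("category")
    for cat in table.index:
        members = [r for r in records if cat in r.categories]
        with_pros = [r for r in members if pros.get(r.accession)]
        n_unique = sum(len(pros[r.accession]) for r in with_pros)
        n_red = sum(
            len(pros[r.accession]) * sum(1 for d in r.diseases if d.category == cat)
            for r in with_pros
        )
        row = table.loc[cat]
        assert row.n_proteins == len(members)
        assert row.n_proteins_with_pros == len(with_pros)
        assert row.n_unique_pros == n_unique
        assert row.pros_counts_redundant == n_red
        assert row.coverage_pct == coverage_pct(len(with_pros), len(members))


def test_table1_counts_and_percentages():
    from conftest import make_feature

    # disease protein with one short motif called; non-disease protein with one
    rec1 = ProteinRecord(
        "P1", 200,
        features=[make_feature("F1", FeatureType.short_sequence_motif, "m", ((5, 10),)),
                  make_feature("F2", FeatureType.region_of_interest, "Interaction", ((1, 40),))],
        diseases=[DiseaseAssignment("D1", "Can")],
    )
    rec2 = ProteinRecord(
        "P2", 200,
        features=[make_feature("F1", FeatureType.short_sequence_motif, "m", ((5, 10),))],
    )
    pros = {"P1": _pros("P1", 1)}
    t1 = table1_stats([rec1, rec2], pros, CFG).set_index("row")
    assert t1.loc["proteins", "all_proteins"] == 2
    assert t1.loc["proteins", "disease_related"] == 1
    assert t1.loc["proteins", "pros"] == 1
    assert t1.loc["proteins", "pros_pct"] == 100.0
    # F2 is 40 residues: not a short annotation
    assert t1.loc["short_annotations", "all_proteins"] == 2
    assert t1.loc["short_annotations", "disease_related"] == 1


def test_table1_zero_calls_gives_zero_percentages():
    rec = _record("P1", [DiseaseAssignment("D1", "Can")])
    t1 = table1_stats([rec], {}, CFG)
    assert (t1["pros_pct"] == 0.0).all()


def test_ranking_order_and_ties():
    records = [_record(a, [DiseaseAssignment("D1", "Can")]) for a in ("A", "B", "C", "D")]
    pros = {
        "A": [PProS("A", "F1", FeatureType.short_sequence_motif,
                    IntervalSet([(1, 63)]), 1.0, SelectionReason.motif_class)],
        "B": [PProS("B", "F1", FeatureType.short_sequence_motif,
                    IntervalSet([(1, 61)]), 1.0, SelectionReason.motif_class)],
        "C": [PProS("C", "F1", FeatureType.short_sequence_motif,
                    IntervalSet([(1, 55)]), 1.0, SelectionReason.motif_class)],
        "D": [PProS("D", "F1", FeatureType.short_sequence_motif,
                    IntervalSet([(1, 55)]), 1.0, SelectionReason.motif_class)],
    }
    ranked = rank_by_pros_residues(records, pros)
    assert list(ranked.accession) == ["A", "B", "C", "D"]  # ties C/D lexicographic
    assert list(ranked.pros_residues) == [63, 61, 55, 55]
    top2 = rank_by_pros_residues(records, pros, top_n=2)
    assert list(top2.accession) == ["A", "B"]


def test_ranking_matches_sort_oracle(rng):
    records, pros = [], {}
    for i in range(60):
        acc = f"P{i:03d}"
        records.append(_record(acc, [DiseaseAssignment("D1", "Can")]))
        start = int(rng.integers(1, 300))
        pros[acc] = [
            PProS(acc, "F1", FeatureType.short_sequence_motif,
                  IntervalSet([(start, start + int(rng.integers(0, 60)))]),
                  1.0, SelectionReason.motif_class)
        ]
    ranked = rank_by_pros_residues(records, pros)
    expected = sorted(
        ((pros[r.accession][0].intervals.total_length, r.accession) for r in records),
        key=lambda t: (-t[0], t[1]),
    )
    assert list(ranked.accession) == [a for _, a in expected]


def test_percentages_recomputable_from_integer_columns(rng):
    records = [
        _record(f"P{i}", [DiseaseAssignment(f"D{int(rng.integers(0, 10))}", "Can")])
        for i in range(30)
    ]
    pros = {r.accession: _pros(r.accession, 1) for r in records[:7]}
    table = category_table(records, pros)
    for row in table.itertuples():
        assert row.coverage_pct == coverage_pct(row.n_proteins_with_pros, row.n_proteins)
        assert row.avg_annotations == average_annotations(row.n_unique_pros, row.n_proteins_with_pros)
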