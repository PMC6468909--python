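"""Segment calling against consensus disorder and non-redundant residue counts."""

import dataclasses

import pytest

from pross.config import ThresholdConfig
from pross.feature_selection import select_binding_features
from pross.idr_consensus import consensus_intervals
from pross.intervals import IntervalSet
from pross.pros_calling import (
    call_pros,
    feature_idr_coverage,
    intersect_features_with_idrs,
    pros_residues_per_protein,
    union_residue_count,
)
from pross.records_io import DisorderTrack, FeatureType, Predictor

from conftest import make_feature, random_intervals

CFG = ThresholdConfig()


def _consensus(length, spans):
    tracks = [
        DisorderTrack(Predictor.mobidb_lite, IntervalSet(spans)),
        DisorderTrack(Predictor.disopred3, IntervalSet(spans)),
    ]
    return consensus_intervals(tracks, length, CFG)


def test_feature_inside_terminal_idr_is_called():
    consensus = _consensus(393, [(1, 60)])
    feat = make_feature("F01", FeatureType.short_sequence_motif, "TAD I", ((15, 25),))
    selected = select_binding_features([feat], CFG)
    (call,) = call_pros("P04637", selected, consensus, CFG)
    assert call.intervals == IntervalSet([(15, 25)])
    assert call.idr_coverage == 1.0


def test_feature_outside_consensus_not_called():
    consensus = _consensus(200, [(1, 60)])
    feat = make_feature("F01", FeatureType.short_sequence_motif, "m", ((100, 110),))
    assert call_pros("P1", select_binding_features([feat], CFG), consensus, CFG) == []


def test_partially_covered_feature_needs_threshold():
    consensus = _consensus(200, [(1, 20)])
    feat = make_feature("F01", FeatureType.short_sequence_motif, "m", ((11, 30),))  # half inside
    assert call_pros("P1", select_binding_features([feat], CFG), consensus, CFG) == []
    lax = dataclasses.replace(CFG, idr_coverage_threshold=0.5)
    (call,) = call_pros("P1", select_binding_features([feat], lax), consensus, lax)
    assert call.idr_coverage == pytest.approx(0.5)


def test_point_feature_coverage():
    consensus = _consensus(100, [(10, 40)])
    inside = make_feature("V1", FeatureType.variant, "variant", ((25, 25),))
    outside = make_feature("V2", FeatureType.variant, "variant", ((90, 90),))
    report = dict(
        (f.feature_id, cov)
        for f, cov in intersect_features_with_idrs([inside, outside], consensus)
    )
    assert report == {"V1": 1.0, "V2": 0.0}


def test_union_residue_count_examples():
    assert union_residue_count([IntervalSet([(360, 365)]), IntervalSet([(360, 362)])]) == 6
    assert union_residue_count([IntervalSet([(1, 5)])]) == 5
    assert union_residue_count([]) == 0


def test_union_matches_set_oracle(rng):
    for _ in range(300):
        length = int(rng.integers(20, 200))
        sets = [IntervalSet(random_intervals(rng, length)) for _ in range(int(rng.integers(1, 5)))]
        brute = set().union(*(s.residues() for s in sets))
        assert union_residue_count(sets) == len(brute)


def test_pros_residue_accounting():
    consensus = _consensus(100, [(1, 60)])
    feats = [
        make_feature("A", FeatureType.short_sequence_motif, "m", ((10, 19),)),
        make_feature("B", FeatureType.short_sequence_motif, "m", ((10, 19),)),
    ]
    calls = call_pros("P1", select_binding_features(feats, CFG), consensus, CFG)
    assert len(calls) == 2  # overlapping annotations stay separate calls
    assert pros_residues_per_protein(calls) == 10  # but residues are unique
    disjoint = [
        make_feature("C", FeatureType.short_sequence_motif, "m", ((1, 5),)),
        make_feature("D", FeatureType.short_sequence_motif, "m", ((7, 9),)),
    ]
    calls = call_pros("P1", select_binding_features(disjoint, CFG), consensus, CFG)
    assert pros_residues_per_protein(calls) == 8


def test_calls_match_residue_membership_oracle_at_two_thresholds(rng):
    for threshold in (1.0, 0.5):
        cfg = dataclasses.replace(CFG, idr_coverage_threshold=threshold)
        for _ in range(100):
            length = int(rng.integers(40, 160))
            consensus = _consensus(length, random_intervals(rng, length))
            idr = consensus.intervals.residues()
            feats = []
            for i in range(int(rng.integers(1, 6))):
                start = int(rng.integers(1, length - 5))
                end = min(length, start + int(rng.integers(1, 25)))
                feats.append(
                    make_feature(f"F{i}", FeatureType.short_sequence_motif, "m", ((start, end),))
                )
            selected = select_binding_features(feats, cfg)
            called = {c.feature_id for c in call_pros("P", selected, consensus, cfg)}
            expected = set()
            for sel in selected:
                residues = sel.feature.location.residues()
                if len(residues & idr) / len(residues) >= threshold:
                    expected.add(sel.feature.feature_id)
            assert called == expected


def test_threshold_monotonicity(rng):
    for _ in range(50):
        length = int(rng.integers(40, 160))
        consensus = _consensus(length, random_intervals(rng, length))
        feats = [
            make_feature(f"F{i}", FeatureType.short_sequence_motif, "m",
                         ((s := int(rng.integers(1, length - 10)), s + 9),))
            for i in range(5)
        ]
        calls = {}
        for threshold in (0.25, 0.5, 1.0):
            cfg = dataclasses.replace(CFG, idr_coverage_threshold=threshold)
            selected = select_binding_features(feats, cfg)
            calls[threshold] = {c.feature_id for c in call_pros("P", selected, consensus, cfg)}
        assert calls[1.0] <= calls[0.5] <= calls[0.25]


def test_calls_never_extend_annotations():
    consensus = _consensus(100, [(1, 100)])
    feat = make_feature("F1", FeatureType.short_sequence_motif, "m", ((5, 9), (20, 24)))
    (call,) = call_pros("P", select_binding_features([feat], CFG), consensus, CFG)
    assert call.intervals.residues() <= feat.location.residues()


def test_coverage_of_multi_interval_feature():
    consensus = _consensus(100, [(1, 10)])
    feat = make_feature("F1", FeatureType.short_sequence_motif, "m", ((5, 9), (20, 24)))
    assert feature_idr_coverage(feat, consensus) == pytest.approx(0.5)
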