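"""Length rule and keyword/negation selection of binding-associated features."""

import dataclasses
import re

import pytest

from pross.config import ThresholdConfig
from pross.feature_selection import (
    SelectionReason,
    is_short,
    select_binding_features,
    selection_reason,
)
from pross.records_io import FeatureType

from conftest import make_feature

CFG = ThresholdConfig()


@pytest.mark.parametrize(
    "spans, expected",
    [
        (((368, 387),), True),   # 20 residues
        (((1, 29),), True),      # boundary: 29 qualifies
        (((1, 30),), False),     # 30 = "not shorter than 30"
        (((370, 372), (368, 387)), True),  # non-redundant union = 20
    ],
)
def test_length_rule(spans, expected):
    assert is_short(make_feature(spans=spans), CFG) is expected


@pytest.mark.parametrize(
    "ftype, description, expected",
    [
        (FeatureType.short_sequence_motif, "TAD I", SelectionReason.motif_class),
        (FeatureType.region_of_interest, "Interaction with USP7", SelectionReason.keyword_region),
        (FeatureType.region_of_interest, "Mediates binding to AP-2", SelectionReason.keyword_region),
        (FeatureType.region_of_interest, "LXXLL motif", SelectionReason.keyword_region),
        (FeatureType.region_of_interest, "Basic", None),
        (FeatureType.mutagenesis_site, "Loss of interactions with MDM2", SelectionReason.keyword_mutagenesis),
        (FeatureType.mutagenesis_site, "Abolishes binding to USP7", SelectionReason.keyword_mutagenesis),
        (FeatureType.mutagenesis_site, "Does not abolish binding to X", None),
        (FeatureType.mutagenesis_site, "No effect on interaction with Y", None),
        # "motif" is a region keyword, not a mutagenesis one
        (FeatureType.mutagenesis_site, "Alters motif conformation", None),
        # negation must match whole words: "nuclear"/"noted" contain "no"
        (FeatureType.mutagenesis_site, "Nuclear binding noted", SelectionReason.keyword_mutagenesis),
        (FeatureType.variant, "Interaction with X", None),
        (FeatureType.modified_residue, "binding", None),
    ],
)
def test_keyword_rules(ftype, description, expected):
    feat = make_feature(ftype=ftype, description=description)
    assert selection_reason(feat, CFG) is expected


def test_selection_applies_length_then_keywords():
    short_hit = make_feature("A", FeatureType.region_of_interest, "Interaction with X", ((1, 10),))
    long_hit = make_feature("B", FeatureType.region_of_interest, "Interaction with X", ((1, 40),))
    short_miss = make_feature("C", FeatureType.region_of_interest, "Basic", ((1, 10),))
    selected = select_binding_features([short_hit, long_hit, short_miss], CFG)
    assert [s.feature.feature_id for s in selected] == ["A"]


def test_selection_permutes_with_input():
    feats = [
        make_feature(f"F{i}", FeatureType.short_sequence_motif, "m", ((i + 1, i + 5),))
        for i in range(6)
    ]
    fwd = [s.feature.feature_id for s in select_binding_features(feats, CFG)]
    rev = [s.feature.feature_id for s in select_binding_features(feats[::-1], CFG)]
    assert rev == fwd[::-1]


def _oracle_selected(ftype, description, cfg) -> bool:
    """Independent token-based re-statement of the keyword rules."""
    words = [w.lower() for w in re.findall(r"[A-Za-z0-9]+", description)]
    def hits(keywords):
        return any(w.startswith(k) for w in words for k in keywords)
    if ftype is FeatureType.short_sequence_motif:
        return True
    if ftype is FeatureType.region_of_interest:
        return hits(cfg.positive_keywords_region)
    if ftype is FeatureType.mutagenesis_site:
        return hits(cfg.positive_keywords_mutagenesis) and not any(
            w in cfg.negation_tokens for w in words
        )
    return False


def test_random_descriptions_match_token_oracle(rng):
    vocab = ["interaction", "binds", "binding", "motif", "no", "not", "loss",
             "nuclear", "notably", "domain", "with", "abolishes", "effect",
             "region", "basic", "Interacts", "NOT", "No"]
    types = [FeatureType.region_of_interest, FeatureType.mutagenesis_site,
             FeatureType.short_sequence_motif, FeatureType.variant]
    for _ in range(500):
        ftype = types[int(rng.integers(0, len(types)))]
        words = rng.choice(vocab, size=int(rng.integers(1, 6)))
        desc = " ".join(words)
        feat = make_feature(ftype=ftype, description=desc)
        got = selection_reason(feat, CFG) is not None
        assert got == _oracle_selected(ftype, desc, CFG), (ftype, desc)


def test_keyword_monotonicity(rng):
    """Growing the positive sets never loses a selection; growing the
    negation set never gains one."""
    feats = [
        make_feature(
            f"F{i}",
            [FeatureType.region_of_interest, FeatureType.mutagenesis_site][i % 2],
            " ".join(rng.choice(["interaction", "loss", "signal", "binding",
                                 "no", "effect", "docking"],
                                size=int(rng.integers(1, 5)))),
            ((1, 10),),
        )
        for i in range(60)
    ]
    base = {s.feature.feature_id for s in select_binding_features(feats, CFG)}
    wider = dataclasses.replace(
        CFG,
        positive_keywords_region=CFG.positive_keywords_region | {"signal", "dock"},
        positive_keywords_mutagenesis=CFG.positive_keywords_mutagenesis | {"loss"},
    )
    assert base <= {s.feature.feature_id for s in select_binding_features(feats, wider)}
    stricter = dataclasses.replace(CFG, negation_tokens=CFG.negation_tokens | {"loss", "effect"})
    assert {s.feature.feature_id for s in select_binding_features(feats, stricter)} <= base
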