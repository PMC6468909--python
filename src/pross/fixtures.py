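"""Hand-coded miniature cohorts for regression testing.

Synthetic stand-ins for three well-studied disease proteins whose
disorder/annotation geometry exercises specific rules:

* ``p53_like`` — a transcription-factor-like chain (393 aa) with disordered
  N- and C-terminal regions and eleven short binding annotations, including
  three stacked at 15-25 and overlapping spans at 359-363/368-387/370-372;
  every annotation must be called.
* ``smn_like`` — an snRNP-assembly-factor-like chain (294 aa) whose
  N-terminal partner-binding region is 32 residues long: inside predicted
  disorder but over the 29-residue cut, so it must NOT be called (a
  pseudo-segment), while two C-terminal annotations are called.
* ``arh_like`` — an endocytosis-adaptor-like chain (308 aa) with a
  C-terminal disordered tail carrying clathrin- and AP-2-binding segments;
  only two of three predictor tracks exist (the consensus still reaches two
  votes), and a negated mutagenesis description must be discarded.

All coordinates are synthetic but shaped on the real proteins' geometry.
"""

from __future__ import annotations

from pathlib import Path

from .intervals import IntervalSet
from .records_io import (
    DiseaseAssignment,
    DisorderTrack,
    FeatureAnnotation,
    FeatureType,
    Predictor,
    ProteinRecord,
    write_cohort,
)

_REGION = FeatureType.region_of_interest
_MUT = FeatureType.mutagenesis_site
_MOTIF = FeatureType.short_sequence_motif


def _feat(fid: str, ftype: FeatureType, desc: str, start: int, end: int) -> FeatureAnnotation:
    return FeatureAnnotation(fid, ftype, desc, IntervalSet([(start, end)]))


def _track(pred: Predictor, *spans: tuple[int, int]) -> DisorderTrack:
    return DisorderTrack(pred, IntervalSet(spans))


def _p53_like() -> list[ProteinRecord]:
    features = [
        _feat("F01", _MOTIF, "TAD I", 15, 25),
        _feat("F02", _MUT, "Loss of interactions with MDM2", 15, 25),
        _feat("F03", _MUT, "Loss of interaction with PPP2R5C, PPP2CA and PPP2R1A", 15, 25),
        _feat("F04", _MOTIF, "TAD II", 48, 56),
        _feat("F05", _MOTIF, "Bipartite nuclear localization signal", 305, 321),
        _feat("F06", _MOTIF, "[KR]-[STA]-K motif", 359, 363),
        _feat("F07", _REGION, "Interaction with USP7", 359, 363),
        _feat("F08", _MUT, "Abolishes binding to USP7", 359, 363),
        _feat("F09", _REGION, "Interaction with HIPK1", 359, 363),
        _feat("F10", _REGION, "Interaction with CCAR2", 370, 372),
        _feat("F11", _REGION, "Basic (interaction with DNA)", 368, 387),
    ]
    tracks = {
        Predictor.mobidb_lite: _track(Predictor.mobidb_lite, (1, 100), (280, 393)),
        Predictor.disopred3: _track(Predictor.disopred3, (1, 95), (285, 393)),
        Predictor.dichot: _track(Predictor.dichot, (1, 105), (300, 393)),
    }
    diseases = [
        DiseaseAssignment(f"HC{i:04d}", "Can") for i in range(1, 9)
    ] + [DiseaseAssignment("HN0001", "Ner")]
    return [
        ProteinRecord(
            accession="P53LIKE",
            length=393,
            features=features,
            tracks=tracks,
            diseases=diseases,
            location_terms=["cytoplasm", "nucleus"],
            interactor_count=1056,
        )
    ]


#: annotation coordinates that must be called on the p53-like fixture,
#: one entry per expected call (overlaps kept separate)
P53_EXPECTED_CALLS = (
    (15, 25), (15, 25), (15, 25), (48, 56), (305, 321),
    (359, 363), (359, 363), (359, 363), (359, 363), (370, 372), (368, 387),
)


def _smn_like() -> list[ProteinRecord]:
    features = [
        # 32 residues: inside disorder but over the length cut -> pseudo-segment
        _feat("F01", _REGION, "Interaction with GEMIN2", 13, 44),
        _feat("F02", _REGION, "Interaction with hnRNP Q", 279, 294),
        _feat("F03", _MOTIF, "YG-box oligomerization motif", 252, 264),
    ]
    tracks = {
        Predictor.mobidb_lite: _track(Predictor.mobidb_lite, (1, 50), (235, 294)),
        Predictor.disopred3: _track(Predictor.disopred3, (1, 45), (240, 294)),
        Predictor.dichot: _track(Predictor.dichot, (1, 55), (245, 294)),
    }
    return [
        ProteinRecord(
            accession="SMNLIKE",
            length=294,
            features=features,
            tracks=tracks,
            diseases=[DiseaseAssignment("HN0002", "Ner")],
            location_terms=["cytoplasm", "nucleus"],
            interactor_count=50,
        )
    ]


#: the over-length annotation that must be excluded on the SMN-like fixture
SMN_PSEUDO_FEATURE_ID = "F01"


def _arh_like() -> list[ProteinRecord]:
    features = [
        _feat("F01", _REGION, "Clathrin box binding motif", 212, 216),
        _feat("F02", _REGION, "AP-2 complex subunit beta binding", 255, 264),
        _feat("F03", _MUT, "Does not affect LDLR binding", 220, 224),
    ]
    # one predictor calls nothing here, so its track is simply absent
    tracks = {
        Predictor.disopred3: _track(Predictor.disopred3, (1, 40), (190, 308)),
        Predictor.dichot: _track(Predictor.dichot, (1, 35), (180, 308)),
    }
    return [
        ProteinRecord(
            accession="ARHLIKE",
            length=308,
            features=features,
            tracks=tracks,
            diseases=[DiseaseAssignment("HD0001", "Dme")],
            location_terms=["cytoplasm"],
            interactor_count=18,
        )
    ]


FIXTURES = {
    "p53_like": _p53_like,
    "smn_like": _smn_like,
    "arh_like": _arh_like,
}


def fixture_records(name: str) -> list[ProteinRecord]:
    try:
        return FIXTURES[name]()
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None


def make_fixture(name: str, out_dir: str | Path) -> dict[str, Path]:
    """Write one fixture cohort in the five-table input dialect."""
    return write_cohort(fixture_records(name), out_dir)
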