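"""Domain model and tab-separated input/output dialects.

A cohort is a set of proteins, each with a length, UniProt-style feature
annotations (type + free-text description + residue location), up to three
disorder-predictor tracks, KEGG-style disease assignments in 15 category
codes, subcellular-location terms, and an interactor count.

Input dialect (all files TSV with header, UTF-8, 1-based inclusive spans):

``features.tsv``
    accession, length, feature_type, description, start, end, feature_id.
    A protein without features is declared by one row whose feature columns
    are all empty.  A multi-interval feature repeats its feature_id across
    rows (description/type must agree).
``tracks.tsv``
    accession, predictor_id, start, end — one row per disordered interval;
    residues not covered are ordered.  A predictor that calls nothing is
    simply absent.
``diseases.tsv``
    accession, disease_id, category_code (one of the 15 codes).
``locations.tsv``
    accession, location_term.
``ppi.tsv``
    accession, interactor_count.

Validation is fail-fast: malformed rows raise :class:`CohortValidationError`
naming the accession (and feature) at fault; nothing is silently dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import ThresholdConfig
from .intervals import IntervalSet


class CohortValidationError(ValueError):
    """Raised when an input table violates the dialect or the data model."""


class FeatureType(str, Enum):
    region_of_interest = "region_of_interest"
    mutagenesis_site = "mutagenesis_site"
    short_sequence_motif = "short_sequence_motif"
    variant = "variant"
    modified_residue = "modified_residue"
    other = "other"


#: The three candidate classes mined for binding-associated segments.
CANDIDATE_FEATURE_TYPES = (
    FeatureType.region_of_interest,
    FeatureType.mutagenesis_site,
    FeatureType.short_sequence_motif,
)


class Predictor(str, Enum):
    mobidb_lite = "mobidb_lite"
    disopred3 = "disopred3"
    dichot = "dichot"


#: The 15 disease-category codes, in canonical report order.
CATEGORY_CODES = (
    "Can", "Car", "Dme", "Mal", "Dig", "End", "Imm", "Mus",
    "Ner", "Oco", "Rep", "Res", "Ski", "Uri", "Oth",
)
CATEGORY_NAMES = {
    "Can": "Cancers",
    "Car": "Cardiovascular diseases",
    "Dme": "Congenital disorders of metabolism",
    "Mal": "Congenital malformations",
    "Dig": "Digestive system diseases",
    "End": "Endocrine and metabolic diseases",
    "Imm": "Immune system diseases",
    "Mus": "Musculoskeletal diseases",
    "Ner": "Nervous system diseases",
    "Oco": "Other congenital disorders",
    "Rep": "Reproductive system diseases",
    "Res": "Respiratory diseases",
    "Ski": "Skin diseases",
    "Uri": "Urinary system diseases",
    "Oth": "Other diseases",
}


@dataclass(frozen=True)
class FeatureAnnotation:
    """One feature-table entry: type, free-text description, location."""

    feature_id: str
    feature_type: FeatureType
    description: str
    location: IntervalSet

    def __post_init__(self) -> None:
        if not self.location:
            raise CohortValidationError(
                f"feature {self.feature_id!r} has an empty location"
            )

    @property
    def length(self) -> int:
        """Non-redundant residue count of the location."""
        return self.location.total_length


@dataclass(frozen=True)
class DisorderTrack:
    """Per-predictor disorder calls, stored as disordered intervals."""

    predictor: Predictor
    intervals: IntervalSet

    def to_mask(self, length: int) -> np.ndarray:
        return self.intervals.to_mask(length)

    @classmethod
    def from_mask(cls, predictor: Predictor, mask) -> "DisorderTrack":
        return cls(predictor, IntervalSet.from_mask(mask))


@dataclass(frozen=True)
class DiseaseAssignment:
    disease_id: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORY_CODES:
            raise CohortValidationError(
                f"unknown disease category code {self.category!r} "
                f"(disease {self.disease_id!r})"
            )


@dataclass
class ProteinRecord:
    accession: str
    length: int
    features: list[FeatureAnnotation] = field(default_factory=list)
    tracks: dict[Predictor, DisorderTrack] = field(default_factory=dict)
    diseases: list[DiseaseAssignment] = field(default_factory=list)
    location_terms: list[str] = field(default_factory=list)
    interactor_count: Optional[int] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.length < 1:
            raise CohortValidationError(
                f"{self.accession}: protein length must be positive, got {self.length}"
            )
        for feat in self.features:
            if feat.location.max_end > self.length:
                raise CohortValidationError(
                    f"{self.accession}: feature {feat.feature_id!r} spans residue "
                    f"{feat.location.max_end} beyond protein length {self.length}"
                )
        for track in self.tracks.values():
            if track.intervals.max_end > self.length:
                raise CohortValidationError(
                    f"{self.accession}: {track.predictor.value} track spans residue "
                    f"{track.intervals.max_end} beyond protein length {self.length}"
                )
        if self.interactor_count is not None and self.interactor_count < 0:
            raise CohortValidationError(
                f"{self.accession}: interactor_count must be non-negative"
            )

    @property
    def is_disease_related(self) -> bool:
        return bool(self.diseases)

    @property
    def disease_ids(self) -> set[str]:
        return {d.disease_id for d in self.diseases}

    @property
    def categories(self) -> set[str]:
        return {d.category for d in self.diseases}


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

FEATURE_COLUMNS = ["accession", "length", "feature_type", "description", "start", "end", "feature_id"]
TRACK_COLUMNS = ["accession", "predictor_id", "start", "end"]
DISEASE_COLUMNS = ["accession", "disease_id", "category_code"]
LOCATION_COLUMNS = ["accession", "location_term"]
PPI_COLUMNS = ["accession", "interactor_count"]


def _read_tsv(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=list(columns))
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise CohortValidationError(f"{path}: missing columns {missing}")
    return df


def _to_int(value: str, what: str, accession: str) -> int:
    try:
        return int(value)
    except (TypeError, ValueError):
        raise CohortValidationError(
            f"{accession}: {what} must be an integer, got {value!r}"
        ) from None


def _parse_feature_type(raw: str) -> FeatureType:
    try:
        return FeatureType(raw)
    except ValueError:
        # pass-through classes outside the modelled set (e.g. UniProt
        # "helix", "chain") are carried as `other`
        return FeatureType.other


def read_cohort(
    annotation_path: str | Path,
    tracks_path: str | Path | None = None,
    disease_path: str | Path | None = None,
    location_path: str | Path | None = None,
    ppi_path: str | Path | None = None,
) -> list[ProteinRecord]:
    """Read a cohort from the five-table dialect.

    Only the feature table is mandatory; omitted tables leave diseases /
    locations empty and interactor_count absent.  Returns records ordered
    by accession.
    """
    feats = _read_tsv(annotation_path, FEATURE_COLUMNS)

    lengths: dict[str, int] = {}
    # feature rows grouped by (accession, feature_id)
    raw_feats: dict[str, dict[str, dict]] = {}
    for row in feats.itertuples(index=False):
        acc = row.accession.strip()
        if not acc:
            raise CohortValidationError(f"{annotation_path}: row with empty accession")
        length = _to_int(row.length, "length", acc)
        if acc in lengths and lengths[acc] != length:
            raise CohortValidationError(
                f"duplicate accession {acc!r} with conflicting lengths "
                f"{lengths[acc]} and {length}"
            )
        lengths[acc] = length
        if row.feature_type == "" and row.feature_id == "":
            continue  # bare protein declaration
        if row.feature_id == "":
            raise CohortValidationError(f"{acc}: feature row without feature_id")
        ftype = _parse_feature_type(row.feature_type)
        start = _to_int(row.start, f"feature {row.feature_id!r} start", acc)
        end = _to_int(row.end, f"feature {row.feature_id!r} end", acc)
        if not (1 <= start <= end):
            raise CohortValidationError(
                f"{acc}: feature {row.feature_id!r} has invalid span ({start}, {end})"
            )
        entry = raw_feats.setdefault(acc, {}).setdefault(
            row.feature_id, {"type": ftype, "description": row.description, "spans": []}
        )
        if entry["type"] is not ftype or entry["description"] != row.description:
            raise CohortValidationError(
                f"{acc}: feature {row.feature_id!r} rows disagree on type/description"
            )
        entry["spans"].append((start, end))

    def _require_known(acc: str, table: str) -> None:
        if acc not in lengths:
            raise CohortValidationError(
                f"{table}: accession {acc!r} not declared in the feature table"
            )

    raw_tracks: dict[str, dict[Predictor, list[tuple[int, int]]]] = {}
    if tracks_path is not None:
        for row in _read_tsv(tracks_path, TRACK_COLUMNS).itertuples(index=False):
            acc = row.accession.strip()
            _require_known(acc, "tracks")
            try:
                pred = Predictor(row.predictor_id)
            except ValueError:
                raise CohortValidationError(
                    f"{acc}: unknown predictor_id {row.predictor_id!r}"
                ) from None
            start = _to_int(row.start, f"{pred.value} track start", acc)
            end = _to_int(row.end, f"{pred.value} track end", acc)
            if not (1 <= start <= end):
                raise CohortValidationError(
                    f"{acc}: {pred.value} track has invalid span ({start}, {end})"
                )
            raw_tracks.setdefault(acc, {}).setdefault(pred, []).append((start, end))

    diseases: dict[str, list[DiseaseAssignment]] = {}
    if disease_path is not None:
        for row in _read_tsv(disease_path, DISEASE_COLUMNS).itertuples(index=False):
            acc = row.accession.strip()
            _require_known(acc, "diseases")
            diseases.setdefault(acc, []).append(
                DiseaseAssignment(row.disease_id, row.category_code)
            )

    locations: dict[str, list[str]] = {}
    if location_path is not None:
        for row in _read_tsv(location_path, LOCATION_COLUMNS).itertuples(index=False):
            acc = row.accession.strip()
            _require_known(acc, "locations")
            locations.setdefault(acc, []).append(row.location_term)

    interactors: dict[str, int] = {}
    if ppi_path is not None:
        for row in _read_tsv(ppi_path, PPI_COLUMNS).itertuples(index=False):
            acc = row.accession.strip()
            _require_known(acc, "ppi")
            count = _to_int(row.interactor_count, "interactor_count", acc)
            if acc in interactors and interactors[acc] != count:
                raise CohortValidationError(
                    f"{acc}: conflicting interactor counts in ppi table"
                )
            interactors[acc] = count

    records: list[ProteinRecord] = []
    for acc in sorted(lengths):
        feats_list = [
            FeatureAnnotation(fid, entry["type"], entry["description"], IntervalSet(entry["spans"]))
            for fid, entry in sorted(raw_feats.get(acc, {}).items())
        ]
        tracks = {
            pred: DisorderTrack(pred, IntervalSet(spans))
            for pred, spans in sorted(
                raw_tracks.get(acc, {}).items(), key=lambda kv: kv[0].value
            )
        }
        records.append(
            ProteinRecord(
                accession=acc,
                length=lengths[acc],
                features=feats_list,
                tracks=tracks,
                diseases=diseases.get(acc, []),
                location_terms=locations.get(acc, []),
                interactor_count=interactors.get(acc),
            )
        )
    return records


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def write_cohort(records: Sequence[ProteinRecord], out_dir: str | Path) -> dict[str, Path]:
    """Write a cohort back to the five-table dialect.

    Rows are sorted (accession, then feature_id/predictor/disease_id/term)
    so identical cohorts serialize byte-identically regardless of the order
    records were built in.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    feat_rows, track_rows, disease_rows, loc_rows, ppi_rows = [], [], [], [], []
    for rec in sorted(records, key=lambda r: r.accession):
        if not rec.features:
            feat_rows.append((rec.accession, rec.length, "", "", "", "", ""))
        for feat in sorted(rec.features, key=lambda f: f.feature_id):
            for iv in feat.location:
                feat_rows.append(
                    (rec.accession, rec.length, feat.feature_type.value,
                     feat.description, iv.start, iv.end, feat.feature_id)
                )
        for pred in sorted(rec.tracks, key=lambda p: p.value):
            for iv in rec.tracks[pred].intervals:
                track_rows.append((rec.accession, pred.value, iv.start, iv.end))
        for d in sorted(rec.diseases, key=lambda d: (d.disease_id, d.category)):
            disease_rows.append((rec.accession, d.disease_id, d.category))
        for term in sorted(rec.location_terms):
            loc_rows.append((rec.accession, term))
        if rec.interactor_count is not None:
            ppi_rows.append((rec.accession, rec.interactor_count))

    paths = {}
    for name, rows, cols in (
        ("features", feat_rows, FEATURE_COLUMNS),
        ("tracks", track_rows, TRACK_COLUMNS),
        ("diseases", disease_rows, DISEASE_COLUMNS),
        ("locations", loc_rows, LOCATION_COLUMNS),
        ("ppi", ppi_rows, PPI_COLUMNS),
    ):
        path = out_dir / f"{name}.tsv"
        pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
        paths[name] = path
    return paths


def write_report(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    config: ThresholdConfig,
    extra_meta: Mapping[str, object] | None = None,
) -> dict[str, Path]:
    """Write report tables as TSV plus a ``config.json`` sidecar.

    Each table is written as ``<name>.tsv`` with header, UTF-8.  Row order
    is whatever the table constructors produced (they all sort on documented
    keys), so identical inputs give byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name in sorted(tables):
        path = out_dir / f"{name}.tsv"
        tables[name].to_csv(path, sep="\t", index=False)
        paths[name] = path
    sidecar = {"thresholds": config.to_dict()}
    if extra_meta:
        sidecar.update(extra_meta)
    cfg_path = out_dir / "config.json"
    cfg_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    paths["config"] = cfg_path
    return paths
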