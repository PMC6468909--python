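"""Synthetic cohorts with known ground truth.

The generator emulates the five input tables of a real run — feature
annotations, three disorder-predictor tracks, disease assignments,
subcellular-location terms and interactor counts — on made-up proteins
whose true disorder, true planted binding segments, true location class and
true disease counts are recorded, so every pipeline output can be checked
against a brute-force recomputation from ground truth.

Per protein:

* chain length is log-normal (median 400 aa), the true disordered content
  is Beta-distributed around the target fraction and placed as one or two
  segments, biased toward the chain termini;
* each predictor track echoes the true per-residue disorder state with its
  agreement probability (agreement 1.0 reproduces truth exactly);
* planted binding segments (Poisson count) sit fully inside true disordered
  segments, 3-29 residues long, with descriptions templated on real
  annotation phrasing ("Interaction with X", "Loss of interaction with X",
  "LXXLL motif") so the keyword rules are exercised realistically;
* decoy features are planted that must NOT be called: keyword features in
  ordered regions, negated mutagenesis descriptions, over-length (>29 aa)
  segments inside disorder, and keyword-free regions;
* disease counts follow a truncated power law (Zipf) over a fixed disease
  catalog whose entries each carry one category;
* the location class is drawn from group-specific probabilities (the
  pProS-containing group is CN-enriched by construction);
* interactor counts are linear in the distinct-disease count plus Gaussian
  noise (noise 0 gives an exactly linear, correlation-1 relationship).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .intervals import Interval, IntervalSet
from .records_io import (
    CATEGORY_CODES,
    DiseaseAssignment,
    DisorderTrack,
    FeatureAnnotation,
    FeatureType,
    Predictor,
    ProteinRecord,
    write_cohort,
)

#: class order used by the localization probability tuples
LOC_CLASS_ORDER = ("N", "C", "M", "CN", "other")

_OTHER_TERMS = (
    "endoplasmic reticulum",
    "mitochondrion",
    "golgi apparatus",
    "cell junction",
    "cell projection",
    "p-body",
    "stress granule",
    "lipid droplet",
)

_MOTIF_TEMPLATES = (
    "LXXLL motif",
    "SH3-binding",
    "Bipartite nuclear localization signal",
    "[KR]-[STA]-K motif",
    "PDZ-binding motif",
)
_REGION_TEMPLATES = (
    "Interaction with {p}",
    "Binding site for {p}",
    "Required for interaction with {p}",
    "Mediates binding to {p}",
)
_MUTAGENESIS_TEMPLATES = (
    "Loss of interaction with {p}",
    "Abolishes binding to {p}",
    "Impairs interaction with {p}",
    "Reduced binding to {p}",
)
_NEGATED_TEMPLATES = (
    "Does not affect interaction with {p}",
    "No effect on binding to {p}",
    "Does not abolish binding to {p}",
)
_NONBINDING_TEMPLATES = (
    "Basic region",
    "Acidic",
    "Disordered linker",
    "Polyampholyte stretch",
)


@dataclass(frozen=True)
class GeneratorParams:
    """Study conditions of a synthetic cohort; fully determine it with seed."""

    n_proteins: int = 500
    length_median: float = 400.0
    length_sigma: float = 0.6
    min_length: int = 60
    max_length: int = 5000
    target_disorder_fraction: float = 0.30
    disorder_concentration: float = 50.0
    terminal_idr_bias: float = 0.8
    predictor_agreement: tuple[float, float, float] = (0.9, 0.9, 0.9)
    n_planted_pros: float = 0.4
    decoy_feature_rate: float = 0.6
    variant_rate: float = 2.0
    variant_idr_fraction: float = 0.4
    phospho_rate: float = 1.0
    disease_fraction: float = 0.17
    disease_power_exponent: float = 2.0
    max_diseases: int = 60
    n_disease_entries: int = 300
    n_categories: int = 15
    loc_probs_pros: tuple[float, ...] = (0.22, 0.14, 0.10, 0.30, 0.24)
    loc_probs_non_pros: tuple[float, ...] = (0.15, 0.20, 0.20, 0.20, 0.25)
    ppi_intercept: float = 5.0
    ppi_slope: float = 20.0
    ppi_noise: float = 15.0
    ppi_missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if not (0 < self.target_disorder_fraction < 1):
            raise ValueError("target_disorder_fraction must be in (0, 1)")
        probs = (
            self.terminal_idr_bias,
            *self.predictor_agreement,
            self.variant_idr_fraction,
            self.disease_fraction,
            self.ppi_missing_rate,
            *self.loc_probs_pros,
            *self.loc_probs_non_pros,
        )
        if any(not (0 <= p <= 1) for p in probs):
            raise ValueError("all probabilities must be in [0, 1]")
        for name in ("loc_probs_pros", "loc_probs_non_pros"):
            t = getattr(self, name)
            if len(t) != 5 or not math.isclose(sum(t), 1.0, abs_tol=1e-9):
                raise ValueError(f"{name} must be 5 probabilities summing to 1")
        if not (1 <= self.n_categories <= len(CATEGORY_CODES)):
            raise ValueError("n_categories must be in 1..15")
        if self.disease_power_exponent <= 1:
            raise ValueError("disease_power_exponent must exceed 1 (Zipf)")
        if self.min_length < 40:
            raise ValueError("min_length must be >= 40 to fit planted segments")
        rates = (self.n_planted_pros, self.decoy_feature_rate, self.variant_rate,
                 self.phospho_rate, self.ppi_noise)
        if any(r < 0 for r in rates):
            raise ValueError("rates must be non-negative")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class GroundTruth:
    """What was planted, for oracle comparisons against pipeline output.

    ``features``: one row per generated feature — accession, feature_id,
    kind (planted / decoy_* / variant / phospho), span, whether it lies in a
    true disordered segment, and ``should_be_called``: whether a noise-free
    default-threshold run must call it.
    """

    features: pd.DataFrame
    disorder: pd.DataFrame  # accession, start, end (true segments)
    location: pd.DataFrame  # accession, group, location_class
    diseases: pd.DataFrame  # accession, n_diseases
    params: GeneratorParams


def _draw_length(rng: np.random.Generator, p: GeneratorParams) -> int:
    raw = rng.lognormal(math.log(p.length_median), p.length_sigma)
    return int(np.clip(round(raw), p.min_length, p.max_length))


def _place_disorder(
    rng: np.random.Generator, length: int, p: GeneratorParams
) -> IntervalSet:
    """Place the protein's true disordered segments."""
    f = rng.beta(
        p.target_disorder_fraction * p.disorder_concentration,
        (1 - p.target_disorder_fraction) * p.disorder_concentration,
    )
    n_dis = min(int(round(f * length)), int(0.8 * length))
    if n_dis < 3:
        return IntervalSet()
    n_seg = 2 if n_dis >= 60 else 1
    seg_lens = [n_dis] if n_seg == 1 else [n_dis // 2, n_dis - n_dis // 2]
    terminals = ["N", "C"]
    rng.shuffle(terminals)
    mid_free = True
    spans: list[tuple[int, int]] = []
    n_used = c_used = 0
    for seg_len in seg_lens:
        zone: str | None = None
        if rng.random() < p.terminal_idr_bias and terminals:
            zone = terminals.pop(0)
        elif mid_free:
            zone = "mid"
        elif terminals:
            zone = terminals.pop(0)
        if zone == "N":
            spans.append((1, seg_len))
            n_used = seg_len
        elif zone == "C":
            spans.append((length - seg_len + 1, length))
            c_used = seg_len
        elif zone == "mid":
            lo = n_used + 2
            hi = length - c_used - seg_len - 1
            if hi < lo:  # no interior room: fall back to a free terminus
                if terminals:
                    zone = terminals.pop(0)
                    if zone == "N":
                        spans.append((1, seg_len))
                        n_used = seg_len
                    else:
                        spans.append((length - seg_len + 1, length))
                        c_used = seg_len
                continue
            start = int(rng.integers(lo, hi + 1))
            spans.append((start, start + seg_len - 1))
            mid_free = False
    return IntervalSet(spans)


def _pick_span_inside(
    rng: np.random.Generator, segments: list[Interval], span_len: int
) -> Optional[tuple[int, int]]:
    """Uniformly pick a host segment that fits, then a position inside it."""
    fitting = [s for s in segments if s.length >= span_len]
    if not fitting:
        return None
    seg = fitting[int(rng.integers(0, len(fitting)))]
    offset = int(rng.integers(0, seg.length - span_len + 1))
    start = seg.start + offset
    return start, start + span_len - 1


def generate_cohort(
    params: GeneratorParams, out_dir: str | Path | None = None
) -> tuple[list[ProteinRecord], GroundTruth]:
    """Build a cohort (and optionally write its five input tables).

    Deterministic in ``params`` (including ``params.seed``); writing to
    ``out_dir`` additionally emits ``ground_truth.tsv``.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    active_categories = CATEGORY_CODES[: p.n_categories]

    # fixed disease catalog: each entry has one category
    catalog_cats = [
        active_categories[int(i)]
        for i in rng.integers(0, len(active_categories), size=p.n_disease_entries)
    ]
    catalog_ids = [f"D{i + 1:04d}" for i in range(p.n_disease_entries)]

    records: list[ProteinRecord] = []
    gt_feat_rows: list[dict] = []
    gt_dis_rows: list[dict] = []
    gt_loc_rows: list[dict] = []
    gt_count_rows: list[dict] = []

    for i in range(p.n_proteins):
        acc = f"SYN{i:05d}"
        length = _draw_length(rng, p)
        disorder = _place_disorder(rng, length, p)
        dis_segments = list(disorder)
        ordered_segments = list(disorder.complement(length))
        true_mask = disorder.to_mask(length)
        for iv in dis_segments:
            gt_dis_rows.append({"accession": acc, "start": iv.start, "end": iv.end})

        # predictor tracks: echo truth per residue with the agreement prob
        tracks: dict[Predictor, DisorderTrack] = {}
        for pred, agreement in zip(Predictor, p.predictor_agreement):
            if agreement >= 1.0:
                mask = true_mask.copy()
            else:
                flip = rng.random(length) >= agreement
                mask = true_mask ^ flip
            if mask.any():
                tracks[pred] = DisorderTrack.from_mask(pred, mask)

        features: list[FeatureAnnotation] = []
        fid = 0

        def add_feature(
            ftype: FeatureType, desc: str, start: int, end: int,
            kind: str, should_be_called: bool,
        ) -> None:
            nonlocal fid
            fid += 1
            feature_id = f"F{fid:03d}"
            features.append(
                FeatureAnnotation(feature_id, ftype, desc, IntervalSet([(start, end)]))
            )
            span = IntervalSet([(start, end)])
            in_idr = span.intersection(disorder).total_length == span.total_length
            gt_feat_rows.append(
                {
                    "accession": acc,
                    "feature_id": feature_id,
                    "kind": kind,
                    "start": start,
                    "end": end,
                    "in_true_idr": in_idr,
                    "should_be_called": should_be_called,
                }
            )

        def partner() -> str:
            return f"PTN{int(rng.integers(1, 500))}"

        # planted true binding segments
        n_planted_called = 0
        for _ in range(int(rng.poisson(p.n_planted_pros))):
            span_len = int(rng.integers(3, 30))
            span = _pick_span_inside(rng, dis_segments, span_len)
            if span is None:
                continue
            kind_idx = int(rng.integers(0, 3))
            if kind_idx == 0:
                ftype = FeatureType.short_sequence_motif
                desc = _MOTIF_TEMPLATES[int(rng.integers(0, len(_MOTIF_TEMPLATES)))]
            elif kind_idx == 1:
                ftype = FeatureType.region_of_interest
                desc = _REGION_TEMPLATES[
                    int(rng.integers(0, len(_REGION_TEMPLATES)))
                ].format(p=partner())
            else:
                ftype = FeatureType.mutagenesis_site
                desc = _MUTAGENESIS_TEMPLATES[
                    int(rng.integers(0, len(_MUTAGENESIS_TEMPLATES)))
                ].format(p=partner())
            add_feature(ftype, desc, span[0], span[1], "planted", True)
            n_planted_called += 1

        # decoys: must never be called under the default thresholds
        for _ in range(int(rng.poisson(p.decoy_feature_rate))):
            choices = ["ordered_keyword", "negated_mutagenesis", "long_feature",
                       "nonbinding_region"]
            kind = choices[int(rng.integers(0, len(choices)))]
            if kind == "ordered_keyword":
                span = _pick_span_inside(rng, ordered_segments, int(rng.integers(3, 30)))
                if span is None:
                    continue
                add_feature(
                    FeatureType.region_of_interest,
                    f"Interaction with {partner()}", span[0], span[1],
                    "decoy_ordered_keyword", False,
                )
            elif kind == "negated_mutagenesis":
                host = dis_segments if dis_segments else ordered_segments
                span = _pick_span_inside(rng, host, int(rng.integers(3, 30)))
                if span is None:
                    continue
                desc = _NEGATED_TEMPLATES[
                    int(rng.integers(0, len(_NEGATED_TEMPLATES)))
                ].format(p=partner())
                add_feature(
                    FeatureType.mutagenesis_site, desc, span[0], span[1],
                    "decoy_negated", False,
                )
            elif kind == "long_feature":
                span = _pick_span_inside(rng, dis_segments, int(rng.integers(31, 46)))
                if span is None:
                    continue
                add_feature(
                    FeatureType.region_of_interest,
                    f"Interaction with {partner()}", span[0], span[1],
                    "decoy_long", False,
                )
            else:
                host = dis_segments if dis_segments else ordered_segments
                span = _pick_span_inside(rng, host, int(rng.integers(3, 30)))
                if span is None:
                    continue
                desc = _NONBINDING_TEMPLATES[
                    int(rng.integers(0, len(_NONBINDING_TEMPLATES)))
                ]
                add_feature(
                    FeatureType.region_of_interest, desc, span[0], span[1],
                    "decoy_nonbinding", False,
                )

        # pass-through classes for the variant / PTM surveys
        idr_positions = np.flatnonzero(true_mask) + 1
        ordered_positions = np.flatnonzero(~true_mask) + 1
        for _ in range(int(rng.poisson(p.variant_rate))):
            in_idr = rng.random() < p.variant_idr_fraction
            pool = idr_positions if (in_idr and idr_positions.size) else ordered_positions
            if pool.size == 0:
                pool = idr_positions
            pos = int(pool[int(rng.integers(0, pool.size))])
            add_feature(
                FeatureType.variant, "Pathogenic missense variant", pos, pos,
                "variant", False,
            )
        for _ in range(int(rng.poisson(p.phospho_rate))):
            pos = int(rng.integers(1, length + 1))
            add_feature(
                FeatureType.modified_residue, "Phosphoserine; by CK2", pos, pos,
                "phospho", False,
            )

        # diseases: truncated power law over the catalog
        diseases: list[DiseaseAssignment] = []
        if rng.random() < p.disease_fraction:
            n_d = int(rng.zipf(p.disease_power_exponent))
            n_d = min(n_d, p.max_diseases, p.n_disease_entries)
            picked = rng.choice(p.n_disease_entries, size=n_d, replace=False)
            for j in sorted(int(x) for x in picked):
                diseases.append(DiseaseAssignment(catalog_ids[j], catalog_cats[j]))
        gt_count_rows.append({"accession": acc, "n_diseases": len(diseases)})

        # localization, drawn from group-specific class probabilities
        group = "pros" if n_planted_called > 0 else "non_pros"
        probs = p.loc_probs_pros if group == "pros" else p.loc_probs_non_pros
        cls = LOC_CLASS_ORDER[int(rng.choice(len(LOC_CLASS_ORDER), p=probs))]
        if cls == "N":
            terms = ["nucleus"]
        elif cls == "C":
            terms = ["cytoplasm"]
        elif cls == "M":
            terms = ["membrane"]
        elif cls == "CN":
            terms = ["cytoplasm", "nucleus"]
        else:
            terms = [_OTHER_TERMS[int(rng.integers(0, len(_OTHER_TERMS)))]]
        gt_loc_rows.append({"accession": acc, "group": group, "location_class": cls})

        # interactor count, linear in distinct diseases plus noise
        if rng.random() < p.ppi_missing_rate:
            interactor: Optional[int] = None
        else:
            n_distinct = len({d.disease_id for d in diseases})
            value = p.ppi_intercept + p.ppi_slope * n_distinct
            if p.ppi_noise > 0:
                value += rng.normal(0.0, p.ppi_noise)
            interactor = max(0, int(round(value)))

        records.append(
            ProteinRecord(
                accession=acc,
                length=length,
                features=features,
                tracks=tracks,
                diseases=diseases,
                location_terms=terms,
                interactor_count=interactor,
            )
        )

    ground_truth = GroundTruth(
        features=pd.DataFrame(
            gt_feat_rows,
            columns=["accession", "feature_id", "kind", "start", "end",
                     "in_true_idr", "should_be_called"],
        ),
        disorder=pd.DataFrame(gt_dis_rows, columns=["accession", "start", "end"]),
        location=pd.DataFrame(gt_loc_rows, columns=["accession", "group", "location_class"]),
        diseases=pd.DataFrame(gt_count_rows, columns=["accession", "n_diseases"]),
        params=p,
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        write_cohort(records, out_dir)
        ground_truth.features.to_csv(out_dir / "ground_truth.tsv", sep="\t", index=False)
    return records, ground_truth
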