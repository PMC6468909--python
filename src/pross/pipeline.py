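"""End-to-end orchestration: read -> select -> consensus -> call -> report.

`analyze_cohort` is the library entry point: it runs every stage on an
in-memory cohort and returns per-protein calls plus all report tables.
`run_pipeline` wraps it with file IO, a run manifest (config snapshot,
input checksums, per-stage row counts, timings), and all-or-nothing output:
tables are staged to a temporary directory and moved into place only when
the whole run succeeded.
"""

from __future__ import annotations

import hashlib
import logging
import os
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .config import ThresholdConfig
from .disease_stats import category_table, rank_by_pros_residues, table1_stats
from .feature_selection import SelectedFeature, select_binding_features
from .idr_consensus import (
    ConsensusIDR,
    aggregate_idr_fraction,
    consensus_intervals,
    empty_consensus,
)
from .localization_enrichment import enrichment, term_tally
from .ppi_disease import (
    UndefinedCorrelationError,
    bin_by_disease_count,
    bin_quartile_table,
    disease_ppi_correlation,
    raw_pair_correlation,
)
from .pros_calling import PProS, call_pros, intersect_features_with_idrs
from .records_io import (
    CANDIDATE_FEATURE_TYPES,
    CATEGORY_CODES,
    FeatureType,
    ProteinRecord,
    read_cohort,
    write_report,
)

logger = logging.getLogger("pross")


@dataclass
class AnalysisResult:
    records: list[ProteinRecord]
    config: ThresholdConfig
    selected: dict[str, list[SelectedFeature]]
    consensus: dict[str, ConsensusIDR]
    pros: dict[str, list[PProS]]
    tables: dict[str, pd.DataFrame]
    counts: dict[str, int] = field(default_factory=dict)


def _pros_calls_table(pros: Mapping[str, Sequence[PProS]]) -> pd.DataFrame:
    rows = []
    for acc in sorted(pros):
        for call in sorted(pros[acc], key=lambda c: c.feature_id):
            for iv in call.intervals:
                rows.append(
                    {
                        "accession": acc,
                        "feature_id": call.feature_id,
                        "feature_type": call.feature_type.value,
                        "start": iv.start,
                        "end": iv.end,
                        "idr_coverage": call.idr_coverage,
                        "selection_reason": call.reason.value,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["accession", "feature_id", "feature_type", "start", "end",
                 "idr_coverage", "selection_reason"],
    )


def _selected_table(selected: Mapping[str, Sequence[SelectedFeature]]) -> pd.DataFrame:
    rows = []
    for acc in sorted(selected):
        for sel in sorted(selected[acc], key=lambda s: s.feature.feature_id):
            for iv in sel.feature.location:
                rows.append(
                    {
                        "accession": acc,
                        "feature_id": sel.feature.feature_id,
                        "feature_type": sel.feature.feature_type.value,
                        "selection_reason": sel.reason.value,
                        "start": iv.start,
                        "end": iv.end,
                        "description": sel.feature.description,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["accession", "feature_id", "feature_type", "selection_reason",
                 "start", "end", "description"],
    )


def _consensus_table(consensus: Mapping[str, ConsensusIDR]) -> pd.DataFrame:
    rows = [
        {"accession": acc, "start": iv.start, "end": iv.end}
        for acc in sorted(consensus)
        for iv in consensus[acc].intervals
    ]
    return pd.DataFrame(rows, columns=["accession", "start", "end"])


def _idr_fraction_rows(
    name: str,
    records: Sequence[ProteinRecord],
    consensus: Mapping[str, ConsensusIDR],
) -> dict | None:
    if not records:
        return None
    summary = aggregate_idr_fraction(
        (consensus[r.accession], r.length) for r in records
    )
    return {
        "set_name": name,
        "n_proteins": summary.n_proteins,
        "residue_weighted_fraction": summary.residue_weighted_fraction,
        "mean_per_protein_fraction": summary.mean_per_protein_fraction,
    }


def _idr_fractions_table(
    records: Sequence[ProteinRecord],
    consensus: Mapping[str, ConsensusIDR],
    pros: Mapping[str, Sequence[PProS]],
) -> pd.DataFrame:
    disease = [r for r in records if r.is_disease_related]
    has_pros = lambda r: bool(pros.get(r.accession))  # noqa: E731
    subsets: list[tuple[str, list[ProteinRecord]]] = [
        ("all_proteins", list(records)),
        ("disease_proteins", disease),
        ("pros_containing", [r for r in disease if has_pros(r)]),
        ("non_pros", [r for r in disease if not has_pros(r)]),
    ]
    for cat in CATEGORY_CODES:
        members = [r for r in disease if cat in r.categories]
        subsets.append((f"category:{cat}:all", members))
        subsets.append((f"category:{cat}:pros", [r for r in members if has_pros(r)]))
        subsets.append((f"category:{cat}:non_pros", [r for r in members if not has_pros(r)]))
    rows = [
        row
        for name, recs in subsets
        if (row := _idr_fraction_rows(name, recs, consensus)) is not None
    ]
    return pd.DataFrame(
        rows,
        columns=["set_name", "n_proteins", "residue_weighted_fraction",
                 "mean_per_protein_fraction"],
    )


def _localization_table(
    records: Sequence[ProteinRecord],
    pros: Mapping[str, Sequence[PProS]],
    config: ThresholdConfig,
) -> pd.DataFrame:
    disease = [r for r in records if r.is_disease_related]
    background = list(records)  # superset background: all proteins
    frames = []
    groups = [("all", disease)] + [
        (cat, [r for r in disease if cat in r.categories]) for cat in CATEGORY_CODES
    ]
    for label, members in groups:
        for group_name, subset in (
            ("pros_containing", [r for r in members if pros.get(r.accession)]),
            ("non_pros", [r for r in members if not pros.get(r.accession)]),
        ):
            if subset:
                frames.append(
                    enrichment(subset, background, config, group=group_name, category=label)
                )
    if not frames:
        return pd.DataFrame(
            columns=["category", "group", "location_class", "group_fraction",
                     "background_fraction", "log_ratio", "flag"]
        )
    return pd.concat(frames, ignore_index=True)


def _ppi_table(records: Sequence[ProteinRecord]) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    bins, excluded = bin_by_disease_count(records)
    rows = []
    for stat in ("mean", "median"):
        for restriction, max_d in (("none", None), ("n_diseases<=9", 9)):
            kept = [b for b in bins if max_d is None or b.n_diseases <= max_d]
            try:
                r = disease_ppi_correlation(bins, stat=stat, max_diseases=max_d)
                flag = ""
            except UndefinedCorrelationError as exc:
                r, flag = float("nan"), str(exc)
            rows.append(
                {"stat": stat, "restriction": restriction, "n_bins": len(kept),
                 "r": r, "flag": flag}
            )
    try:
        raw = raw_pair_correlation(records)
        raw_flag = ""
    except UndefinedCorrelationError as exc:
        raw, raw_flag = float("nan"), str(exc)
    rows.append(
        {"stat": "raw_pairs", "restriction": "none",
         "n_bins": sum(b.n_proteins for b in bins), "r": raw, "flag": raw_flag}
    )
    corr = pd.DataFrame(rows, columns=["stat", "restriction", "n_bins", "r", "flag"])
    return corr, bin_quartile_table(bins), excluded


def _survey_table(
    records: Sequence[ProteinRecord], consensus: Mapping[str, ConsensusIDR]
) -> pd.DataFrame:
    """Disorder-coverage survey of the pass-through feature classes."""
    rows = []
    for ftype in (FeatureType.variant, FeatureType.modified_residue):
        n_total = n_inside = n_proteins_inside = 0
        for rec in records:
            feats = [f for f in rec.features if f.feature_type is ftype]
            if not feats:
                continue
            inside_here = 0
            for _, coverage in intersect_features_with_idrs(feats, consensus[rec.accession]):
                n_total += 1
                if coverage >= 1.0:
                    inside_here += 1
            if inside_here:
                n_proteins_inside += 1
            n_inside += inside_here
        rows.append(
            {
                "feature_type": ftype.value,
                "n_sites": n_total,
                "n_sites_in_idr": n_inside,
                "n_proteins_with_sites_in_idr": n_proteins_inside,
                "fraction_in_idr": (n_inside / n_total) if n_total else 0.0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["feature_type", "n_sites", "n_sites_in_idr",
                 "n_proteins_with_sites_in_idr", "fraction_in_idr"],
    )


def analyze_cohort(
    records: Sequence[ProteinRecord], config: ThresholdConfig | None = None
) -> AnalysisResult:
    """Run every analysis stage on an in-memory cohort."""
    config = config or ThresholdConfig()
    records = sorted(records, key=lambda r: r.accession)

    selected: dict[str, list[SelectedFeature]] = {}
    consensus: dict[str, ConsensusIDR] = {}
    pros: dict[str, list[PProS]] = {}
    for rec in records:
        if rec.tracks:
            consensus[rec.accession] = consensus_intervals(
                list(rec.tracks.values()), rec.length, config
            )
        else:
            consensus[rec.accession] = empty_consensus(rec.length)
        sel = select_binding_features(rec.features, config)
        selected[rec.accession] = sel
        calls = call_pros(rec.accession, sel, consensus[rec.accession], config)
        if calls:
            pros[rec.accession] = calls

    ppi_corr, ppi_bins, ppi_excluded = _ppi_table(records)
    tables = {
        "table1": table1_stats(records, pros, config),
        "table2": category_table(records, pros),
        "table3": rank_by_pros_residues(records, pros),
        "idr_fractions": _idr_fractions_table(records, consensus, pros),
        "localization_enrichment": _localization_table(records, pros, config),
        "location_terms": term_tally(records),
        "ppi_correlation": ppi_corr,
        "ppi_bins": ppi_bins,
        "pros_calls": _pros_calls_table(pros),
        "selected_features": _selected_table(selected),
        "consensus": _consensus_table(consensus),
        "feature_idr_survey": _survey_table(records, consensus),
    }
    counts = {
        "n_proteins": len(records),
        "n_disease_proteins": sum(1 for r in records if r.is_disease_related),
        "n_selected_features": sum(len(v) for v in selected.values()),
        "n_pros_calls": sum(len(v) for v in pros.values()),
        "n_pros_proteins": len(pros),
        "n_ppi_excluded": ppi_excluded,
    }
    logger.info("analysis counts: %s", counts)
    return AnalysisResult(
        records=list(records), config=config, selected=selected,
        consensus=consensus, pros=pros, tables=tables, counts=counts,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    annotation_path: str | Path,
    out_dir: str | Path,
    tracks_path: str | Path | None = None,
    disease_path: str | Path | None = None,
    location_path: str | Path | None = None,
    ppi_path: str | Path | None = None,
    config: ThresholdConfig | None = None,
) -> AnalysisResult:
    """Read a cohort from files, analyze it, and write the report.

    Output is all-or-nothing: the report is staged to a sibling temporary
    directory and renamed into ``out_dir`` only after every table was
    written, so a failed run leaves no partial report behind.
    """
    config = config or ThresholdConfig()
    out_dir = Path(out_dir)
    t0 = time.perf_counter()
    inputs = {
        "features": Path(annotation_path),
        "tracks": Path(tracks_path) if tracks_path else None,
        "diseases": Path(disease_path) if disease_path else None,
        "locations": Path(location_path) if location_path else None,
        "ppi": Path(ppi_path) if ppi_path else None,
    }
    for name, path in inputs.items():
        if path is not None and not path.exists():
            raise FileNotFoundError(f"{name} table not found: {path}")
    records = read_cohort(
        annotation_path, tracks_path, disease_path, location_path, ppi_path
    )
    t_read = time.perf_counter()
    result = analyze_cohort(records, config)
    t_analyze = time.perf_counter()

    # timings go to the log only: the written report must be byte-identical
    # across repeated runs on the same inputs
    logger.info(
        "timings: read %.3fs, analyze %.3fs", t_read - t0, t_analyze - t_read
    )
    manifest = {
        "input_checksums": {
            name: _sha256(path) for name, path in inputs.items() if path is not None
        },
        "row_counts": result.counts,
        "table_rows": {name: int(len(df)) for name, df in sorted(result.tables.items())},
    }
    staging = out_dir.parent / f".{out_dir.name}.staging-{os.getpid()}"
    if staging.exists():
        shutil.rmtree(staging)
    try:
        write_report(result.tables, staging, config, extra_meta={"manifest": manifest})
        if out_dir.exists():
            shutil.rmtree(out_dir)
        staging.rename(out_dir)
    finally:
        if staging.exists():
            shutil.rmtree(staging)
    logger.info("report written to %s", out_dir)
    return result
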