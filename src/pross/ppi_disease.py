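"""Disease multiplicity versus interaction-network degree.

Disease proteins are binned by their number of distinct assigned diseases;
the per-bin mean (or median) interactor count is then correlated with the
bin value by Pearson's r.  The per-bin summary correlation is the primary
statistic (hub proteins with hundreds of partners dominate raw pairs); the
raw per-protein correlation is emitted alongside for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .records_io import ProteinRecord


class UndefinedCorrelationError(ValueError):
    """Fewer than two bins, or zero variance on either axis."""


@dataclass(frozen=True)
class DiseaseBin:
    n_diseases: int
    interactor_counts: tuple[int, ...]

    @property
    def n_proteins(self) -> int:
        return len(self.interactor_counts)


def bin_by_disease_count(
    records: Sequence[ProteinRecord],
) -> tuple[list[DiseaseBin], int]:
    """One bin per observed distinct-disease count.

    Proteins without diseases or without interactor data are excluded; the
    excluded count is returned so callers can log it.
    """
    groups: dict[int, list[int]] = {}
    excluded = 0
    for rec in records:
        n = len(rec.disease_ids)
        if n == 0 or rec.interactor_count is None:
            excluded += 1
            continue
        groups.setdefault(n, []).append(rec.interactor_count)
    bins = [
        DiseaseBin(n, tuple(counts)) for n, counts in sorted(groups.items())
    ]
    return bins, excluded


def _bin_stat(b: DiseaseBin, stat: str) -> float:
    if stat == "mean":
        return float(np.mean(b.interactor_counts))
    if stat == "median":
        return float(np.median(b.interactor_counts))
    raise ValueError(f"stat must be 'mean' or 'median', got {stat!r}")


def disease_ppi_correlation(
    bins: Sequence[DiseaseBin],
    stat: str = "mean",
    max_diseases: int | None = None,
) -> float:
    """Pearson r between bin disease count and the per-bin interactor stat.

    ``max_diseases`` keeps only bins with n_diseases <= max_diseases (the
    "fewer than 10 diseases" restriction is max_diseases=9).  Raises
    :class:`UndefinedCorrelationError` when r is undefined.
    """
    kept = [b for b in bins if max_diseases is None or b.n_diseases <= max_diseases]
    if len(kept) < 2:
        raise UndefinedCorrelationError(
            f"need at least 2 bins, have {len(kept)}"
        )
    x = np.array([b.n_diseases for b in kept], dtype=float)
    y = np.array([_bin_stat(b, stat) for b in kept])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance on one axis")
    return float(sps.pearsonr(x, y).statistic)


def raw_pair_correlation(
    records: Sequence[ProteinRecord], max_diseases: int | None = None
) -> float:
    """Pearson r over raw (n_diseases, interactor_count) protein pairs."""
    pairs = [
        (len(r.disease_ids), r.interactor_count)
        for r in records
        if r.disease_ids and r.interactor_count is not None
        and (max_diseases is None or len(r.disease_ids) <= max_diseases)
    ]
    if len(pairs) < 2:
        raise UndefinedCorrelationError("need at least 2 proteins")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance on one axis")
    return float(sps.pearsonr(x, y).statistic)


def bin_quartile_table(bins: Sequence[DiseaseBin]) -> pd.DataFrame:
    """Per-bin five-number-plus-mean summary (box-plot reproduction data)."""
    rows = []
    for b in bins:
        counts = np.array(b.interactor_counts, dtype=float)
        rows.append(
            {
                "n_diseases": b.n_diseases,
                "n_proteins": b.n_proteins,
                "min": float(counts.min()),
                "q1": float(np.percentile(counts, 25)),
                "median": float(np.median(counts)),
                "q3": float(np.percentile(counts, 75)),
                "max": float(counts.max()),
                "mean": float(counts.mean()),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["n_diseases", "n_proteins", "min", "q1", "median", "q3", "max", "mean"],
    )
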