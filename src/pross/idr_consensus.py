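"""Consensus disorder calling from per-predictor tracks.

Three predictors (MobiDB-lite, DISOPRED3, DICHOT) each supply a per-residue
disorder call.  A residue is consensus-disordered when at least
``min_predictor_votes`` (default 2) of the tracks call it disordered.  A
missing track contributes zero votes everywhere — a protein for which
MobiDB-lite predicts nothing can still reach consensus through the other
two predictors, but a protein with a single available track cannot.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .config import ThresholdConfig
from .intervals import IntervalSet
from .records_io import DisorderTrack


@dataclass(frozen=True)
class ConsensusIDR:
    """Consensus disordered regions plus the per-residue vote count."""

    intervals: IntervalSet
    votes: np.ndarray  # int vector, one entry per residue

    @property
    def n_residues(self) -> int:
        return self.intervals.total_length

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConsensusIDR):
            return NotImplemented
        return self.intervals == other.intervals and np.array_equal(self.votes, other.votes)


def consensus_intervals(
    tracks: Sequence[DisorderTrack], protein_length: int, config: ThresholdConfig
) -> ConsensusIDR:
    """Vote per residue across 1-3 tracks and return the consensus regions.

    Raises if no tracks are supplied or a track extends past the protein.
    """
    if protein_length < 1:
        raise ValueError("protein_length must be positive")
    if not tracks:
        raise ValueError("consensus requires at least one disorder track")
    seen = set()
    votes = np.zeros(protein_length, dtype=np.int8)
    for track in tracks:
        if track.predictor in seen:
            raise ValueError(f"duplicate track for predictor {track.predictor.value}")
        seen.add(track.predictor)
        votes += track.to_mask(protein_length)  # raises on length mismatch
    mask = votes >= config.min_predictor_votes
    return ConsensusIDR(IntervalSet.from_mask(mask), votes.astype(int))


def empty_consensus(protein_length: int) -> ConsensusIDR:
    """Consensus for a protein with no available tracks (zero votes)."""
    return ConsensusIDR(IntervalSet(), np.zeros(protein_length, dtype=int))


def idr_fraction(consensus: ConsensusIDR, protein_length: int) -> float:
    """Fraction of the chain that is consensus-disordered."""
    if protein_length < 1:
        raise ValueError("protein_length must be positive")
    if consensus.intervals.max_end > protein_length:
        raise ValueError("consensus extends beyond protein length")
    return consensus.n_residues / protein_length


@dataclass(frozen=True)
class IdrFractionSummary:
    """Disorder content of a protein subset, two ways.

    ``residue_weighted_fraction`` pools residues (Σ disordered / Σ length);
    ``mean_per_protein_fraction`` averages each protein's own fraction.
    Both are reported because published per-set disorder ratios rarely say
    which convention they use.
    """

    n_proteins: int
    residue_weighted_fraction: float
    mean_per_protein_fraction: float


def aggregate_idr_fraction(
    items: Iterable[tuple[ConsensusIDR, int]]
) -> IdrFractionSummary:
    """Aggregate disorder fraction over (consensus, protein_length) pairs."""
    disordered = 0
    total = 0
    fractions: list[float] = []
    for consensus, length in items:
        fractions.append(idr_fraction(consensus, length))
        disordered += consensus.n_residues
        total += length
    if not fractions:
        raise ValueError("aggregate_idr_fraction requires a non-empty subset")
    return IdrFractionSummary(
        n_proteins=len(fractions),
        residue_weighted_fraction=disordered / total,
        mean_per_protein_fraction=float(np.mean(fractions)),
    )
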