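"""Interval algebra on 1-based inclusive protein coordinates.

UniProt feature locations and disorder-predictor calls are spans of residues,
numbered from 1 and inclusive at both ends ("from 360 to 365" covers six
residues).  :class:`IntervalSet` is the normalized form used everywhere in
this package: sorted, pairwise non-overlapping, with adjacent spans merged,
so that ``total_length`` is always the non-redundant residue count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np


@dataclass(frozen=True, order=True)
class Interval:
    """A contiguous residue span, 1-based and inclusive at both ends."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval ({self.start}, {self.end}): need 1 <= start <= end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def residues(self) -> range:
        """All residue indices covered by the span."""
        return range(self.start, self.end + 1)


class IntervalSet:
    """A normalized set of residue spans.

    Construction normalizes the input: spans are sorted by start, and
    overlapping or adjacent spans (``[1,5]`` and ``[6,9]``) are merged, so
    two IntervalSets covering the same residues compare equal and
    ``total_length`` counts each residue once.
    """

    __slots__ = ("intervals",)

    def __init__(self, intervals: Iterable[Interval | tuple[int, int]] = ()) -> None:
        object.__setattr__(self, "intervals", self._normalize(intervals))

    @staticmethod
    def _normalize(intervals: Iterable[Interval | tuple[int, int]]) -> tuple[Interval, ...]:
        ivs = sorted(
            iv if isinstance(iv, Interval) else Interval(int(iv[0]), int(iv[1]))
            for iv in intervals
        )
        merged: list[Interval] = []
        for iv in ivs:
            if merged and iv.start <= merged[-1].end + 1:
                if iv.end > merged[-1].end:
                    merged[-1] = Interval(merged[-1].start, iv.end)
            else:
                merged.append(iv)
        return tuple(merged)

    # -- container protocol -------------------------------------------------

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __bool__(self) -> bool:
        return bool(self.intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals

    def __hash__(self) -> int:
        return hash(self.intervals)

    def __repr__(self) -> str:
        spans = ", ".join(f"{iv.start}-{iv.end}" for iv in self.intervals)
        return f"IntervalSet([{spans}])"

    # -- measures ------------------------------------------------------------

    @property
    def total_length(self) -> int:
        """Non-redundant residue count of the set."""
        return sum(iv.length for iv in self.intervals)

    @property
    def max_end(self) -> int:
        return self.intervals[-1].end if self.intervals else 0

    @property
    def min_start(self) -> int:
        return self.intervals[0].start if self.intervals else 0

    def residues(self) -> set[int]:
        """Explicit residue-index set (convenience; O(total_length))."""
        out: set[int] = set()
        for iv in self.intervals:
            out.update(iv.residues())
        return out

    # -- set operations -------------------------------------------------------

    @classmethod
    def union(cls, sets: Iterable["IntervalSet"]) -> "IntervalSet":
        return cls(iv for s in sets for iv in s)

    def intersection(self, other: "IntervalSet") -> "IntervalSet":
        """Residues present in both sets (two-pointer sweep)."""
        out: list[tuple[int, int]] = []
        a, b = self.intervals, other.intervals
        i = j = 0
        while i < len(a) and j < len(b):
            lo = max(a[i].start, b[j].start)
            hi = min(a[i].end, b[j].end)
            if lo <= hi:
                out.append((lo, hi))
            if a[i].end < b[j].end:
                i += 1
            else:
                j += 1
        return IntervalSet(out)

    def complement(self, length: int) -> "IntervalSet":
        """Residues 1..length not covered by the set."""
        if length < 1:
            raise ValueError("length must be positive")
        gaps: list[tuple[int, int]] = []
        prev_end = 0
        for iv in self.intervals:
            if iv.start > prev_end + 1:
                gaps.append((prev_end + 1, iv.start - 1))
            prev_end = iv.end
        if prev_end < length:
            gaps.append((prev_end + 1, length))
        return IntervalSet(gaps)

    # -- boolean-mask interconversion (lossless) ------------------------------

    def to_mask(self, length: int) -> np.ndarray:
        """Boolean vector of size ``length``; index 0 is residue 1."""
        if self.max_end > length:
            raise ValueError(
                f"interval set reaches residue {self.max_end} beyond length {length}"
            )
        mask = np.zeros(length, dtype=bool)
        for iv in self.intervals:
            mask[iv.start - 1 : iv.end] = True
        return mask

    @classmethod
    def from_mask(cls, mask: Sequence[bool] | np.ndarray) -> "IntervalSet":
        arr = np.asarray(mask, dtype=bool)
        if arr.ndim != 1:
            raise ValueError("mask must be one-dimensional")
        padded = np.concatenate(([False], arr, [False]))
        diff = np.flatnonzero(padded[1:] != padded[:-1])
        starts, ends = diff[0::2] + 1, diff[1::2]  # 1-based inclusive
        return cls(zip(starts.tolist(), ends.tolist()))
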