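"""Half-open interval arithmetic shared by the coverage-based filters.

Three rules in the pipeline reduce to "what fraction of a sequence do
these alignment segments cover": the human-decontamination filter, the
viral-cluster pair-coverage rule, and the read-mapping presence call.
All coordinates are 0-based half-open; conversion from 1-based formats
happens at the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open interval ``[start, end)``."""

    start: int
    end: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"malformed interval [{self.start}, {self.end}): start must be < end")

    def __len__(self) -> int:
        return self.end - self.start


def merge_intervals(intervals: Iterable[Interval]) -> List[Interval]:
    """Coalesce intervals into a sorted, disjoint, non-adjacent list.

    The union of covered positions is preserved exactly.  Adjacent
    half-open intervals (``[0,100)`` + ``[100,200)``) are merged: they
    share no position but leave no gap, and coverage is a position count.
    """
    ivs = sorted(intervals)
    merged: List[Interval] = []
    for iv in ivs:
        if merged and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = Interval(merged[-1].start, iv.end)
        else:
            merged.append(iv)
    return merged


def covered_fraction(intervals: Iterable[Interval], length: int) -> float:
    """Fraction of ``[0, length)`` covered by the union of *intervals*.

    Intervals are clipped to the sequence bounds; portions outside
    contribute nothing.
    """
    if length <= 0:
        raise ValueError(f"length must be positive, got {length}")
    clipped = []
    for iv in intervals:
        s, e = max(iv.start, 0), min(iv.end, length)
        if s < e:
            clipped.append(Interval(s, e))
    covered = sum(len(iv) for iv in merge_intervals(clipped))
    return covered / length
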