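"""Half-open time intervals ``[start, end)`` and the set operations on them.

All pipeline times are seconds from recording start.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import ValidationError

__all__ = ["Interval", "merge_intervals", "total_duration", "overlap_duration"]


@dataclass(frozen=True, order=True)
class Interval:
    start: float
    end: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"interval requires 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def duration(self) -> float:
        return self.end - self.start

    def intersects(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end

    def overlap(self, other: "Interval") -> float:
        return max(0.0, min(self.end, other.end) - max(self.start, other.start))


def merge_intervals(intervals: Iterable[Interval], gap_close_s: float = 0.0) -> list[Interval]:
    """Union of intervals; additionally bridges gaps strictly below ``gap_close_s``."""
    ivs = sorted(intervals)
    merged: list[Interval] = []
    for iv in ivs:
        if merged and (
            iv.start <= merged[-1].end or iv.start - merged[-1].end < gap_close_s
        ):
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = Interval(last.start, iv.end)
        else:
            merged.append(iv)
    return merged


def total_duration(intervals: Sequence[Interval]) -> float:
    return float(sum(iv.duration for iv in intervals))


def overlap_duration(iv: Interval, mask: Sequence[Interval]) -> float:
    """Total duration of ``iv`` covered by a (not necessarily disjoint) mask."""
    covered = merge_intervals(mask)
    return float(sum(iv.overlap(m) for m in covered))
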