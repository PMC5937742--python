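"""Correlating candidate movements with physician annotations.

A physician call-out lags the movement it reports, so each annotation is
projected onto the candidate timeline as a tolerance window extending 3.5 s
into the past and 1.5 s into the future.  An annotation counts as *detected*
iff its window intersects at least one candidate interval.  Several same-type
call-outs within a 5 s window collapse to a single movement before matching.

A scrambled-timeline null control re-randomizes the candidate start times
(preserving durations and count) to estimate the chance-level detection rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError, ValidationError
from .intervals import Interval, merge_intervals
from .io_formats import Annotation, AnnotationTimeline, MovementType
from .segmentation import CandidateTimeline

__all__ = [
    "MatchingConfig",
    "MatchResult",
    "annotation_window",
    "merge_annotations",
    "match",
    "candidate_to_seen_ratio",
    "scramble_candidates",
    "scramble_control",
]


@dataclass(frozen=True)
class MatchingConfig:
    window_before_s: float = 3.5
    window_after_s: float = 1.5
    merge_window_s: float = 5.0
    exclude_probe_moves: bool = True
    chain_merge: bool = True  # rolling same-type merge; False = anchor at group start

    def __post_init__(self) -> None:
        if min(self.window_before_s, self.window_after_s, self.merge_window_s) < 0:
            raise ConfigurationError("matching windows must be >= 0")


@dataclass
class MatchResult:
    """Per-type detection counts/rates plus matched pairs and the candidate tally."""

    n_observed: dict[MovementType, int]
    n_detected: dict[MovementType, int]
    detection_rate: dict[MovementType, Optional[float]]  # percent; None when unobserved
    matched_pairs: list[tuple[int, Interval]] = field(default_factory=list)
    n_candidates_total: int = 0

    @property
    def total_observed(self) -> int:
        return sum(self.n_observed.values())

    @property
    def total_detected(self) -> int:
        return sum(self.n_detected.values())


def annotation_window(t: float, cfg: MatchingConfig, duration_s: float) -> Interval:
    """Tolerance window [t - before, t + after), clamped to the recording."""
    if not 0 <= t <= duration_s:
        raise ValidationError(
            f"annotation at t={t} outside recording of {duration_s} s"
        )
    start = max(0.0, t - cfg.window_before_s)
    end = min(duration_s, t + cfg.window_after_s)
    if end <= start:  # annotation at the very end with window_after 0
        end = min(duration_s, start + 1e-9)
    return Interval(start, end)


def merge_annotations(
    timeline: AnnotationTimeline, merge_window_s: float, chain: bool = True
) -> AnnotationTimeline:
    """Collapse same-type call-out clusters into single movements.

    Consecutive annotations of the same type whose inter-event gap is below
    ``merge_window_s`` are represented by the first event of the cluster.
    With ``chain=True`` (default) the gap is measured to the previous event
    of the cluster (rolling); with ``chain=False`` to the cluster's first
    event.  Different movement types never merge.
    """
    kept: list[Annotation] = []
    for mtype in MovementType:
        anchor = None  # time the current cluster is measured against
        for a in timeline.of_type(mtype):
            if anchor is None or a.t - anchor >= merge_window_s:
                kept.append(a)
                anchor = a.t
            elif chain:
                anchor = a.t
        # chain=False keeps anchor at the cluster's first event
    return AnnotationTimeline(annotations=kept, probe_moves=list(timeline.probe_moves))


def _filter_probe_moves(
    candidates: CandidateTimeline, probe_moves: Sequence[Interval]
) -> CandidateTimeline:
    if not probe_moves:
        return candidates
    keep = [
        i
        for i, iv in enumerate(candidates.intervals)
        if not any(iv.intersects(p) for p in probe_moves)
    ]
    return CandidateTimeline(
        intervals=[candidates.intervals[i] for i in keep],
        provenance=[candidates.provenance[i] for i in keep],
    )


def match(
    candidates: CandidateTimeline,
    annotations: AnnotationTimeline,
    cfg: MatchingConfig = MatchingConfig(),
    duration_s: Optional[float] = None,
    premerged: bool = False,
) -> MatchResult:
    """Match candidate movements against the annotation timeline.

    Annotations are first cluster-merged (unless ``premerged``).  Candidates
    overlapping probe-move intervals are excluded when
    ``cfg.exclude_probe_moves``.  Each annotation's tolerance window is then
    intersected with the candidate timeline; the per-type detection rate is
    ``100 * detected / observed``, reported as None for unobserved types.
    """
    merged = annotations if premerged else merge_annotations(
        annotations, cfg.merge_window_s, chain=cfg.chain_merge
    )
    if duration_s is None:
        t_max = [a.t for a in merged.annotations] + [
            iv.end for iv in candidates.intervals
        ]
        duration_s = max(t_max) if t_max else 0.0
    cands = (
        _filter_probe_moves(candidates, merged.probe_moves)
        if cfg.exclude_probe_moves
        else candidates
    )
    n_observed = merged.counts()
    n_detected = {m: 0 for m in MovementType}
    pairs: list[tuple[int, Interval]] = []
    for idx, a in enumerate(merged.annotations):
        win = annotation_window(a.t, cfg, duration_s)
        best, best_ov = None, 0.0
        for iv in cands.intervals:
            ov = win.overlap(iv)
            if ov > best_ov:
                best, best_ov = iv, ov
        if best is not None:
            n_detected[a.mtype] += 1
            pairs.append((idx, best))
    rates = {
        m: (100.0 * n_detected[m] / n_observed[m] if n_observed[m] else None)
        for m in MovementType
    }
    return MatchResult(
        n_observed=n_observed,
        n_detected=n_detected,
        detection_rate=rates,
        matched_pairs=pairs,
        n_candidates_total=len(cands),
    )


def candidate_to_seen_ratio(result: MatchResult) -> float:
    """Candidate movements per observed (merged) movement; the false-positive load."""
    if result.total_observed == 0:
        raise ValidationError("candidate_to_seen_ratio undefined: zero observed movements")
    return result.n_candidates_total / result.total_observed


def scramble_candidates(
    candidates: CandidateTimeline,
    duration_s: float,
    seed: int | np.random.Generator,
    merge: bool = True,
) -> CandidateTimeline:
    """Re-randomize candidate start times, preserving count and durations.

    Start times are drawn uniformly in ``[0, duration_s - d]`` per interval.
    Overlaps arising from random placement are merged to restore the
    disjointness invariant (set ``merge=False`` to get the raw intervals as a
    plain list instead).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    durations = candidates.durations
    if any(d > duration_s for d in durations):
        raise ValidationError("candidate longer than the recording duration")
    raw = []
    for d in durations:
        start = rng.uniform(0.0, duration_s - d)
        raw.append(Interval(start, start + d))
    if not merge:
        return sorted(raw)
    return CandidateTimeline(intervals=merge_intervals(raw))


def scramble_control(
    candidates: CandidateTimeline,
    annotations: AnnotationTimeline,
    duration_s: float,
    cfg: MatchingConfig = MatchingConfig(),
    n_reps: int = 100,
    seed: int = 0,
) -> dict[MovementType, dict[str, Optional[float]]]:
    """Scrambled-timeline null control.

    Repeats scramble + match ``n_reps`` times and reports the per-type mean
    and standard deviation of the scrambled detection rate (percent).
    """
    rng = np.random.default_rng(seed)
    merged = merge_annotations(annotations, cfg.merge_window_s, chain=cfg.chain_merge)
    rates: dict[MovementType, list[float]] = {m: [] for m in MovementType}
    for _ in range(n_reps):
        scrambled = scramble_candidates(candidates, duration_s, rng)
        res = match(scrambled, merged, cfg, duration_s=duration_s, premerged=True)
        for m in MovementType:
            if res.detection_rate[m] is not None:
                rates[m].append(res.detection_rate[m])
    out: dict[MovementType, dict[str, Optional[float]]] = {}
    for m in MovementType:
        if rates[m]:
            out[m] = {
                "mean": float(np.mean(rates[m])),
                "std": float(np.std(rates[m])),
                "n_reps": float(len(rates[m])),
            }
        else:
            out[m] = {"mean": None, "std": None, "n_reps": 0.0}
    return out
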