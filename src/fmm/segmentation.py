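"""Six-step segmentation of candidate fetal movements.

The pipeline per acoustic channel is: comb-notch filtering, de-noising,
rectified-envelope averaging, SNR thresholding into per-channel regions of
interest (ROIs), exclusion of intervals of maternal movement detected on the
accelerometer, and finally fusion of all channels into a single timeline of
candidate movements.

The SNR convention throughout: the noise floor is the median of a channel's
envelope (robust to sparse bursts), and a ROI's SNR is its mean in-interval
envelope divided by that floor.  Because both numerator and denominator scale
linearly with the input, segmentation is invariant to amplitude scaling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, ValidationError
from .intervals import Interval, merge_intervals, overlap_duration
from .io_formats import SensorRecording
from .preprocessing import PreprocessConfig, condition, envelope

__all__ = [
    "Interval",
    "ROI",
    "CandidateTimeline",
    "SegmentationConfig",
    "noise_floor",
    "detect_channel_rois",
    "maternal_mask",
    "remove_maternal",
    "fuse_channels",
    "segment_recording",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ROI:
    """A per-channel temporal interval of elevated acoustic activity."""

    channel: int
    interval: Interval
    snr: float
    peak_env: float

    def __post_init__(self) -> None:
        if self.snr < 0:
            raise ValidationError(f"snr must be >= 0, got {self.snr}")


@dataclass
class CandidateTimeline:
    """Fused, disjoint candidate-movement intervals with channel provenance."""

    intervals: list[Interval] = field(default_factory=list)
    provenance: list[tuple[int, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.provenance) not in (0, len(self.intervals)):
            raise ValidationError("provenance length must match intervals")
        if not self.provenance:
            self.provenance = [()] * len(self.intervals)
        order = np.argsort([iv.start for iv in self.intervals])
        self.intervals = [self.intervals[i] for i in order]
        self.provenance = [self.provenance[i] for i in order]
        for a, b in zip(self.intervals, self.intervals[1:]):
            if b.start < a.end:
                raise ValidationError("candidate intervals must be disjoint")

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def durations(self) -> list[float]:
        return [iv.duration for iv in self.intervals]


@dataclass(frozen=True)
class SegmentationConfig:
    snr_threshold: float = 3.0
    min_duration_s: float = 0.1
    gap_close_s: float = 0.5
    maternal_hp_hz: float = 0.5
    maternal_threshold_g: float = 0.1
    maternal_pad_s: float = 0.5
    maternal_overlap_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.snr_threshold <= 1:
            raise ConfigurationError("snr_threshold must be > 1")
        if not 0 < self.maternal_overlap_frac <= 1:
            raise ConfigurationError("maternal_overlap_frac must be in (0, 1]")
        if self.min_duration_s < 0 or self.gap_close_s < 0:
            raise ConfigurationError("durations must be non-negative")


def noise_floor(env: np.ndarray) -> float:
    """Robust baseline level of an envelope: its median.

    The median barely moves when a minority of samples belong to bursts, which
    is exactly the sparse-activity regime of a fetal scan.
    """
    env = np.asarray(env, dtype=float)
    if env.size == 0:
        raise ValidationError("noise_floor of empty envelope")
    return float(np.median(env))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [i, j) runs of True in a boolean vector."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return list(zip(starts, ends))


def detect_channel_rois(
    env: np.ndarray, fs: float, cfg: SegmentationConfig, channel: int = 0
) -> list[ROI]:
    """Threshold one channel's envelope into ROIs.

    Keeps maximal runs with ``env > snr_threshold * noise_floor``, bridges
    gaps shorter than ``gap_close_s``, then discards runs shorter than
    ``min_duration_s``.
    """
    env = np.asarray(env, dtype=float)
    floor = noise_floor(env)
    if floor <= 0:
        warnings.warn(
            f"channel {channel}: degenerate (zero) noise floor, no ROIs detected",
            stacklevel=2,
        )
        return []
    above = env > cfg.snr_threshold * floor
    intervals = [Interval(s / fs, e / fs) for s, e in _runs(above)]
    intervals = merge_intervals(intervals, gap_close_s=cfg.gap_close_s)
    rois = []
    for iv in intervals:
        if iv.duration < cfg.min_duration_s:
            continue
        sl = slice(int(round(iv.start * fs)), int(round(iv.end * fs)))
        seg = env[sl]
        rois.append(
            ROI(
                channel=channel,
                interval=iv,
                snr=float(seg.mean() / floor),
                peak_env=float(seg.max()),
            )
        )
    return rois


def maternal_mask(
    accel: np.ndarray, fs: float, cfg: SegmentationConfig
) -> list[Interval]:
    """Intervals of maternal movement from the tri-axial accelerometer.

    Each axis is high-passed at ``maternal_hp_hz`` (removing the static
    gravity component), the vector magnitude is enveloped, thresholded at
    ``maternal_threshold_g``, and flagged runs are padded by
    ``maternal_pad_s`` on both sides and merged.
    """
    from scipy import signal as sps

    accel = np.atleast_2d(np.asarray(accel, dtype=float))
    if accel.shape[0] != 3:
        raise ValidationError("accel must be a 3 x n matrix")
    if accel.shape[1] < 16:
        return []
    sos = sps.butter(2, cfg.maternal_hp_hz, btype="high", fs=fs, output="sos")
    hp = sps.sosfiltfilt(sos, accel, axis=1)
    mag = np.sqrt((hp**2).sum(axis=0))
    env = envelope(mag, fs, 0.25, rectify=True)
    above = env > cfg.maternal_threshold_g
    duration = accel.shape[1] / fs
    padded = []
    for s, e in _runs(above):
        start = max(0.0, s / fs - cfg.maternal_pad_s)
        end = min(duration, e / fs + cfg.maternal_pad_s)
        if end > start:
            padded.append(Interval(start, end))
    return merge_intervals(padded)


def remove_maternal(
    rois: Sequence[ROI], mask: Sequence[Interval], maternal_overlap_frac: float
) -> list[ROI]:
    """Drop ROIs whose maternal-mask overlap fraction reaches the threshold."""
    if not mask:
        return list(rois)
    kept = []
    for roi in rois:
        frac = overlap_duration(roi.interval, mask) / roi.interval.duration
        if frac < maternal_overlap_frac:
            kept.append(roi)
    return kept


def fuse_channels(
    per_channel_rois: Sequence[Sequence[ROI]], gap_close_s: float
) -> CandidateTimeline:
    """Union of per-channel ROI intervals into one candidate timeline.

    Overlapping intervals — and intervals separated by less than
    ``gap_close_s`` — merge; the fused interval records every channel whose
    ROI intersects it.
    """
    all_rois = [roi for rois in per_channel_rois for roi in rois]
    fused = merge_intervals([r.interval for r in all_rois], gap_close_s=gap_close_s)
    provenance = []
    for iv in fused:
        chans = sorted(
            {r.channel for r in all_rois if r.interval.overlap(iv) > 0
             or (iv.start <= r.interval.start and r.interval.end <= iv.end)}
        )
        provenance.append(tuple(chans))
    return CandidateTimeline(intervals=fused, provenance=provenance)


def segment_recording(
    recording: SensorRecording,
    pre_cfg: PreprocessConfig = PreprocessConfig(),
    seg_cfg: SegmentationConfig = SegmentationConfig(),
    return_rois: bool = False,
):
    """Run the full six-step segmentation on a recording.

    Composition: comb-notch -> de-noise -> rectified envelope ->
    per-channel ROI detection -> maternal-interval removal -> channel fusion.
    Deterministic for fixed input and configuration.

    With ``return_rois=True`` also returns the post-maternal-removal
    per-channel ROI lists (used by the discrimination stage).
    """
    fs = recording.fs
    mask = maternal_mask(recording.accel, fs, seg_cfg)
    per_channel: list[list[ROI]] = []
    for ch in range(recording.n_acoustic):
        x = recording.acoustic[ch]
        if not np.any(x):
            logger.warning("channel %d is all-zero; skipped", ch)
            per_channel.append([])
            continue
        env = envelope(condition(x, fs, pre_cfg), fs, pre_cfg.env_window_s, rectify=True)
        rois = detect_channel_rois(env, fs, seg_cfg, channel=ch)
        per_channel.append(remove_maternal(rois, mask, seg_cfg.maternal_overlap_frac))
    timeline = fuse_channels(per_channel, seg_cfg.gap_close_s)
    if return_rois:
        return timeline, per_channel
    return timeline


def write_candidates(timeline: CandidateTimeline, path) -> None:
    """Serialize a candidate timeline as CSV ``start_s,end_s,channels``.

    The provenance channel list is '|'-joined (1-based indices).
    """
    import pandas as pd

    rows = [
        {
            "start_s": iv.start,
            "end_s": iv.end,
            "channels": "|".join(str(c + 1) for c in prov),
        }
        for iv, prov in zip(timeline.intervals, timeline.provenance)
    ]
    pd.DataFrame(rows, columns=["start_s", "end_s", "channels"]).to_csv(
        path, index=False, float_format="%.12g"
    )


def read_candidates(path) -> CandidateTimeline:
    """Read the candidate CSV dialect back into a timeline."""
    import pandas as pd

    from .errors import FormatError

    df = pd.read_csv(path)
    if df.empty and len(df.columns) == 0:
        return CandidateTimeline()
    if not {"start_s", "end_s"}.issubset(df.columns):
        raise FormatError(f"candidate file needs start_s,end_s; got {list(df.columns)}")
    intervals, provenance = [], []
    for _, row in df.iterrows():
        intervals.append(Interval(float(row["start_s"]), float(row["end_s"])))
        chans = row.get("channels")
        if isinstance(chans, str) and chans:
            provenance.append(tuple(int(c) - 1 for c in chans.split("|")))
        else:
            provenance.append(())
    return CandidateTimeline(intervals=intervals, provenance=provenance)
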