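"""End-to-end scan analysis: segmentation -> matching -> feature extraction.

This is the composition the CLI commands and the reproduction script drive;
each stage is the corresponding module's public operation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .discrimination import (
    LabeledFeatureSet,
    extract_features,
    min_signal_length,
    select_best_roi,
)
from .io_formats import AnnotationTimeline, SensorRecording
from .matching import MatchingConfig, MatchResult, annotation_window, match, merge_annotations
from .preprocessing import PreprocessConfig, condition
from .segmentation import (
    ROI,
    CandidateTimeline,
    SegmentationConfig,
    segment_recording,
)

__all__ = ["ScanAnalysis", "analyze_scan", "matched_feature_set"]

logger = logging.getLogger(__name__)


@dataclass
class ScanAnalysis:
    """Everything one scan yields: candidates, per-channel ROIs, match, features."""

    candidates: CandidateTimeline
    per_channel_rois: list[list[ROI]]
    match_result: MatchResult
    features: Optional[LabeledFeatureSet] = None
    feature_intervals: list[tuple[float, float]] = field(default_factory=list)
    merged_annotations: Optional[AnnotationTimeline] = None
    skipped_short_rois: int = 0


def matched_feature_set(
    recording: SensorRecording,
    merged: AnnotationTimeline,
    match_result: MatchResult,
    per_channel_rois: list[list[ROI]],
    pre_cfg: PreprocessConfig,
    match_cfg: MatchingConfig,
) -> tuple[LabeledFeatureSet, list[tuple[float, float]], int]:
    """Feature vectors for every detected annotation.

    For each matched annotation, the overlapping per-channel ROIs are ranked
    by SNR, the best one is excised from the *non-rectified* conditioned
    signal of its channel, and the 12-component feature vector is computed.
    ROIs shorter than the wavelet support are skipped (counted, logged).
    """
    fs = recording.fs
    conditioned = np.vstack(
        [condition(recording.acoustic[c], fs, pre_cfg)
         for c in range(recording.n_acoustic)]
    )
    need = min_signal_length(fs)
    rows, labels, ivs, skipped = [], [], [], 0
    detected = {idx for idx, _ in match_result.matched_pairs}
    for idx, ann in enumerate(merged.annotations):
        if idx not in detected:
            continue
        win = annotation_window(ann.t, match_cfg, recording.duration_s)
        overlapping = [
            roi
            for rois in per_channel_rois
            for roi in rois
            if roi.interval.intersects(win)
        ]
        if not overlapping:
            continue
        best = select_best_roi(overlapping)
        i0 = int(round(best.interval.start * fs))
        i1 = int(round(best.interval.end * fs))
        seg = conditioned[best.channel, i0:i1]
        if seg.size < need:
            skipped += 1
            continue
        rows.append(extract_features(seg, fs).to_array())
        labels.append(ann.mtype)
        ivs.append((best.interval.start, best.interval.end))
    if skipped:
        logger.warning("%d matched ROIs too short for feature extraction", skipped)
    X = np.array(rows) if rows else np.empty((0, 12))
    fset = LabeledFeatureSet(
        X=X, labels=labels, subject_ids=[recording.subject_id] * len(labels)
    )
    return fset, ivs, skipped


def analyze_scan(
    recording: SensorRecording,
    annotations: AnnotationTimeline,
    pre_cfg: PreprocessConfig = PreprocessConfig(),
    seg_cfg: SegmentationConfig = SegmentationConfig(),
    match_cfg: MatchingConfig = MatchingConfig(),
    with_features: bool = True,
) -> ScanAnalysis:
    """Segment a recording, match against annotations, extract matched features."""
    candidates, per_channel = segment_recording(
        recording, pre_cfg, seg_cfg, return_rois=True
    )
    merged = merge_annotations(
        annotations, match_cfg.merge_window_s, chain=match_cfg.chain_merge
    )
    result = match(
        candidates, merged, match_cfg, duration_s=recording.duration_s, premerged=True
    )
    features = None
    ivs: list[tuple[float, float]] = []
    skipped = 0
    if with_features:
        features, ivs, skipped = matched_feature_set(
            recording, merged, result, per_channel, pre_cfg, match_cfg
        )
    return ScanAnalysis(
        candidates=candidates,
        per_channel_rois=per_channel,
        match_result=result,
        features=features,
        feature_intervals=ivs,
        merged_annotations=merged,
        skipped_short_rois=skipped,
    )
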