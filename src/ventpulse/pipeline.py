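"""End-to-end helpers: cohort -> segmented, annotated, model-ready breaths."""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from .annotate import annotate_recording
from .classifier import TrainConfig, preprocess_breath
from .dataio import BreathSegment
from .segment import SegmentationParams, segment_breaths
from .simulate import CohortEntry

__all__ = ["BreathDataset", "build_dataset", "truth_segments"]


@dataclass
class BreathDataset:
    """Model-ready breaths pooled across a cohort."""

    X: np.ndarray  # (n, 2, segment_len)
    y: np.ndarray  # annotated weak labels (bool)
    patient_id: np.ndarray
    ttot: np.ndarray  # s, per breath
    ptp_min: np.ndarray  # cmH2O*s/min, annotated
    weak_true: np.ndarray  # simulator ground truth for matched breaths
    matched: np.ndarray  # bool, truth match found

    def __len__(self) -> int:
        return len(self.y)


def truth_segments(entry: CohortEntry) -> List[BreathSegment]:
    """Ground-truth boundaries of a simulated recording as BreathSegments."""
    tr = entry.truth
    fs = entry.recording.fs
    return [
        BreathSegment.from_indices(o, i, e, fs)
        for o, i, e in zip(tr.onset_idx, tr.insp_end_idx, tr.breath_end_idx)
    ]


def build_dataset(
    entries: Sequence[CohortEntry],
    cfg: TrainConfig = TrainConfig(),
    seg_params: SegmentationParams = SegmentationParams(),
    use_truth_segments: bool = False,
    weak_threshold: float = 50.0,
    match_tol: float = 0.5,
) -> BreathDataset:
    """Segment, annotate and preprocess every recording of a cohort.

    Labels are the annotation stage's weak labels (as in the clinical
    pipeline, where Pes-derived PTP is the training reference); the
    simulator's own labels are carried alongside for matched breaths.
    """
    xs, ys, pids, ttots, ptps, wtrue, matched = [], [], [], [], [], [], []
    for entry in entries:
        rec = entry.recording
        segs = (
            truth_segments(entry)
            if use_truth_segments
            else segment_breaths(rec, seg_params)
        )
        annotated = annotate_recording(
            rec,
            segs,
            entry.profile,
            ecw=entry.mechanics.ecw,
            rcw=entry.mechanics.rcw,
            weak_threshold=weak_threshold,
        )
        truth_onsets = entry.truth.onset_idx / rec.fs
        for ab in annotated:
            xs.append(preprocess_breath(rec, ab.segment, cfg))
            ys.append(ab.weak)
            pids.append(rec.patient_id)
            ttots.append(ab.segment.ttot)
            ptps.append(ab.ptp_min)
            onset_t = ab.segment.onset_idx / rec.fs
            if truth_onsets.size:
                j = int(np.argmin(np.abs(truth_onsets - onset_t)))
                hit = abs(truth_onsets[j] - onset_t) <= match_tol
            else:
                hit = False
            wtrue.append(bool(entry.truth.weak_true[j]) if hit else False)
            matched.append(hit)
    return BreathDataset(
        X=np.stack(xs) if xs else np.empty((0, 2, cfg.segment_len), dtype=np.float32),
        y=np.asarray(ys, dtype=bool),
        patient_id=np.asarray(pids),
        ttot=np.asarray(ttots),
        ptp_min=np.asarray(ptps),
        weak_true=np.asarray(wtrue, dtype=bool),
        matched=np.asarray(matched, dtype=bool),
    )
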