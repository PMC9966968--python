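"""Breath segmentation from airway pressure and flow.

The start of each mechanical inspiration is placed where the rapid decline
of Paw begins at triggering; the end of inspiration is the point where flow
crosses from positive to negative. Onset candidates come from a Haar-style
multiscale (wavelet-detail) analysis of Paw: a negative detail deflection
exceeding a robust-SD threshold marks the trigger dip. Because a weak
effort's trigger dip can be small relative to pressure noise while the
subsequent pressure-support upstroke never is, a second Paw-only pass walks
backward from any large positive deflection that lacks a preceding
candidate, through the dip, to the local start of the decline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import uniform_filter1d

from .dataio import BreathSegment, Recording

__all__ = [
    "SegmentationParams",
    "detect_onsets",
    "detect_insp_end",
    "segment_breaths",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the Paw-based onset detector and Ti gating."""

    scales: Tuple[int, ...] = (4, 8, 16)  # Haar detail half-widths, samples at 100 Hz
    threshold: float = 2.5  # in robust-SD units of the detail coefficients
    refractory: float = 0.4  # s, minimum spacing between onsets
    min_ti: float = 0.2  # s
    max_ti: float = 3.0  # s
    smooth_ms: float = 30.0  # Paw pre-smoothing window
    slope_tol: float = 3.0  # cmH2O/s, decline-start criterion
    rescue: bool = True  # upstroke-anchored recovery of missed dips

    def __post_init__(self) -> None:
        if not self.refractory > 0:
            raise ValueError("refractory must be positive")
        if not (0 < self.min_ti < self.max_ti):
            raise ValueError("require 0 < min_ti < max_ti")


def _haar_detail(x: np.ndarray, scale: int) -> np.ndarray:
    """Right-minus-left boxcar mean difference at the given half-width.

    d[i] = mean(x[i:i+s]) - mean(x[i-s:i]); a negative value marks a local
    downward step of Paw at sample i. Edges are zero-padded.
    """
    n = x.size
    c = np.concatenate(([0.0], np.cumsum(x)))
    d = np.zeros(n)
    lo, hi = scale, n - scale
    if hi > lo:
        idx = np.arange(lo, hi)
        right = (c[idx + scale] - c[idx]) / scale
        left = (c[idx] - c[idx - scale]) / scale
        d[lo:hi] = right - left
    return d


def _robust_sd(x: np.ndarray) -> float:
    mad = np.median(np.abs(x - np.median(x)))
    return float(1.4826 * mad) or 1e-12


def _decline_start(paw_s: np.ndarray, j: int, fs: float, slope_tol: float) -> int:
    """Walk backward from j to the last sample before the Paw decline began."""
    w = max(2, int(round(0.03 * fs)))
    thresh = slope_tol / fs  # per-sample decline
    i = j
    while i - w > 0 and (paw_s[i - w] - paw_s[i]) / w > thresh:
        i -= 1
    return i


def detect_onsets(
    paw: np.ndarray,
    flow: np.ndarray,
    fs: float,
    params: SegmentationParams = SegmentationParams(),
) -> List[int]:
    """Detect breath onsets (start of the triggering Paw decline).

    Returns a sorted, strictly increasing list of sample indices; an
    all-constant Paw yields an empty list.
    """
    paw = np.asarray(paw, dtype=float)
    flow = np.asarray(flow, dtype=float)
    n = paw.size
    smooth = max(1, int(round(params.smooth_ms / 1000.0 * fs)))
    paw_s = uniform_filter1d(paw, smooth, mode="nearest")

    # scale set declared at 100 Hz; adapt to the actual sampling rate
    scales = [max(2, int(round(s * fs / 100.0))) for s in params.scales]
    neg_score = np.zeros(n)
    pos_score = np.zeros(n)
    for s in scales:
        d = _haar_detail(paw_s, s)
        sd = _robust_sd(d)
        neg_score = np.maximum(neg_score, -d / sd)
        pos_score = np.maximum(pos_score, d / sd)

    refr = int(round(params.refractory * fs))

    def _events(score: np.ndarray) -> List[int]:
        above = score > params.threshold
        events = []
        i = 0
        while i < n:
            if above[i]:
                j = i
                while j + 1 < n and above[j + 1]:
                    j += 1
                events.append(i + int(np.argmax(score[i : j + 1])))
                i = j + 1
            else:
                i += 1
        return events

    anchors = _events(neg_score)

    if params.rescue:
        for u in _events(pos_score):
            if any(u - refr <= a <= u for a in anchors):
                continue
            # anchor at the Paw minimum just before the upstroke (the
            # trigger dip preceding pressurization)
            lo = max(0, u - int(round(0.35 * fs)))
            if u > lo:
                anchors.append(lo + int(np.argmin(paw_s[lo : u + 1])))

    # Refine each anchor to the start of the triggering decline. The
    # inspiratory flow rise starts the dip, so the upward flow zero
    # crossing localizes it; anchors without one nearby are declines of a
    # different origin (cycling-off) and are discarded. Falls back to a
    # Paw slope walk-back when flow never goes nonpositive in the window.
    candidates = []  # (index, anchored_on_flow_crossing)
    back, fwd = int(round(0.30 * fs)), int(round(0.35 * fs))
    for a in sorted(set(anchors)):
        lo, hi = max(0, a - back), min(n - 1, a + fwd)
        w = flow[lo : hi + 1]
        cross = np.nonzero((w[:-1] <= 0) & (w[1:] > 0))[0]
        if cross.size:
            candidates.append((lo + int(cross[-1]) + 1, True))
        elif w.size and np.max(np.abs(w)) < 0.05:
            # flow channel flat/uninformative: fall back to the Paw slope
            candidates.append((_decline_start(paw_s, a, fs, params.slope_tol), False))
        # otherwise: a Paw decline inside or at the end of inspiration
        # (cycling-off), not a trigger

    # merge candidates closer than the refractory period; a candidate backed
    # by an inspiratory-flow start outranks a slope-only one, otherwise the
    # earlier wins
    merged: List[Tuple[int, bool]] = []
    for c, crossed in sorted(set(candidates)):
        if merged and c - merged[-1][0] < refr:
            if crossed and not merged[-1][1]:
                merged[-1] = (c, crossed)
            continue
        merged.append((c, crossed))
    return [c for c, _ in merged]


def detect_insp_end(
    flow: np.ndarray,
    onset_idx: int,
    fs: float,
    params: SegmentationParams = SegmentationParams(),
    search_end: Optional[int] = None,
) -> Optional[int]:
    """End of mechanical inspiration after ``onset_idx``.

    Returns the sample index of the first positive-to-nonpositive flow
    crossing (sub-sample linear interpolation, rounded to the nearest
    sample), or None when flow never cycles before ``search_end``.
    """
    flow = np.asarray(flow, dtype=float)
    n = flow.size if search_end is None else min(search_end, flow.size)
    i = onset_idx
    while i < n and flow[i] <= 0:
        i += 1
    while i + 1 < n:
        if flow[i] > 0 and flow[i + 1] <= 0:
            frac = flow[i] / (flow[i] - flow[i + 1])
            return int(round(i + frac))
        i += 1
    return None


def segment_breaths(
    rec: Recording,
    params: SegmentationParams = SegmentationParams(),
    exclusion_mask: Optional[Sequence[Tuple[float, float]]] = None,
) -> List[BreathSegment]:
    """Segment a recording into breaths; the last partial breath is dropped.

    Breaths overlapping an interval of ``exclusion_mask`` (seconds) are kept
    but flagged invalid with reason "artifact"; breaths without a flow
    cycling point get reason "no_cycle"; Ti outside [min_ti, max_ti] gives
    reason "ti_out_of_range".
    """
    onsets = detect_onsets(rec.paw, rec.flow, rec.fs, params)
    segments: List[BreathSegment] = []
    for k in range(len(onsets) - 1):
        onset, nxt = onsets[k], onsets[k + 1]
        insp_end = detect_insp_end(rec.flow, onset, rec.fs, params, search_end=nxt)
        valid, reason = True, None
        if insp_end is None:
            valid, reason = False, "no_cycle"
            insp_end = nxt
        else:
            ti = (insp_end - onset) / rec.fs
            if not (params.min_ti <= ti <= params.max_ti):
                valid, reason = False, "ti_out_of_range"
        if exclusion_mask:
            t0, t1 = onset / rec.fs, nxt / rec.fs
            for m0, m1 in exclusion_mask:
                if t0 < m1 and m0 < t1:
                    valid, reason = False, "artifact"
                    break
        segments.append(
            BreathSegment.from_indices(
                onset, insp_end, nxt, rec.fs, valid=valid, exclusion_reason=reason
            )
        )
    return segments
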