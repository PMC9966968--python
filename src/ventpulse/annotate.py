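"""Pmus reconstruction, pressure-time product (PTP) and weak-effort labels.

The respiratory-muscle pressure is reconstructed from esophageal pressure
via the chest-wall equation of motion (Campbell-type reconstruction):

    Pmus(t) = Ecw * V(t) + Rcw * Flow(t) + Pes_endexp - Pes(t)

with V(t) the running integral of flow re-zeroed at each breath onset.
Chest-wall elastance Ecw is derived from predicted vital capacity (VC),
itself computed from sex, age and height. PTP per breath is the integral
of Pmus over the mechanical inspiration; PTP per minute multiplies it by
the breath's own instantaneous respiratory rate (60/Ttot). Breaths with
PTP/min below 50 cmH2O*s/min are labeled weak.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .dataio import AnnotatedBreath, BreathSegment, PatientProfile, Recording

__all__ = [
    "ElastanceModel",
    "ValidationReport",
    "predicted_vc",
    "chest_wall_elastance",
    "compute_volume",
    "compute_pmus",
    "compute_ptp",
    "label_weak",
    "annotate_recording",
    "annotation_table",
    "validate_annotations",
]


@dataclass(frozen=True)
class ElastanceModel:
    """Predicted vital capacity (mL) and the chest-wall elastance it implies."""

    vc_pred: float
    ecw: float

    def __post_init__(self) -> None:
        if not (self.vc_pred > 0 and self.ecw > 0):
            raise ValueError("vc_pred and ecw must be positive")


@dataclass
class ValidationReport:
    """Three-level agreement between computed and reference annotations."""

    pct_segments_correct: float
    median_abs_ptp_diff: float
    iqr_abs_ptp_diff: Tuple[float, float]
    pct_label_agreement: float
    n_matched: int = 0

    def __post_init__(self) -> None:
        for pct in (self.pct_segments_correct, self.pct_label_agreement):
            if not (0.0 <= pct <= 100.0):
                raise ValueError("percentages must lie in [0, 100]")


def predicted_vc(sex: str, age: float, height: float) -> float:
    """Predicted vital capacity in mL from sex, age (years), height (cm).

    VC = (27.63 - 0.112*age) * height for males,
    VC = (21.78 - 0.101*age) * height for females.
    """
    if not (age > 0 and height > 0):
        raise ValueError("age and height must be positive")
    if sex == "male":
        coeff = 27.63 - 0.112 * age
    elif sex == "female":
        coeff = 21.78 - 0.101 * age
    else:
        raise ValueError("sex must be 'male' or 'female'")
    if coeff <= 0:
        raise ValueError(f"age {age} outside the validity range of the VC equation")
    return coeff * height


def chest_wall_elastance(vc_pred: float, mode: str = "compliance_4pct_vc") -> float:
    """Chest-wall elastance (cmH2O/L) from predicted VC (mL).

    Default mode takes chest-wall compliance as 4% of predicted VC per
    cmH2O, i.e. Ecw = 1 / (0.04 * VC_L), giving physiologic values around
    7 cmH2O/L. Mode ``"literal"`` applies Ecw = 0.025 * VC with VC in L.
    """
    if not vc_pred > 0:
        raise ValueError("vc_pred must be positive")
    vc_l = vc_pred / 1000.0
    if mode == "compliance_4pct_vc":
        return 1.0 / (0.04 * vc_l)
    if mode == "literal":
        return 0.025 * vc_pred
    raise ValueError(f"unknown ecw mode {mode!r}")


def elastance_model(profile: PatientProfile, mode: str = "compliance_4pct_vc") -> ElastanceModel:
    vc = predicted_vc(profile.sex, profile.age, profile.height)
    return ElastanceModel(vc_pred=vc, ecw=chest_wall_elastance(vc, mode))


def compute_volume(flow_segment: np.ndarray, fs: float) -> np.ndarray:
    """Cumulative trapezoidal integral of flow (L), zero at the first sample."""
    return cumulative_trapezoid(np.asarray(flow_segment, dtype=float), dx=1.0 / fs, initial=0.0)


def compute_pmus(
    rec: Recording,
    seg: BreathSegment,
    profile: PatientProfile,
    ecw: float,
    rcw: float = 1.5,
) -> np.ndarray:
    """Reconstruct Pmus (cmH2O) over [onset, breath_end).

    Applies Pmus = Ecw*V(t) + Rcw*Flow(t) + Pes_endexp - Pes(t) with V(t)
    integrated from the breath onset (at end-inspiration this recovers the
    VT*Ecw product of the static formulation).
    """
    if not seg.valid:
        raise ValueError("invalid_segment")
    s, e = seg.onset_idx, seg.breath_end_idx
    flow = rec.flow[s:e]
    vol = compute_volume(flow, rec.fs)
    return ecw * vol + rcw * flow + profile.pes_endexp - rec.pes[s:e]


def compute_ptp(
    pmus: np.ndarray, seg: BreathSegment, fs: float
) -> Tuple[float, float]:
    """(PTP per breath, PTP per minute) from a Pmus series over the breath.

    PTP/breath integrates the signed Pmus over [onset, insp_end]; PTP/min
    multiplies by the breath's own rate 60/Ttot.
    """
    n_insp = seg.insp_end_idx - seg.onset_idx
    ptp_breath = float(np.trapezoid(pmus[: n_insp + 1], dx=1.0 / fs))
    ptp_min = ptp_breath * 60.0 / seg.ttot
    return ptp_breath, ptp_min


def label_weak(ptp_min: float, threshold: float = 50.0) -> bool:
    """True iff PTP/min is strictly below the weak-effort threshold."""
    if not np.isfinite(ptp_min):
        raise ValueError("ptp_min must be finite")
    return bool(ptp_min < threshold)


def annotate_recording(
    rec: Recording,
    segments: Sequence[BreathSegment],
    profile: PatientProfile,
    ecw: Optional[float] = None,
    rcw: float = 1.5,
    weak_threshold: float = 50.0,
    ecw_mode: str = "compliance_4pct_vc",
) -> List[AnnotatedBreath]:
    """Annotate every valid segment of a recording; invalid ones are skipped."""
    if ecw is None:
        ecw = elastance_model(profile, ecw_mode).ecw
    out: List[AnnotatedBreath] = []
    for seg in segments:
        if not seg.valid:
            continue
        pmus = compute_pmus(rec, seg, profile, ecw, rcw)
        vol = compute_volume(rec.flow[seg.onset_idx : seg.breath_end_idx], rec.fs)
        vt = float(vol[seg.insp_end_idx - seg.onset_idx])
        ptp_breath, ptp_min = compute_ptp(pmus, seg, rec.fs)
        out.append(
            AnnotatedBreath(
                segment=seg,
                pmus=pmus,
                vt=vt,
                ptp_breath=ptp_breath,
                ptp_min=ptp_min,
                weak=label_weak(ptp_min, weak_threshold),
            )
        )
    return out


def annotation_table(
    rec: Recording, annotated: Sequence[AnnotatedBreath]
) -> pd.DataFrame:
    """Flatten annotations into a breath table (one row per breath)."""
    return pd.DataFrame(
        {
            "patient_id": rec.patient_id,
            "support_level": rec.support_level,
            "breath_idx": np.arange(len(annotated)),
            "onset_t": [a.segment.onset_idx / rec.fs for a in annotated],
            "insp_end_t": [a.segment.insp_end_idx / rec.fs for a in annotated],
            "breath_end_t": [a.segment.breath_end_idx / rec.fs for a in annotated],
            "ti": [a.segment.ti for a in annotated],
            "ttot": [a.segment.ttot for a in annotated],
            "vt": [a.vt for a in annotated],
            "ptp_breath": [a.ptp_breath for a in annotated],
            "ptp_min": [a.ptp_min for a in annotated],
            "weak": [a.weak for a in annotated],
        }
    )


def _match_by_onset(
    onset_a: np.ndarray, onset_b: np.ndarray, tol: float
) -> List[Tuple[int, int]]:
    """Greedy one-to-one nearest matching of breath onsets within ``tol`` s."""
    pairs = []
    used = set()
    for i, ta in enumerate(onset_a):
        if len(onset_b) == 0:
            break
        j = int(np.argmin(np.abs(onset_b - ta)))
        if j not in used and abs(onset_b[j] - ta) <= tol:
            used.add(j)
            pairs.append((i, j))
    return pairs


def validate_annotations(
    annotated: pd.DataFrame,
    reference: pd.DataFrame,
    boundary_tol: float = 0.05,
    sample_size: int = 8,
    seed: int = 0,
    match_tol: float = 1.0,
) -> ValidationReport:
    """Three-level validation of a computed breath table against a reference.

    Both tables need columns patient_id, support_level (reference may omit
    it), onset_t, insp_end_t, ptp_min, weak. Levels: (i) % of reference
    breaths whose onset and inspiration end are matched within
    ``boundary_tol`` s; (ii) per support level, the absolute difference of
    ``sample_size``-breath median PTP/min (seeded random sample),
    summarized as median and IQR across levels; (iii) % weak-label
    agreement over matched breaths.
    """
    rng = np.random.default_rng(seed)
    seg_total = 0
    seg_correct = 0
    label_total = 0
    label_agree = 0
    level_diffs = []
    matched_total = 0
    common = sorted(set(annotated.patient_id) & set(reference.patient_id))
    if not common:
        raise ValueError("no overlapping patient keys between tables")
    for pid in common:
        sub_a = annotated[annotated.patient_id == pid]
        sub_r = reference[reference.patient_id == pid]
        levels = (
            sorted(sub_a.support_level.unique())
            if "support_level" in sub_a.columns
            else [None]
        )
        for level in levels:
            a = sub_a if level is None else sub_a[sub_a.support_level == level]
            if "support_level" in sub_r.columns and level is not None:
                r = sub_r[sub_r.support_level == level]
            else:
                r = sub_r
            if len(r) == 0:
                continue
            pairs = _match_by_onset(
                r.onset_t.to_numpy(), a.onset_t.to_numpy(), match_tol
            )
            seg_total += len(r)
            matched_total += len(pairs)
            ptp_a, ptp_r = [], []
            for ir, ia in pairs:
                row_r = r.iloc[ir]
                row_a = a.iloc[ia]
                if (
                    abs(row_a.onset_t - row_r.onset_t) <= boundary_tol
                    and abs(row_a.insp_end_t - row_r.insp_end_t) <= boundary_tol
                ):
                    seg_correct += 1
                label_total += 1
                label_agree += int(bool(row_a.weak) == bool(row_r.weak))
                ptp_a.append(row_a.ptp_min)
                ptp_r.append(row_r.ptp_min)
            if len(ptp_a) >= 1:
                k = min(sample_size, len(ptp_a))
                idx = rng.choice(len(ptp_a), size=k, replace=False)
                med_a = float(np.median(np.asarray(ptp_a)[idx]))
                med_r = float(np.median(np.asarray(ptp_r)[idx]))
                level_diffs.append(abs(med_a - med_r))
    if label_total == 0:
        raise ValueError("no matched breaths between tables")
    diffs = np.asarray(level_diffs)
    return ValidationReport(
        pct_segments_correct=100.0 * seg_correct / seg_total,
        median_abs_ptp_diff=float(np.median(diffs)),
        iqr_abs_ptp_diff=(
            float(np.percentile(diffs, 25)),
            float(np.percentile(diffs, 75)),
        ),
        pct_label_agreement=100.0 * label_agree / label_total,
        n_matched=matched_total,
    )
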