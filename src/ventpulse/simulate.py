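"""Patient-ventilator simulator for pressure support ventilation (PSV).

A single-compartment linear respiratory system,

    Paw(t) + Pmus(t) - PEEP - PEEPi = Ers * V(t) + Rrs * V'(t),

is driven by a parametric respiratory-muscle pressure (Pmus) profile through
a ventilator finite-state machine (exhalation -> flow trigger -> trigger
delay -> exponential pressurization to PEEP+PS -> cycling off at a fraction
of peak inspiratory flow). Esophageal pressure is synthesized by inverting
the chest-wall equation of motion,

    Pes(t) = Pes_endexp + Ecw * V(t) + Rcw * Flow(t) - Pmus(t),

so the true Pmus is recoverable exactly from the synthesized channels.
Ground truth (true Pmus, breath boundaries, per-breath pressure-time
products and weak labels) is returned alongside each recording.

Volume is advanced with a semi-implicit trapezoid rule so that the
integrator state coincides, to floating-point round-off, with the
trapezoidal cumulative integral of the recorded flow that the annotation
stage recomputes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .annotate import chest_wall_elastance, predicted_vc
from .dataio import PatientProfile, Recording

__all__ = [
    "MechanicsParams",
    "VentParams",
    "EffortParams",
    "GroundTruth",
    "CohortEntry",
    "pmus_profile",
    "simulate_psv",
    "generate_cohort",
]


@dataclass(frozen=True)
class MechanicsParams:
    """Single-compartment respiratory mechanics (cmH2O, L, s)."""

    ers: float  # respiratory-system elastance, cmH2O/L
    rrs: float  # respiratory-system resistance, cmH2O/(L/s)
    ecw: float  # chest-wall elastance, cmH2O/L
    rcw: float = 1.5  # chest-wall resistance, cmH2O/(L/s)
    peep_i: float = 0.0  # intrinsic PEEP, cmH2O

    def __post_init__(self) -> None:
        if not (self.ers > 0 and self.rrs > 0 and self.ecw > 0):
            raise ValueError("ers, rrs, ecw must be positive")
        if self.peep_i < 0:
            raise ValueError("peep_i must be >= 0")
        if self.ecw >= self.ers:
            import warnings

            warnings.warn("ecw >= ers is physiologically implausible", stacklevel=2)


@dataclass(frozen=True)
class VentParams:
    """Ventilator settings and trigger/cycling behaviour."""

    ps: float  # pressure support above PEEP, cmH2O
    peep: float  # set PEEP, cmH2O
    trigger_flow_threshold: float = 0.03  # L/s
    trigger_delay: float = 0.09  # s
    rise_time_constant: float = 0.05  # s, pressurization time constant
    cycle_fraction: float = 0.25  # fraction of peak inspiratory flow
    exp_time_constant: float = 0.04  # s, expiratory valve relaxation
    demand_resistance: float = 4.0  # cmH2O/(L/s), PEEP-valve imperfection

    def __post_init__(self) -> None:
        if self.ps < 0:
            raise ValueError("ps must be >= 0")
        if not (0 < self.cycle_fraction < 1):
            raise ValueError("cycle_fraction must be in (0, 1)")
        if self.trigger_delay < 0:
            raise ValueError("trigger_delay must be >= 0")


@dataclass(frozen=True)
class EffortParams:
    """Parametric inspiratory-effort template and neural timing.

    Each neural breath follows a quadratic rise to ``pmax`` over ``t_rise``
    and a quadratic release over ``t_release``; breath-to-breath lognormal
    jitter is applied to the amplitude (``pmax_cv``) and timing
    (``timing_cv``).
    """

    pmax: float  # cmH2O
    t_rise: float = 0.6  # s
    t_release: float = 0.3  # s
    neural_rr: float = 21.0  # breaths/min
    pmax_cv: float = 0.12
    timing_cv: float = 0.08

    def __post_init__(self) -> None:
        if self.pmax < 0:
            raise ValueError("pmax must be >= 0")
        if not (self.t_rise > 0 and self.t_release > 0 and self.neural_rr > 0):
            raise ValueError("t_rise, t_release, neural_rr must be positive")


@dataclass
class GroundTruth:
    """Simulator-side truth on the same grid as the Recording."""

    pmus_true: np.ndarray  # cmH2O, noise-free
    onset_idx: np.ndarray  # start of inspiratory flow / Paw decline
    trigger_idx: np.ndarray  # sample where flow crossed the trigger threshold
    delivery_idx: np.ndarray  # start of pressurization
    cycle_idx: np.ndarray  # cycling-off sample (flow <= fraction * peak)
    insp_end_idx: np.ndarray  # flow positive-to-negative zero crossing
    breath_end_idx: np.ndarray  # next onset
    ptp_breath_true: np.ndarray  # cmH2O*s
    ptp_min_true: np.ndarray  # cmH2O*s/min
    weak_true: np.ndarray  # bool
    effort_start_t: np.ndarray  # s, neural onset of each delivered effort
    effort_pmax: np.ndarray
    effort_t_rise: np.ndarray
    effort_t_release: np.ndarray

    @property
    def n_breaths(self) -> int:
        return len(self.onset_idx)

    def to_table(self, patient_id: str, fs: float) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": patient_id,
                "breath_idx": np.arange(self.n_breaths),
                "onset_t": self.onset_idx / fs,
                "insp_end_t": self.insp_end_idx / fs,
                "breath_end_t": self.breath_end_idx / fs,
                "ptp_breath_true": self.ptp_breath_true,
                "ptp_min_true": self.ptp_min_true,
                "weak_true": self.weak_true,
            }
        )


@dataclass
class CohortEntry:
    recording: Recording
    truth: GroundTruth
    profile: PatientProfile
    mechanics: MechanicsParams
    vent: VentParams


def pmus_profile(effort: EffortParams, t_in_breath) -> np.ndarray:
    """Muscle-pressure template at time(s) ``t_in_breath`` since neural onset.

    Quadratic rise from 0 to ``pmax`` over ``t_rise`` (zero slope at the
    peak), quadratic release to 0 over ``t_release``, 0 afterwards.
    Continuous total function; returns 0 at t = 0.
    """
    t = np.asarray(t_in_breath, dtype=float)
    u = t / effort.t_rise
    w = (t - effort.t_rise) / effort.t_release
    rise = effort.pmax * (2.0 * u - u * u)
    release = effort.pmax * (1.0 - w * w)
    out = np.where(t < effort.t_rise, rise, np.where(w < 1.0, release, 0.0))
    out = np.where(t <= 0.0, 0.0, out)
    return out if out.ndim else float(out)


def _neural_schedule(
    effort: EffortParams, duration: float, rng: np.random.Generator
) -> List[Tuple[float, float, float, float]]:
    """Draw (start_t, pmax, t_rise, t_release) per neural breath."""
    breaths = []
    t = 0.5  # settle time before the first effort
    mean_ttot = 60.0 / effort.neural_rr
    while t < duration - 0.5:
        pmax = effort.pmax * rng.lognormal(0.0, effort.pmax_cv)
        scale = rng.lognormal(0.0, effort.timing_cv)
        breaths.append((t, pmax, effort.t_rise * scale, effort.t_release * scale))
        t += mean_ttot * rng.lognormal(0.0, effort.timing_cv)
    return breaths


_EXHALE, _WAIT, _INSP = 0, 1, 2


def simulate_psv(
    mech: MechanicsParams,
    vent: VentParams,
    effort: EffortParams,
    duration: float = 60.0,
    fs: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    patient_id: str = "sim",
    pes_endexp: float = 5.0,
    weak_threshold: float = 50.0,
) -> Tuple[Recording, GroundTruth]:
    """Simulate one PSV recording at a fixed support level.

    Returns the Recording (flow, Paw, Pes on a uniform grid; Gaussian noise
    of ``noise_sd`` added to the pressure channels only) and the matching
    GroundTruth. Deterministic for a fixed seed. An effort too weak to
    trigger produces apnea at PEEP and an empty breath list.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    dt = 1.0 / fs
    t = np.arange(n) * dt

    # Precompute the true Pmus waveform from the neural schedule.
    schedule = _neural_schedule(effort, duration, rng)
    pmus = np.zeros(n)
    for start, pmax, t_rise, t_release in schedule:
        eff = EffortParams(
            pmax=pmax, t_rise=t_rise, t_release=t_release, neural_rr=effort.neural_rr
        )
        i0 = int(np.ceil(start * fs))
        i1 = min(n, int(np.ceil((start + t_rise + t_release) * fs)) + 1)
        if i0 >= n:
            break
        pmus[i0:i1] += pmus_profile(eff, t[i0:i1] - start)

    flow = np.zeros(n)
    paw = np.zeros(n)
    v = np.zeros(n)

    alpha_insp = 1.0 - np.exp(-dt / vent.rise_time_constant)
    alpha_exp = 1.0 - np.exp(-dt / vent.exp_time_constant)
    delay_samples = int(np.ceil(vent.trigger_delay * fs))
    refractory_samples = int(round(0.3 * fs))
    min_insp_samples = int(round(0.1 * fs))

    state = _EXHALE
    paw_cur = vent.peep
    v_prev = 0.0
    flow_prev = 0.0
    wait_until = -1
    delivery = -1
    peak_flow = 0.0
    last_cycle = -refractory_samples
    triggers: List[Tuple[int, int, int]] = []  # (trigger, delivery, cycle)
    trig_cur = -1

    denom = mech.rrs + mech.ers * dt / 2.0
    for i in range(n):
        # airway pressure update from the previous step's state
        if i > 0:
            if state == _INSP:
                target = vent.peep + vent.ps
                paw_cur += alpha_insp * (target - paw_cur)
            else:
                target = vent.peep - vent.demand_resistance * flow_prev
                paw_cur += alpha_exp * (target - paw_cur)
        paw[i] = paw_cur

        drive = paw_cur + pmus[i] - vent.peep - mech.peep_i
        if i == 0:
            f = drive / mech.rrs
        else:
            f = (drive - mech.ers * (v_prev + dt / 2.0 * flow_prev)) / denom
        if v_prev <= 0.0 and f < 0.0:
            f = 0.0  # lungs cannot empty below FRC
        flow[i] = f
        v[i] = v_prev + dt / 2.0 * (flow_prev + f) if i > 0 else 0.0

        # ventilator state machine
        if state == _EXHALE:
            if (
                i - last_cycle >= refractory_samples
                and f >= vent.trigger_flow_threshold
            ):
                state = _WAIT
                trig_cur = i
                wait_until = i + delay_samples
        elif state == _WAIT:
            if i >= wait_until:
                state = _INSP
                delivery = i
                peak_flow = max(f, 0.0)
        else:  # _INSP
            peak_flow = max(peak_flow, f)
            if (
                i - delivery >= min_insp_samples
                and f <= vent.cycle_fraction * peak_flow
            ):
                state = _EXHALE
                last_cycle = i
                triggers.append((trig_cur, delivery, i))

        flow_prev = f
        v_prev = v[i]

    truth = _build_ground_truth(
        flow, pmus, triggers, schedule, fs, weak_threshold
    )

    # Pes synthesized as the exact algebraic inverse of the Pmus formula,
    # with volume re-zeroed at each true onset exactly as the annotation
    # stage recomputes it.
    pes = np.empty(n)
    v_global = cumulative_trapezoid(flow, dx=dt, initial=0.0)
    # before the first onset use the global integral, then per-breath
    # cumulative integrals identical to compute_volume
    first = int(truth.onset_idx[0]) if truth.n_breaths else n
    pes[:first] = (
        pes_endexp
        + mech.ecw * v_global[:first]
        + mech.rcw * flow[:first]
        - pmus[:first]
    )
    starts = list(truth.onset_idx)
    for k, s in enumerate(starts):
        e = starts[k + 1] if k + 1 < len(starts) else n
        seg = flow[s:e]
        vol = cumulative_trapezoid(seg, dx=dt, initial=0.0)
        pes[s:e] = pes_endexp + mech.ecw * vol + mech.rcw * seg - pmus[s:e]

    if noise_sd > 0:
        paw = paw + rng.normal(0.0, noise_sd, n)
        pes = pes + rng.normal(0.0, noise_sd, n)

    rec = Recording(
        patient_id=patient_id,
        fs=fs,
        t=t,
        flow=flow,
        paw=paw,
        pes=pes,
        support_level=vent.ps,
        peep=vent.peep,
    )
    return rec, truth


def _build_ground_truth(
    flow: np.ndarray,
    pmus: np.ndarray,
    triggers: Sequence[Tuple[int, int, int]],
    schedule: Sequence[Tuple[float, float, float, float]],
    fs: float,
    weak_threshold: float,
) -> GroundTruth:
    n = flow.size
    dt = 1.0 / fs
    onsets, trigs, delivs, cycles, ends = [], [], [], [], []
    eff_meta = []
    starts = np.array([s[0] for s in schedule]) if schedule else np.empty(0)
    for trig, deliv, cyc in triggers:
        # onset: walk back from the trigger to the start of inspiratory flow
        j = trig
        while j > 0 and flow[j - 1] > 0:
            j -= 1
        # end of inspiration: first flow <= 0 after cycling
        k = cyc
        while k < n and flow[k] > 0:
            k += 1
        if k >= n:
            continue
        onsets.append(j)
        trigs.append(trig)
        delivs.append(deliv)
        cycles.append(cyc)
        ends.append(k)
        # effort metadata: the latest neural effort starting before delivery
        idx = int(np.searchsorted(starts, deliv * dt, side="right")) - 1
        eff_meta.append(schedule[max(idx, 0)])

    # drop the final breath: its Ttot (next onset) is unknown
    keep = len(onsets) - 1
    if keep < 0:
        keep = 0
    breath_end = [onsets[i + 1] for i in range(keep)]

    ptp_b, ptp_m, weak = [], [], []
    for i in range(keep):
        s, e = onsets[i], ends[i]
        p = float(np.trapezoid(pmus[s : e + 1], dx=dt))
        ttot = (breath_end[i] - s) * dt
        pm = p * 60.0 / ttot
        ptp_b.append(p)
        ptp_m.append(pm)
        weak.append(pm < weak_threshold)

    meta = eff_meta[:keep]
    return GroundTruth(
        pmus_true=pmus,
        onset_idx=np.array(onsets[:keep], dtype=int),
        trigger_idx=np.array(trigs[:keep], dtype=int),
        delivery_idx=np.array(delivs[:keep], dtype=int),
        cycle_idx=np.array(cycles[:keep], dtype=int),
        insp_end_idx=np.array(ends[:keep], dtype=int),
        breath_end_idx=np.array(breath_end, dtype=int),
        ptp_breath_true=np.array(ptp_b),
        ptp_min_true=np.array(ptp_m),
        weak_true=np.array(weak, dtype=bool),
        effort_start_t=np.array([m[0] for m in meta]),
        effort_pmax=np.array([m[1] for m in meta]),
        effort_t_rise=np.array([m[2] for m in meta]),
        effort_t_release=np.array([m[3] for m in meta]),
    )


def generate_cohort(
    n_patients: int,
    levels_per_patient: Optional[int] = None,
    duration: float = 150.0,
    fs: float = 100.0,
    noise_sd: float = 0.3,
    weak_threshold: float = 50.0,
    seed: int = 0,
    effort_scale: float = 1.0,
) -> List[CohortEntry]:
    """Generate a PSV cohort with drawn demographics, mechanics and efforts.

    Each patient contributes 2-5 support levels (drawn uniformly unless
    ``levels_per_patient`` fixes the count); effort amplitude falls
    exponentially with the level of support, emulating down-regulation of
    drive under increasing assist, which produces a weak-effort
    (PTP/min < 50 cmH2O*s/min) prevalence near 14% under defaults.
    Deterministic per seed; patient ids unique.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if levels_per_patient is not None and not (2 <= levels_per_patient <= 5):
        raise ValueError("levels_per_patient must be in 2..5")
    rng = np.random.default_rng(seed)
    entries: List[CohortEntry] = []
    for p in range(n_patients):
        pid = f"P{p:03d}"
        sex = "male" if rng.random() < 0.46 else "female"
        age = float(np.clip(rng.normal(70.0, 10.0), 30.0, 90.0))
        height = float(
            np.clip(rng.normal(175.0 if sex == "male" else 162.0, 7.0), 145.0, 200.0)
        )
        pes_endexp = float(np.clip(rng.normal(5.0, 2.0), 0.0, 12.0))
        profile = PatientProfile(sex=sex, age=age, height=height, pes_endexp=pes_endexp)
        ecw = chest_wall_elastance(predicted_vc(sex, age, height))

        compliance = float(np.clip(rng.normal(46.0, 14.0), 15.0, 90.0))  # mL/cmH2O
        ers = 1000.0 / compliance
        rrs = float(rng.uniform(8.0, 15.0))
        mech = MechanicsParams(ers=ers, rrs=rrs, ecw=ecw, rcw=1.5, peep_i=0.0)

        peep = float(np.clip(np.round(rng.normal(7.0, 2.0)), 4.0, 12.0))
        trigger_delay = float(rng.uniform(0.08, 0.10))
        n_levels = (
            levels_per_patient
            if levels_per_patient is not None
            else int(rng.integers(2, 6))
        )
        ps_levels = np.clip(np.sort(rng.normal(7.0, 4.0, n_levels)), 0.0, 20.0)

        drive = effort_scale * rng.lognormal(np.log(15.0), 0.30)  # cmH2O at PS=0
        rr0 = float(np.clip(rng.normal(21.0, 5.0), 10.0, 34.0))
        for li, ps in enumerate(ps_levels):
            # over-assisted levels suppress drive (and with it the rate),
            # producing the weak tail of the effort distribution
            suppressed = rng.random() < 0.15
            drive_factor = 0.35 if suppressed else 1.0
            pmax = float(
                np.clip(
                    drive * np.exp(-ps / 18.0) * drive_factor * rng.lognormal(0.0, 0.15),
                    3.0,
                    25.0,
                )
            )
            t_rise = float(np.clip(0.35 + 0.035 * pmax, 0.35, 1.00))
            neural_rr = float(
                np.clip(
                    (rr0 - 0.12 * (ps - 7.0) + rng.normal(0, 1.0))
                    * (0.85 if suppressed else 1.0),
                    8.0,
                    32.0,
                )
            )
            eff = EffortParams(
                pmax=pmax,
                t_rise=t_rise,
                t_release=0.5 * t_rise,
                neural_rr=neural_rr,
            )
            vent = VentParams(ps=float(ps), peep=peep, trigger_delay=trigger_delay)
            rec, truth = simulate_psv(
                mech,
                vent,
                eff,
                duration=duration,
                fs=fs,
                noise_sd=noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
                patient_id=pid,
                pes_endexp=pes_endexp,
                weak_threshold=weak_threshold,
            )
            entries.append(CohortEntry(rec, truth, profile, mech, vent))
    return entries
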