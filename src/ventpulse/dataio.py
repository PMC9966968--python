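"""Domain types, waveform I/O and run configuration.

Units follow clinical convention throughout the package: flow in L/s
(inspiration positive), volumes in L, all pressures in cmH2O, time in s.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Recording",
    "PatientProfile",
    "BreathSegment",
    "AnnotatedBreath",
    "RunConfig",
    "read_recording",
    "write_recording",
    "load_config",
]

_CHANNELS = ("flow", "paw", "pes")


class FormatError(ValueError):
    """Input file lacks a required channel or metadata field."""


class SamplingError(ValueError):
    """Time axis is not a uniform grid."""


@dataclass
class Recording:
    """Synchronized multichannel ventilator recording.

    Channels: ``flow`` (L/s, inspiration positive), ``paw`` and ``pes``
    (cmH2O), optional ``pga``. ``t`` must be a uniform grid with step 1/fs.
    """

    patient_id: str
    fs: float
    t: np.ndarray
    flow: np.ndarray
    paw: np.ndarray
    pes: np.ndarray
    pga: Optional[np.ndarray] = None
    support_level: float = 0.0
    peep: float = 0.0

    def __post_init__(self) -> None:
        for name in ("t",) + _CHANNELS:
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.pga is not None:
            self.pga = np.asarray(self.pga, dtype=float)
        n = self.t.size
        if n < 2:
            raise ValueError("Recording needs at least 2 samples")
        for name in _CHANNELS + (("pga",) if self.pga is not None else ()):
            if getattr(self, name).size != n:
                raise ValueError(f"channel {name!r} length differs from t")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        dt = 1.0 / self.fs
        steps = np.diff(self.t)
        if np.any(np.abs(steps - dt) > 1e-9 * dt):
            raise SamplingError("t is not uniformly sampled at 1/fs")

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return (self.n_samples - 1) / self.fs


@dataclass(frozen=True)
class PatientProfile:
    """Demographics and esophageal baseline used for Pmus reconstruction."""

    sex: str  # "male" | "female"
    age: float  # years
    height: float  # cm
    pes_endexp: float  # cmH2O, end-expiratory esophageal pressure

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")
        if not (self.age > 0 and self.height > 0):
            raise ValueError("age and height must be positive")


@dataclass
class BreathSegment:
    """Boundaries of one mechanical breath, in sample indices.

    ``onset_idx``: start of inspiration (start of the triggering Paw decline);
    ``insp_end_idx``: end of mechanical inspiration (flow zero crossing);
    ``breath_end_idx``: next onset (or recording end). Ti and Ttot in seconds.
    """

    onset_idx: int
    insp_end_idx: int
    breath_end_idx: int
    ti: float
    ttot: float
    valid: bool = True
    exclusion_reason: Optional[str] = None

    @classmethod
    def from_indices(
        cls,
        onset_idx: int,
        insp_end_idx: int,
        breath_end_idx: int,
        fs: float,
        valid: bool = True,
        exclusion_reason: Optional[str] = None,
    ) -> "BreathSegment":
        return cls(
            onset_idx=int(onset_idx),
            insp_end_idx=int(insp_end_idx),
            breath_end_idx=int(breath_end_idx),
            ti=(insp_end_idx - onset_idx) / fs,
            ttot=(breath_end_idx - onset_idx) / fs,
            valid=valid,
            exclusion_reason=exclusion_reason,
        )

    def __post_init__(self) -> None:
        if self.valid and not (self.onset_idx < self.insp_end_idx <= self.breath_end_idx):
            raise ValueError("require onset_idx < insp_end_idx <= breath_end_idx")


@dataclass
class AnnotatedBreath:
    """One breath with reconstructed Pmus and effort quantification."""

    segment: BreathSegment
    pmus: np.ndarray  # cmH2O, over [onset, breath_end)
    vt: float  # L
    ptp_breath: float  # cmH2O*s
    ptp_min: float  # cmH2O*s/min
    weak: bool


@dataclass
class RunConfig:
    """Pipeline configuration with clinical defaults.

    ``weak_threshold`` is the PTP/min cut-off below which an effort is weak
    (50 cmH2O*s/min); ``rcw`` the chest-wall resistance used in Pmus
    reconstruction (1.5 cmH2O/(L/s)); ``ecw_mode`` selects how chest-wall
    elastance is derived from predicted vital capacity.
    """

    weak_threshold: float = 50.0
    rcw: float = 1.5
    ecw_mode: str = "compliance_4pct_vc"  # or "literal"
    fs: float = 100.0
    fs_model: float = 50.0
    segment_len: int = 300
    seed: int = 0
    split_fractions: tuple = (0.45, 0.15, 0.40)
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 30
    patience: int = 4
    decision_threshold: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.weak_threshold > 0:
            raise ValueError("weak_threshold must be positive")
        if not self.segment_len > 0:
            raise ValueError("segment_len must be positive")
        if self.ecw_mode not in ("compliance_4pct_vc", "literal"):
            raise ValueError(f"unknown ecw_mode {self.ecw_mode!r}")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split_fractions must sum to 1")


def load_config(path) -> RunConfig:
    """Load a YAML config, applying defaults for absent keys."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise FormatError("config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    if "split_fractions" in data:
        data["split_fractions"] = tuple(data["split_fractions"])
    return RunConfig(**data)


def _infer_format(path, format: Optional[str]) -> str:
    if format is not None:
        return format
    suffix = Path(path).suffix.lower()
    if suffix in (".h5", ".hdf5"):
        return "hdf5"
    return "csv"


def read_recording(path, format: Optional[str] = None) -> Recording:
    """Read a Recording from CSV or HDF5.

    CSV: columns t, flow, paw, pes (pga optional), metadata in leading
    ``# key=value`` comment lines. HDF5: one dataset per channel, metadata
    in root attributes.
    """
    fmt = _infer_format(path, format)
    if fmt == "hdf5":
        with h5py.File(path, "r") as fh:
            meta = dict(fh.attrs)
            for ch in _CHANNELS + ("t",):
                if ch not in fh:
                    raise FormatError(f"missing channel {ch!r} in {path}")
            kwargs = {ch: fh[ch][:] for ch in ("t",) + _CHANNELS}
            if "pga" in fh:
                kwargs["pga"] = fh["pga"][:]
    elif fmt == "csv":
        meta = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                key, _, value = line[1:].strip().partition("=")
                meta[key.strip()] = value.strip()
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
        for ch in ("t",) + _CHANNELS:
            if ch not in df.columns:
                raise FormatError(f"missing channel {ch!r} in {path}")
        kwargs = {ch: df[ch].to_numpy() for ch in ("t",) + _CHANNELS}
        if "pga" in df.columns:
            kwargs["pga"] = df["pga"].to_numpy()
    else:
        raise ValueError(f"unknown format {fmt!r}")

    t = np.asarray(kwargs["t"], dtype=float)
    if t.size < 2:
        raise FormatError("recording too short")
    dt = np.median(np.diff(t))
    if dt <= 0:
        raise SamplingError("non-increasing time axis")
    return Recording(
        patient_id=str(meta.get("patient_id", "unknown")),
        fs=float(meta.get("fs", 1.0 / dt)),
        support_level=float(meta.get("support_level", 0.0)),
        peep=float(meta.get("peep", 0.0)),
        **kwargs,
    )


def write_recording(rec: Recording, path, format: Optional[str] = None) -> None:
    """Write a Recording; read_recording round-trips it exactly.

    Floats are serialized with 17 significant digits in CSV so the
    round-trip is bit-exact for both formats.
    """
    fmt = _infer_format(path, format)
    meta = {
        "patient_id": rec.patient_id,
        "fs": rec.fs,
        "support_level": rec.support_level,
        "peep": rec.peep,
    }
    if fmt == "hdf5":
        with h5py.File(path, "w") as fh:
            for ch in ("t",) + _CHANNELS:
                fh.create_dataset(ch, data=getattr(rec, ch))
            if rec.pga is not None:
                fh.create_dataset("pga", data=rec.pga)
            for key, value in meta.items():
                fh.attrs[key] = value
    elif fmt == "csv":
        cols = {ch: getattr(rec, ch) for ch in ("t",) + _CHANNELS}
        if rec.pga is not None:
            cols["pga"] = rec.pga
        with open(path, "w") as fh:
            for key, value in meta.items():
                fh.write(f"# {key}={value}\n")
            pd.DataFrame(cols).to_csv(fh, index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown format {fmt!r}")
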