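"""Domain types and CSV I/O for ventilator-logger exports.

One spontaneous breathing trial (SBT) yields two tables:

* a *waveform* table — airway pressure (Paw, cmH2O), flow (L/min) and
  volume (mL) sampled on a fixed grid (canonically every 15 ms);
* a *numeric* table — 25 monitoring channels logged at a sub-breath
  cadence, each held piecewise-constant over a breath.

Both are exchanged as plain UTF-8 CSV.  Validation is strict and total:
a malformed file raises :class:`FormatError` or :class:`ValidationError`,
never a silently truncated record.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_NUMERIC_CHANNELS",
    "FormatError",
    "ValidationError",
    "WaveformRecording",
    "BreathNumericTable",
    "SBTRecord",
    "Cohort",
    "read_waveform_csv",
    "write_waveform_csv",
    "read_numeric_csv",
    "write_numeric_csv",
    "read_labels_manifest",
    "write_labels_manifest",
]


class FormatError(ValueError):
    """A file does not conform to the expected CSV dialect."""


class ValidationError(ValueError):
    """Structurally parseable data violates a domain invariant."""


# Canonical ordered list of the 25 numeric monitoring channels.  The first
# five are the channels named in the study summary (inspiratory / spontaneous
# expiratory tidal volume, breathing frequency, I:E ratio, airway occlusion
# pressure P0.1); the remainder are standard pressure-support monitoring
# channels of a modern ICU ventilator.  This tuple is the single source of
# truth for column order everywhere in the package.  It is a stand-in
# inventory: the study's own 25-channel list is not public.
CANONICAL_NUMERIC_CHANNELS: tuple[str, ...] = (
    "vt_insp_ml",
    "vt_exp_spont_ml",
    "resp_rate_bpm",
    "ie_ratio",
    "p01_cmh2o",
    "peak_pressure_cmh2o",
    "mean_pressure_cmh2o",
    "peep_cmh2o",
    "minute_volume_l",
    "spont_minute_volume_l",
    "spont_rate_bpm",
    "rsbi_bpm_per_l",
    "compliance_dyn_ml_cmh2o",
    "resistance_insp_cmh2o_l_s",
    "resistance_exp_cmh2o_l_s",
    "rc_expiratory_s",
    "insp_time_s",
    "exp_time_s",
    "peak_insp_flow_l_min",
    "peak_exp_flow_l_min",
    "leak_pct",
    "pressure_support_cmh2o",
    "work_of_breathing_j_l",
    "pressure_time_product",
    "fio2_pct",
)

_LABELS = ("success", "failure")


def _as_clean_1d(name: str, values, n: Optional[int] = None) -> np.ndarray:
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim != 1 or arr.size < 1:
        raise ValidationError(f"channel {name!r} must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(arr)):
        bad = int(np.flatnonzero(~np.isfinite(arr))[0])
        raise ValidationError(f"channel {name!r} has a non-finite value at row {bad}")
    if n is not None and arr.size != n:
        raise ValidationError(
            f"channel {name!r} has length {arr.size}, expected {n}"
        )
    return arr


@dataclass(frozen=True)
class WaveformRecording:
    """Three-channel ventilator waveform for one SBT on a fixed time grid."""

    patient_id: str
    sample_period_ms: float
    paw: np.ndarray
    flow: np.ndarray
    volume: np.ndarray

    def __post_init__(self):
        if not self.patient_id:
            raise ValidationError("patient_id must be non-empty")
        if not (self.sample_period_ms > 0):
            raise ValidationError("sample_period_ms must be > 0")
        paw = _as_clean_1d("paw", self.paw)
        flow = _as_clean_1d("flow", self.flow, paw.size)
        volume = _as_clean_1d("volume", self.volume, paw.size)
        object.__setattr__(self, "paw", paw)
        object.__setattr__(self, "flow", flow)
        object.__setattr__(self, "volume", volume)

    def __len__(self) -> int:
        return int(self.paw.size)

    @property
    def duration_s(self) -> float:
        return len(self) * self.sample_period_ms / 1000.0

    def as_array(self) -> np.ndarray:
        """Channels-first float array of shape (3, T): paw, flow, volume."""
        return np.stack([self.paw, self.flow, self.volume])


@dataclass(frozen=True)
class BreathNumericTable:
    """The 25-channel numeric monitoring series for one SBT.

    ``channels`` maps canonical channel name -> 1-D series; iteration order
    always follows :data:`CANONICAL_NUMERIC_CHANNELS`.
    """

    patient_id: str
    step_period_s: float
    channels: dict[str, np.ndarray]

    def __post_init__(self):
        if not self.patient_id:
            raise ValidationError("patient_id must be non-empty")
        if not (self.step_period_s > 0):
            raise ValidationError("step_period_s must be > 0")
        names = tuple(self.channels)
        if sorted(names) != sorted(CANONICAL_NUMERIC_CHANNELS):
            unknown = set(names) - set(CANONICAL_NUMERIC_CHANNELS)
            if unknown:
                raise ValidationError(f"unknown channel names: {sorted(unknown)}")
            raise ValidationError(
                f"expected 25 channels, got {len(names)}"
            )
        first = _as_clean_1d(CANONICAL_NUMERIC_CHANNELS[0],
                             self.channels[CANONICAL_NUMERIC_CHANNELS[0]])
        ordered = {CANONICAL_NUMERIC_CHANNELS[0]: first}
        for name in CANONICAL_NUMERIC_CHANNELS[1:]:
            ordered[name] = _as_clean_1d(name, self.channels[name], first.size)
        object.__setattr__(self, "channels", ordered)

    def __len__(self) -> int:
        return int(next(iter(self.channels.values())).size)

    @property
    def channel_names(self) -> tuple[str, ...]:
        return CANONICAL_NUMERIC_CHANNELS

    def as_array(self) -> np.ndarray:
        """Channels-first float array of shape (25, T_n) in canonical order."""
        return np.stack([self.channels[c] for c in CANONICAL_NUMERIC_CHANNELS])


@dataclass(frozen=True)
class SBTRecord:
    """One patient's SBT: waveform + numeric tables, optional outcome label."""

    waveform: WaveformRecording
    numeric: BreathNumericTable
    label: Optional[str] = None
    summary_frequency: Optional[float] = None    # breaths/min, realized mean
    summary_tidal_volume: Optional[float] = None  # liters, realized mean

    def __post_init__(self):
        if self.waveform.patient_id != self.numeric.patient_id:
            raise ValidationError(
                "waveform and numeric tables belong to different patients: "
                f"{self.waveform.patient_id!r} vs {self.numeric.patient_id!r}"
            )
        if self.label is not None and self.label not in _LABELS:
            raise ValidationError(
                f"label must be one of {_LABELS}, got {self.label!r}"
            )
        if self.summary_tidal_volume is not None and not (self.summary_tidal_volume > 0):
            raise ValidationError("summary_tidal_volume must be > 0 when present")

    @property
    def patient_id(self) -> str:
        return self.waveform.patient_id

    def with_label(self, label: str) -> "SBTRecord":
        return replace(self, label=label)


@dataclass(frozen=True)
class Cohort:
    """A list of SBT records with unique patient ids."""

    records: tuple[SBTRecord, ...] = field(default_factory=tuple)

    def __post_init__(self):
        object.__setattr__(self, "records", tuple(self.records))
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate patient ids in cohort: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    @property
    def labels(self) -> list[Optional[str]]:
        return [r.label for r in self.records]

    def subset(self, patient_ids) -> "Cohort":
        wanted = set(patient_ids)
        return Cohort(tuple(r for r in self.records if r.patient_id in wanted))


# ---------------------------------------------------------------------------
# CSV dialects


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV surfaces as a format error
        raise FormatError(f"{path}: not parseable as CSV: {exc}") from exc
    if df.shape[0] < 1:
        raise FormatError(f"{path}: no data rows")
    return df


def _check_no_nan(df: pd.DataFrame, path) -> None:
    if df.isna().any().any():
        row = int(df.index[df.isna().any(axis=1)][0])
        raise ValidationError(f"{path}: missing value at data row {row}")


def read_waveform_csv(path, patient_id: Optional[str] = None) -> WaveformRecording:
    """Read a waveform CSV with header ``time_ms,paw,flow,volume``.

    The sample period is inferred from the first two time stamps; the time
    column must be strictly increasing and evenly spaced (1e-6 ms slack).
    ``patient_id`` defaults to the file stem.
    """
    path = Path(path)
    df = _read_csv(path)
    for col in ("time_ms", "paw", "flow", "volume"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    _check_no_nan(df, path)
    t = df["time_ms"].to_numpy(dtype=np.float64)
    if len(t) >= 2:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValidationError(f"{path}: time_ms is not strictly increasing")
        if np.max(np.abs(dt - dt[0])) > 1e-6:
            raise ValidationError(f"{path}: time_ms is not evenly spaced")
        period = float(dt[0])
    else:
        period = 15.0
    return WaveformRecording(
        patient_id=patient_id or path.stem.removesuffix("_waveform"),
        sample_period_ms=period,
        paw=df["paw"].to_numpy(np.float64),
        flow=df["flow"].to_numpy(np.float64),
        volume=df["volume"].to_numpy(np.float64),
    )


def write_waveform_csv(rec: WaveformRecording, path) -> Path:
    """Write ``rec`` in the dialect accepted by :func:`read_waveform_csv`."""
    path = Path(path)
    t = np.arange(len(rec), dtype=np.float64) * rec.sample_period_ms
    df = pd.DataFrame(
        {"time_ms": t, "paw": rec.paw, "flow": rec.flow, "volume": rec.volume}
    )
    df.to_csv(path, index=False, float_format="%.8g")
    return path


def read_numeric_csv(path, patient_id: Optional[str] = None) -> BreathNumericTable:
    """Read a numeric CSV with header ``time_s`` + the 25 canonical channels.

    Column order on disk is arbitrary; in memory it is normalized to
    :data:`CANONICAL_NUMERIC_CHANNELS`.
    """
    path = Path(path)
    df = _read_csv(path)
    if "time_s" not in df.columns:
        raise FormatError(f"{path}: missing required column 'time_s'")
    names = [c for c in df.columns if c != "time_s"]
    unknown = sorted(set(names) - set(CANONICAL_NUMERIC_CHANNELS))
    if unknown:
        raise FormatError(f"{path}: unknown channel name(s) {unknown}")
    if len(names) != len(CANONICAL_NUMERIC_CHANNELS):
        raise FormatError(
            f"{path}: expected 25 channels, got {len(names)}"
        )
    _check_no_nan(df, path)
    t = df["time_s"].to_numpy(np.float64)
    if len(t) >= 2:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValidationError(f"{path}: time_s is not strictly increasing")
        step = float(dt[0])
    else:
        step = 0.5
    return BreathNumericTable(
        patient_id=patient_id or path.stem.removesuffix("_numeric"),
        step_period_s=step,
        channels={c: df[c].to_numpy(np.float64) for c in CANONICAL_NUMERIC_CHANNELS},
    )


def write_numeric_csv(table: BreathNumericTable, path) -> Path:
    path = Path(path)
    t = np.arange(len(table), dtype=np.float64) * table.step_period_s
    cols = {"time_s": t}
    cols.update({c: table.channels[c] for c in CANONICAL_NUMERIC_CHANNELS})
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.8g")
    return path


def read_labels_manifest(path) -> dict[str, str]:
    """Read a two-column ``patient_id,label`` manifest into a dict.

    Labels must be ``success`` or ``failure``; duplicate ids are rejected.
    """
    path = Path(path)
    df = _read_csv(path)
    for col in ("patient_id", "label"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    _check_no_nan(df, path)
    out: dict[str, str] = {}
    for _, row in df.iterrows():
        pid, label = str(row["patient_id"]), str(row["label"])
        if label not in _LABELS:
            raise FormatError(
                f"{path}: unknown label {label!r} for {pid!r}; allowed: {_LABELS}"
            )
        if pid in out:
            raise ValidationError(f"{path}: duplicate patient_id {pid!r}")
        out[pid] = label
    return out


def write_labels_manifest(labels: dict[str, str], path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"patient_id": list(labels), "label": [labels[k] for k in labels]}
    ).to_csv(path, index=False)
    return path
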