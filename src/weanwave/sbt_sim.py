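"""Synthetic spontaneous-breathing-trial generator.

Emulates what a ventilator data logger records during a 30-minute
pressure-support SBT (PEEP plus up to 6 cmH2O of support): a 3-channel
waveform (Paw / flow / volume, one sample every 15 ms) and a 25-channel
numeric monitoring table, for cohorts of "weaning success" and "weaning
failure" patients.

The breath template is deliberately simple and closed-form-checkable
rather than a lung-mechanics ODE:

* inspiration — half-sine flow, raised to a power ``1 + dyssynchrony`` to
  round the profile, rescaled so the discrete integral equals the tidal
  volume;
* expiration — passive exponential decay (time constant one third of the
  expiratory time), rescaled so the breath's volume returns to baseline;
* Paw — fast rise to PEEP + PS held over inspiration, with a
  dyssynchrony-scaled mid-inspiratory dip (strong patient effort pulls
  airway pressure down against the fixed support level), and exponential
  relaxation back to PEEP in expiration.

Failure-pattern cohorts mix two phenotypes: rapid shallow breathing
(high rate, low tidal volume — high RSBI) and dyssynchrony-dominant
breathing (near-normal rate/volume but deep Paw dips, rounded flow and
high breath-to-breath variability).  This keeps the rapid-shallow-
breathing index informative but imperfect, while the waveform morphology
separates the classes cleanly — the regime the prediction model targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .vent_data import (
    CANONICAL_NUMERIC_CHANNELS,
    BreathNumericTable,
    Cohort,
    SBTRecord,
    ValidationError,
    WaveformRecording,
    read_labels_manifest,
    read_numeric_csv,
    read_waveform_csv,
    write_labels_manifest,
    write_numeric_csv,
    write_waveform_csv,
)

__all__ = [
    "BreathPattern",
    "SimConfig",
    "PatternRanges",
    "ProfilePriors",
    "default_priors",
    "simulate_breath",
    "simulate_recording",
    "inject_cough",
    "simulate_cohort",
    "save_cohort",
    "load_cohort",
]


@dataclass(frozen=True)
class BreathPattern:
    """Per-patient breathing phenotype.

    respiratory_rate : breaths/min
    tidal_volume     : liters
    inspiratory_fraction : Ti / breath period, in (0, 1)
    rate_cv, volume_cv   : breath-to-breath coefficients of variation
    dyssynchrony_level   : [0, 1]; scales the inspiratory Paw dip and the
        rounding of the inspiratory flow profile
    """

    respiratory_rate: float
    tidal_volume: float
    inspiratory_fraction: float = 0.35
    rate_cv: float = 0.05
    volume_cv: float = 0.05
    dyssynchrony_level: float = 0.0

    def __post_init__(self):
        if not (self.respiratory_rate > 0):
            raise ValidationError("respiratory_rate must be > 0")
        if not (self.tidal_volume > 0):
            raise ValidationError("tidal_volume must be > 0")
        if not (0.0 < self.inspiratory_fraction < 1.0):
            raise ValidationError("inspiratory_fraction must be in (0, 1)")
        if self.rate_cv < 0 or self.volume_cv < 0:
            raise ValidationError("coefficients of variation must be >= 0")
        if not (0.0 <= self.dyssynchrony_level <= 1.0):
            raise ValidationError("dyssynchrony_level must be in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation settings (defaults follow the SBT protocol:
    30-minute trial, PEEP 5 cmH2O, pressure support 6 cmH2O)."""

    n_patients: int = 40
    failure_prevalence: float = 0.25
    duration_s: float = 1800.0
    peep: float = 5.0
    pressure_support: float = 6.0
    sample_period_ms: float = 15.0
    numeric_step_s: float = 0.5
    cough_rate_per_min: float = 0.1
    noise_paw: float = 0.15     # cmH2O, measurement noise s.d.
    noise_flow: float = 0.8     # L/min
    noise_volume: float = 2.0   # mL
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        if not (0.0 <= self.failure_prevalence <= 1.0):
            raise ValidationError("failure_prevalence must be in [0, 1]")
        if self.duration_s < 10.0:
            raise ValidationError("duration_s must cover at least one breath")
        if self.cough_rate_per_min < 0:
            raise ValidationError("cough_rate_per_min must be >= 0")


@dataclass(frozen=True)
class PatternRanges:
    """Uniform sampling ranges (lo, hi) for each BreathPattern field."""

    respiratory_rate: tuple[float, float]
    tidal_volume: tuple[float, float]
    inspiratory_fraction: tuple[float, float] = (0.30, 0.40)
    rate_cv: tuple[float, float] = (0.03, 0.08)
    volume_cv: tuple[float, float] = (0.03, 0.08)
    dyssynchrony_level: tuple[float, float] = (0.0, 0.1)

    def sample(self, rng: np.random.Generator) -> BreathPattern:
        u = lambda lo_hi: float(rng.uniform(*lo_hi))
        return BreathPattern(
            respiratory_rate=u(self.respiratory_rate),
            tidal_volume=u(self.tidal_volume),
            inspiratory_fraction=u(self.inspiratory_fraction),
            rate_cv=u(self.rate_cv),
            volume_cv=u(self.volume_cv),
            dyssynchrony_level=u(self.dyssynchrony_level),
        )

    def mean_rsbi(self) -> float:
        """E[rate / VT] under independent uniform draws (E[1/VT] in closed
        form for a uniform tidal volume)."""
        r = 0.5 * (self.respiratory_rate[0] + self.respiratory_rate[1])
        a, b = self.tidal_volume
        inv_vt = math.log(b / a) / (b - a) if b > a else 1.0 / a
        return r * inv_vt


@dataclass(frozen=True)
class ProfilePriors:
    """Distributions over breathing phenotypes for the two outcome classes.

    ``failure`` is a mixture of (weight, ranges) components so the failure
    class can contain both rapid-shallow and dyssynchrony-dominant
    phenotypes.  The defaults satisfy E[RSBI | failure] > 105 >
    E[RSBI | success].
    """

    success: PatternRanges
    failure: tuple[tuple[float, PatternRanges], ...]

    def __post_init__(self):
        w = sum(wi for wi, _ in self.failure)
        if not math.isclose(w, 1.0, rel_tol=1e-6):
            raise ValidationError("failure mixture weights must sum to 1")
        if not (self.mean_rsbi("failure") > 105.0 > self.mean_rsbi("success")):
            raise ValidationError(
                "priors must satisfy E[RSBI|failure] > 105 > E[RSBI|success]"
            )

    def mean_rsbi(self, label: str) -> float:
        if label == "success":
            return self.success.mean_rsbi()
        return sum(w * r.mean_rsbi() for w, r in self.failure)

    def sample(self, label: str, rng: np.random.Generator) -> BreathPattern:
        if label == "success":
            return self.success.sample(rng)
        weights = np.array([w for w, _ in self.failure])
        idx = int(rng.choice(len(self.failure), p=weights / weights.sum()))
        return self.failure[idx][1].sample(rng)


def default_priors() -> ProfilePriors:
    """Study-condition priors.

    Success: regular breathing at normal rate and volume, negligible
    dyssynchrony (RSBI roughly 25-70).  Failure: 60% rapid-shallow
    (RSBI roughly 95-250), 40% dyssynchrony-dominant with near-normal
    RSBI but deep effort dips and irregular timing.  The mixture keeps
    mean failure RSBI above the classical 105 cutoff while leaving enough
    overlap that a thresholded RSBI is an informative-but-weak baseline.
    """
    success = PatternRanges(
        respiratory_rate=(14.0, 24.0),
        tidal_volume=(0.35, 0.55),
        inspiratory_fraction=(0.30, 0.40),
        rate_cv=(0.03, 0.08),
        volume_cv=(0.03, 0.08),
        dyssynchrony_level=(0.0, 0.15),
    )
    rapid_shallow = PatternRanges(
        respiratory_rate=(28.0, 38.0),
        tidal_volume=(0.15, 0.30),
        inspiratory_fraction=(0.35, 0.45),
        rate_cv=(0.10, 0.20),
        volume_cv=(0.10, 0.20),
        dyssynchrony_level=(0.4, 0.9),
    )
    dyssynchronous = PatternRanges(
        respiratory_rate=(18.0, 28.0),
        tidal_volume=(0.30, 0.45),
        inspiratory_fraction=(0.30, 0.45),
        rate_cv=(0.12, 0.25),
        volume_cv=(0.10, 0.20),
        dyssynchrony_level=(0.5, 1.0),
    )
    return ProfilePriors(
        success=success,
        failure=((0.6, rapid_shallow), (0.4, dyssynchronous)),
    )


# ---------------------------------------------------------------------------
# Breath template


def simulate_breath(
    pattern: BreathPattern,
    peep: float,
    ps: float,
    dt_ms: float,
    period_s: Optional[float] = None,
    tidal_volume_l: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One breath's (paw, flow, volume) sampled every ``dt_ms``.

    ``period_s`` / ``tidal_volume_l`` override the pattern's nominal values
    (used for breath-to-breath jitter); the discrete flow integral is
    rescaled so peak volume equals the tidal volume exactly and end-of-
    breath volume returns to zero.  Units: paw cmH2O, flow L/min,
    volume mL.
    """
    if not (dt_ms > 0):
        raise ValidationError("dt_ms must be > 0")
    period = period_s if period_s is not None else 60.0 / pattern.respiratory_rate
    vt = tidal_volume_l if tidal_volume_l is not None else pattern.tidal_volume
    dt = dt_ms / 1000.0
    n = max(4, int(round(period / dt)))
    ti = pattern.inspiratory_fraction * period
    n_in = max(2, min(n - 2, int(round(ti / dt))))
    n_ex = n - n_in
    te = n_ex * dt
    dys = pattern.dyssynchrony_level

    # inspiratory flow: rounded half-sine, rescaled to integrate to VT
    t_in = (np.arange(n_in) + 0.5) * dt
    shape = np.sin(np.pi * t_in / (n_in * dt)) ** (1.0 + dys)
    flow_in = shape * (vt / (shape.sum() * dt))          # L/s

    # passive expiration: exponential decay, rescaled to return volume to 0
    tau = te / 3.0
    t_ex = (np.arange(n_ex) + 0.5) * dt
    decay = np.exp(-t_ex / tau)
    flow_ex = -decay * (vt / (decay.sum() * dt))         # L/s

    flow_ls = np.concatenate([flow_in, flow_ex])
    volume = np.cumsum(flow_ls) * dt * 1000.0            # mL above baseline

    # airway pressure: rise to PEEP+PS, dyssynchrony dip, passive relaxation
    rise = 1.0 - np.exp(-t_in / (0.15 * n_in * dt))
    dip = 1.5 * dys * ps * np.sin(np.pi * t_in / (n_in * dt)) ** 2
    paw_in = peep + ps * rise - dip
    end_support = ps * rise[-1] - dip[-1]
    paw_ex = peep + end_support * np.exp(-t_ex / 0.08)
    paw = np.concatenate([paw_in, paw_ex])

    flow = flow_ls * 60.0                                # L/min
    return paw, flow, volume


def simulate_recording(
    pattern: BreathPattern,
    config: SimConfig,
    rng: np.random.Generator,
    patient_id: str = "sim-0",
) -> SBTRecord:
    """Full unlabelled SBT record for one patient.

    Breath periods and tidal volumes jitter around the pattern's nominal
    values with the pattern's CVs; numeric channels are held piecewise-
    constant per breath and logged every ``config.numeric_step_s``.
    """
    dt = config.sample_period_ms / 1000.0
    total_n = int(config.duration_s * 1000.0 / config.sample_period_ms)
    peep, ps = config.peep, config.pressure_support
    nominal_period = 60.0 / pattern.respiratory_rate

    paw_parts, flow_parts, vol_parts = [], [], []
    breath_starts_s: list[float] = []
    breath_values: list[dict[str, float]] = []
    periods: list[float] = []
    vts: list[float] = []
    t_cursor = 0.0
    n_done = 0
    while n_done < total_n:
        period = nominal_period * (1.0 + pattern.rate_cv * rng.standard_normal())
        period = float(np.clip(period, 0.4 * nominal_period, 2.5 * nominal_period))
        vt = pattern.tidal_volume * (1.0 + pattern.volume_cv * rng.standard_normal())
        vt = float(np.clip(vt, 0.3 * pattern.tidal_volume, 2.0 * pattern.tidal_volume))
        paw, flow, vol = simulate_breath(
            pattern, peep, ps, config.sample_period_ms,
            period_s=period, tidal_volume_l=vt,
        )
        paw_parts.append(paw)
        flow_parts.append(flow)
        vol_parts.append(vol)
        breath_starts_s.append(t_cursor)
        breath_values.append(
            _numeric_breath_values(pattern, config, period, vt, flow, paw, rng)
        )
        periods.append(period)
        vts.append(vt)
        n_done += paw.size
        t_cursor += paw.size * dt

    paw_all = np.concatenate(paw_parts)[:total_n]
    flow_all = np.concatenate(flow_parts)[:total_n]
    vol_all = np.concatenate(vol_parts)[:total_n]
    paw_all = paw_all + config.noise_paw * rng.standard_normal(total_n)
    flow_all = flow_all + config.noise_flow * rng.standard_normal(total_n)
    vol_all = vol_all + config.noise_volume * rng.standard_normal(total_n)

    waveform = WaveformRecording(
        patient_id=patient_id,
        sample_period_ms=config.sample_period_ms,
        paw=paw_all, flow=flow_all, volume=vol_all,
    )

    # numeric table: piecewise-constant per breath, sampled every step
    t_n = int(config.duration_s / config.numeric_step_s)
    step_times = np.arange(t_n) * config.numeric_step_s
    idx = np.searchsorted(np.asarray(breath_starts_s), step_times, side="right") - 1
    idx = np.clip(idx, 0, len(breath_values) - 1)
    channels = {
        name: np.array([breath_values[i][name] for i in idx])
        for name in CANONICAL_NUMERIC_CHANNELS
    }
    numeric = BreathNumericTable(
        patient_id=patient_id,
        step_period_s=config.numeric_step_s,
        channels=channels,
    )

    return SBTRecord(
        waveform=waveform,
        numeric=numeric,
        summary_frequency=60.0 / float(np.mean(periods)),
        summary_tidal_volume=float(np.mean(vts)),
    )


def _numeric_breath_values(
    pattern: BreathPattern,
    config: SimConfig,
    period: float,
    vt: float,
    flow: np.ndarray,
    paw: np.ndarray,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Per-breath values of the 25 monitoring channels (with logger noise)."""
    dys = pattern.dyssynchrony_level
    rr = 60.0 / period
    ti = pattern.inspiratory_fraction * period
    te = period - ti
    j = lambda x, s=0.02: x * (1.0 + s * rng.standard_normal())
    vt_ml = vt * 1000.0
    vals = {
        "vt_insp_ml": j(vt_ml),
        "vt_exp_spont_ml": j(0.97 * vt_ml),
        "resp_rate_bpm": j(rr, 0.01),
        "ie_ratio": j(ti / te),
        "p01_cmh2o": j(1.2 + 3.5 * dys, 0.10),
        "peak_pressure_cmh2o": j(float(paw.max())),
        "mean_pressure_cmh2o": j(float(paw.mean())),
        "peep_cmh2o": j(config.peep, 0.01),
        "minute_volume_l": j(vt * rr),
        "spont_minute_volume_l": j(vt * rr),
        "spont_rate_bpm": j(rr, 0.01),
        "rsbi_bpm_per_l": j(rr / vt, 0.03),
        "compliance_dyn_ml_cmh2o": j(vt_ml / max(config.pressure_support, 1.0), 0.05),
        "resistance_insp_cmh2o_l_s": j(8.0 + 4.0 * dys, 0.08),
        "resistance_exp_cmh2o_l_s": j(10.0 + 4.0 * dys, 0.08),
        "rc_expiratory_s": j(te / 3.0, 0.05),
        "insp_time_s": j(ti, 0.02),
        "exp_time_s": j(te, 0.02),
        "peak_insp_flow_l_min": j(float(flow.max()), 0.03),
        "peak_exp_flow_l_min": j(float(-flow.min()), 0.03),
        "leak_pct": abs(j(1.5, 0.5)),
        "pressure_support_cmh2o": j(config.pressure_support, 0.01),
        "work_of_breathing_j_l": j(0.3 + 0.9 * dys, 0.10),
        "pressure_time_product": j(60.0 + 150.0 * dys, 0.10),
        "fio2_pct": j(35.0, 0.01),
    }
    return vals


def inject_cough(
    rec: SBTRecord,
    times_s: Sequence[float],
    rng: Optional[np.random.Generator] = None,
) -> SBTRecord:
    """Superimpose cough artifacts at the given onset times.

    A cough is a ~0.6 s biphasic transient: a violent expiratory flow
    spike with an airway-pressure surge, then a brief inspiratory
    rebound.  Samples more than 2 s from every onset are bitwise
    unchanged; an onset outside the recording raises ValidationError.
    """
    if len(times_s) == 0:
        return rec
    wf = rec.waveform
    dt = wf.sample_period_ms / 1000.0
    T = len(wf)
    rng = rng or np.random.default_rng(0)
    paw = wf.paw.copy()
    flow = wf.flow.copy()
    vol = wf.volume.copy()
    n_tpl = int(round(0.6 / dt))
    t = np.arange(n_tpl) * dt
    for onset in times_s:
        if not (0.0 <= onset <= wf.duration_s):
            raise ValidationError(
                f"cough time {onset} s outside recording (0..{wf.duration_s:.1f} s)"
            )
        amp = 1.0 + 0.1 * abs(rng.standard_normal())
        # expiratory blast (gamma-shaped pulse peaking at 200*amp L/min,
        # well above any physiological peak flow), then a brief rebound
        tau = 0.05
        pulse = (t / tau) * np.exp(1.0 - t / tau)
        blast = -200.0 * amp * pulse
        rebound = 35.0 * amp * np.exp(-((t - 0.35) / 0.08) ** 2)
        flow_tpl = blast + rebound
        paw_tpl = 25.0 * amp * pulse
        i0 = int(round(onset / dt))
        i1 = min(T, i0 + n_tpl)
        if i1 <= i0:
            continue
        flow[i0:i1] += flow_tpl[: i1 - i0]
        paw[i0:i1] += paw_tpl[: i1 - i0]
        vol[i0:i1] += np.cumsum(flow_tpl[: i1 - i0]) * dt * 1000.0 / 60.0
    new_wf = WaveformRecording(
        patient_id=wf.patient_id,
        sample_period_ms=wf.sample_period_ms,
        paw=paw, flow=flow, volume=vol,
    )
    return SBTRecord(
        waveform=new_wf,
        numeric=rec.numeric,
        label=rec.label,
        summary_frequency=rec.summary_frequency,
        summary_tidal_volume=rec.summary_tidal_volume,
    )


def simulate_cohort(
    priors: Optional[ProfilePriors] = None,
    config: Optional[SimConfig] = None,
) -> Cohort:
    """Labelled cohort with exactly ``round(n * prevalence)`` failures.

    Label assignment is stratified (not Bernoulli) and the whole cohort is
    a pure function of ``config.seed``.
    """
    priors = priors or default_priors()
    config = config or SimConfig()
    n = config.n_patients
    n_fail = int(round(n * config.failure_prevalence))
    labels = ["failure"] * n_fail + ["success"] * (n - n_fail)
    root = np.random.SeedSequence(config.seed)
    order_rng = np.random.default_rng(root.spawn(1)[0])
    order = order_rng.permutation(n)
    labels = [labels[i] for i in order]

    records = []
    patient_seeds = root.spawn(n + 1)[1:]
    for i, (label, ss) in enumerate(zip(labels, patient_seeds)):
        rng = np.random.default_rng(ss)
        pattern = priors.sample(label, rng)
        rec = simulate_recording(
            pattern, config, rng, patient_id=f"sim-{i:04d}"
        )
        if config.cough_rate_per_min > 0:
            n_coughs = int(rng.poisson(
                config.cough_rate_per_min * config.duration_s / 60.0
            ))
            if n_coughs:
                times = np.sort(rng.uniform(0, config.duration_s - 1.0, n_coughs))
                rec = inject_cough(rec, times.tolist(), rng)
        records.append(rec.with_label(label))
    return Cohort(tuple(records))


# ---------------------------------------------------------------------------
# Cohort directory layout: <id>_waveform.csv, <id>_numeric.csv, labels.csv,
# summaries.csv


def save_cohort(cohort: Cohort, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = {}
    summaries = []
    for rec in cohort:
        pid = rec.patient_id
        write_waveform_csv(rec.waveform, out / f"{pid}_waveform.csv")
        write_numeric_csv(rec.numeric, out / f"{pid}_numeric.csv")
        if rec.label is not None:
            labels[pid] = rec.label
        summaries.append(
            (pid, rec.summary_frequency, rec.summary_tidal_volume)
        )
    if labels:
        write_labels_manifest(labels, out / "labels.csv")
    with open(out / "summaries.csv", "w") as fh:
        fh.write("patient_id,summary_frequency,summary_tidal_volume\n")
        for pid, f, v in summaries:
            fh.write(f"{pid},{'' if f is None else f'{f:.6g}'},"
                     f"{'' if v is None else f'{v:.6g}'}\n")
    return out


def load_cohort(in_dir) -> Cohort:
    root = Path(in_dir)
    if not root.is_dir():
        raise FileNotFoundError(root)
    labels = {}
    if (root / "labels.csv").exists():
        labels = read_labels_manifest(root / "labels.csv")
    summaries: dict[str, tuple[Optional[float], Optional[float]]] = {}
    if (root / "summaries.csv").exists():
        import csv

        with open(root / "summaries.csv") as fh:
            for row in csv.DictReader(fh):
                f = float(row["summary_frequency"]) if row["summary_frequency"] else None
                v = float(row["summary_tidal_volume"]) if row["summary_tidal_volume"] else None
                summaries[row["patient_id"]] = (f, v)
    records = []
    for wf_path in sorted(root.glob("*_waveform.csv")):
        pid = wf_path.stem.removesuffix("_waveform")
        wf = read_waveform_csv(wf_path, patient_id=pid)
        num = read_numeric_csv(root / f"{pid}_numeric.csv", patient_id=pid)
        f, v = summaries.get(pid, (None, None))
        records.append(SBTRecord(
            waveform=wf, numeric=num, label=labels.get(pid),
            summary_frequency=f, summary_tidal_volume=v,
        ))
    return Cohort(tuple(records))
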