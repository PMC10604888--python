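"""Physical and statistical properties of the synthetic SBT generator."""

import numpy as np
import pytest

from weanwave.sbt_sim import (
    BreathPattern,
    SimConfig,
    default_priors,
    inject_cough,
    simulate_breath,
    simulate_cohort,
    simulate_recording,
)
from weanwave.vent_data import ValidationError


PATTERNS = [
    BreathPattern(respiratory_rate=16, tidal_volume=0.5),
    BreathPattern(respiratory_rate=32, tidal_volume=0.2,
                  dyssynchrony_level=0.8, inspiratory_fraction=0.4),
    BreathPattern(respiratory_rate=22, tidal_volume=0.35,
                  dyssynchrony_level=1.0),
]


@pytest.mark.parametrize("pattern", PATTERNS)
def test_breath_volume_conservation(pattern):
    """Volume peaks at the tidal volume and returns to ~0 at end-expiration."""
    paw, flow, vol = simulate_breath(pattern, peep=5, ps=6, dt_ms=15)
    vt_ml = pattern.tidal_volume * 1000
    assert abs(vol.max() - vt_ml) <= 0.02 * vt_ml
    assert abs(vol[-1]) <= 0.05 * vt_ml


@pytest.mark.parametrize("pattern", PATTERNS)
def test_breath_flow_signs(pattern):
    """Flow is positive through inspiration and negative through expiration."""
    _, flow, vol = simulate_breath(pattern, peep=5, ps=6, dt_ms=15)
    peak = int(np.argmax(vol))
    assert np.all(flow[:peak + 1] > 0)
    assert np.all(flow[peak + 1:] < 0)


def test_breath_no_dip_when_no_dyssynchrony():
    pattern = BreathPattern(respiratory_rate=18, tidal_volume=0.45,
                            dyssynchrony_level=0.0)
    paw, flow, vol = simulate_breath(pattern, peep=5, ps=6, dt_ms=15)
    n_in = int(np.argmax(vol)) + 1
    assert paw[:n_in].min() >= 5.0 - 1e-9


def test_breath_dyssynchrony_dips_below_support():
    calm = BreathPattern(respiratory_rate=20, tidal_volume=0.4,
                         dyssynchrony_level=0.0)
    effort = BreathPattern(respiratory_rate=20, tidal_volume=0.4,
                           dyssynchrony_level=1.0)
    paw0, _, _ = simulate_breath(calm, peep=5, ps=6, dt_ms=15)
    paw1, _, _ = simulate_breath(effort, peep=5, ps=6, dt_ms=15)
    assert paw1.min() < paw0.min() - 1.0


def test_invalid_pattern_rejected():
    with pytest.raises(ValidationError):
        BreathPattern(respiratory_rate=20, tidal_volume=0.4,
                      inspiratory_fraction=1.2)


def test_recording_lengths_30min():
    """A 30-minute SBT yields 120,000 waveform samples and 3,600 numeric
    steps at the default cadences (training crops remain feasible)."""
    cfg = SimConfig(n_patients=1, duration_s=1800.0, seed=3)
    rec = simulate_recording(PATTERNS[0], cfg, np.random.default_rng(3))
    assert len(rec.waveform) == 120_000
    assert len(rec.numeric) == 3_600
    assert len(rec.numeric) >= 3_500


def test_recording_deterministic_under_seed():
    cfg = SimConfig(n_patients=1, duration_s=60.0, seed=5)
    a = simulate_recording(PATTERNS[1], cfg, np.random.default_rng(5))
    b = simulate_recording(PATTERNS[1], cfg, np.random.default_rng(5))
    assert np.array_equal(a.waveform.as_array(), b.waveform.as_array())
    assert np.array_equal(a.numeric.as_array(), b.numeric.as_array())


def test_recording_summaries_match_pattern():
    cfg = SimConfig(n_patients=1, duration_s=120.0, seed=9)
    pattern = BreathPattern(respiratory_rate=24, tidal_volume=0.3)
    rec = simulate_recording(pattern, cfg, np.random.default_rng(9))
    assert rec.summary_frequency == pytest.approx(24, rel=0.15)
    assert rec.summary_tidal_volume == pytest.approx(0.3, rel=0.15)


def test_cohort_stratified_label_counts():
    cfg = SimConfig(n_patients=10, failure_prevalence=0.3, duration_s=30.0,
                    cough_rate_per_min=0.0, seed=1)
    cohort = simulate_cohort(default_priors(), cfg)
    assert sum(lab == "failure" for lab in cohort.labels) == 3


def test_cohort_rsbi_separation():
    """Failure records have higher mean RSBI than success records."""
    cfg = SimConfig(n_patients=20, failure_prevalence=0.5, duration_s=60.0,
                    cough_rate_per_min=0.0, seed=2)
    cohort = simulate_cohort(default_priors(), cfg)
    rsbi = {lab: [] for lab in ("success", "failure")}
    for r in cohort:
        rsbi[r.label].append(r.summary_frequency / r.summary_tidal_volume)
    assert np.mean(rsbi["failure"]) > np.mean(rsbi["success"])


def test_priors_expected_rsbi_straddles_105():
    priors = default_priors()
    assert priors.mean_rsbi("failure") > 105 > priors.mean_rsbi("success")


def test_cohort_reproducible_bytes():
    cfg = SimConfig(n_patients=4, failure_prevalence=0.25, duration_s=30.0,
                    seed=13)
    a = simulate_cohort(default_priors(), cfg)
    b = simulate_cohort(default_priors(), cfg)
    assert a.labels == b.labels
    for ra, rb in zip(a, b):
        assert np.array_equal(ra.waveform.as_array(), rb.waveform.as_array())


def test_cohort_invalid_prevalence_rejected():
    with pytest.raises(ValidationError):
        SimConfig(n_patients=4, failure_prevalence=1.5)


def test_cough_empty_times_is_identity(tiny_record):
    out = inject_cough(tiny_record, [])
    assert out is tiny_record


def test_cough_increases_peak_flow(tiny_record):
    out = inject_cough(tiny_record, [10.0], np.random.default_rng(0))
    assert np.max(np.abs(out.waveform.flow)) > np.max(np.abs(tiny_record.waveform.flow))


def test_cough_locality(tiny_record):
    """Samples more than 2 s from any cough are bitwise unchanged."""
    onset = 20.0
    out = inject_cough(tiny_record, [onset], np.random.default_rng(0))
    dt = tiny_record.waveform.sample_period_ms / 1000.0
    lo = int((onset - 2.0) / dt)
    hi = int((onset + 2.0) / dt)
    for ch in ("paw", "flow", "volume"):
        a = getattr(tiny_record.waveform, ch)
        b = getattr(out.waveform, ch)
        assert np.array_equal(a[:lo], b[:lo])
        assert np.array_equal(a[hi:], b[hi:])


def test_cough_outside_recording_rejected(tiny_record):
    with pytest.raises(ValidationError):
        inject_cough(tiny_record, [10_000.0])
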