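"""Transient detection, peeling, evoked amplitudes, BBN reliability."""

import numpy as np
import pytest

from tonopipe.synthetic import transient_template
from tonopipe.transients import (
    DetectionParams,
    bbn_reliability,
    detect_transients,
    evoked_amplitude,
    peel,
)
from tonopipe.twophoton import DffTrace

FS = 30.0


def _trace(values):
    return DffTrace(np.asarray(values, float), FS, f0=1.0)


def _with_transient(n, onset_idx, amp, noise_sd=0.0, seed=0, **kin):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, noise_sd, n) if noise_sd else np.zeros(n)
    tmpl = amp * transient_template(FS, **kin)
    stop = min(onset_idx + len(tmpl), n)
    x[onset_idx:stop] += tmpl[: stop - onset_idx]
    return _trace(x)


def test_zero_trace_yields_no_events():
    assert detect_transients(_trace(np.zeros(600))) == []


def test_single_transient_detected_with_accurate_onset():
    """A 5-sigma transient gives exactly one event, onset within 2 frames."""
    for seed in range(5):
        dff = _with_transient(1800, 600, amp=0.2, noise_sd=0.04, seed=seed)
        events = detect_transients(dff)
        assert len(events) == 1
        assert abs(events[0].onset_s - 600 / FS) <= 2 / FS + 1e-9
        assert events[0].peak_amplitude == pytest.approx(0.2, rel=0.35)
        assert events[0].peak_s >= events[0].onset_s


def test_false_positive_rate_on_pure_noise():
    """Pure-noise traces (60 s, 30 Hz): <= 0.05 events/s across seeds."""
    n_events = 0
    for seed in range(40):
        rng = np.random.default_rng(1000 + seed)
        n_events += len(detect_transients(_trace(rng.normal(0, 0.04, 1800))))
    assert n_events / (40 * 60.0) <= 0.05


def test_detection_monotone_in_noise_k():
    dff = _with_transient(3600, 300, 0.12, noise_sd=0.04, seed=3)
    counts = [
        len(detect_transients(dff, DetectionParams(noise_k=k))) for k in (2.0, 3.0, 4.0, 6.0)
    ]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_peel_conservation():
    """Components + residual reproduce the input to numerical tolerance."""
    rng = np.random.default_rng(0)
    x = rng.normal(0, 0.03, 2400)
    tmpl = transient_template(FS)
    for onset in (300, 800, 815, 1600):
        x[onset : onset + len(tmpl)] += 0.25 * tmpl[: len(x) - onset]
    dff = _trace(x)
    res = peel(dff)
    rms = np.sqrt(np.mean((res.components + res.residual - x) ** 2))
    assert rms <= 1e-6


def test_peel_separates_overlapping_pair():
    """Two equal transients 0.5 s apart: single-pass detection merges them,
    peeling recovers both."""
    x = np.zeros(900)
    tmpl = transient_template(FS)
    for onset in (300, 315):
        x[onset : onset + len(tmpl)] += 0.25 * tmpl[: len(x) - onset]
    dff = _trace(x)
    assert len(detect_transients(dff)) == 1
    res = peel(dff)
    assert len(res.events) == 2
    assert res.converged


def test_peel_matches_detection_when_well_separated():
    """Non-overlapping transients (> 5 decay constants apart): peeling finds
    the same events as plain detection."""
    x = np.zeros(3000)
    tmpl = transient_template(FS)
    onsets = (300, 900, 1800)
    for onset in onsets:
        x[onset : onset + len(tmpl)] += 0.3 * tmpl[: len(x) - onset]
    dff = _trace(x)
    det = detect_transients(dff)
    res = peel(dff)
    assert len(det) == len(res.events) == len(onsets)
    assert np.allclose(sorted(e.onset_s for e in det), sorted(res.onsets_s), atol=2 / FS)


def test_evoked_amplitude_flat_and_rectangular():
    flat = _trace(np.zeros(600))
    assert evoked_amplitude(flat, onset_s=10.0) == pytest.approx(0.0, abs=1e-12)
    x = np.zeros(600)
    x[310:340] = 0.5  # rectangular pulse spanning the peak window
    assert evoked_amplitude(_trace(x), onset_s=10.0) == pytest.approx(0.5)


def test_evoked_amplitude_recovers_template_peak():
    dff = _with_transient(900, 450, amp=0.3)
    amp = evoked_amplitude(dff, onset_s=450 / FS - 0.01)
    assert amp == pytest.approx(0.3, rel=0.10)


def test_evoked_amplitude_bounds_error():
    with pytest.raises(ValueError):
        evoked_amplitude(_trace(np.zeros(100)), onset_s=3.0)


@pytest.mark.parametrize(
    "n_resp, expect_rate, expect_reliable",
    [(7, 0.7, True), (5, 0.5, True), (2, 0.2, False), (0, 0.0, False)],
)
def test_bbn_reliability_counting(n_resp, expect_rate, expect_reliable):
    """Success rate = fraction of evoked BBN presentations; Reliable at the
    inclusive >= 50% boundary."""
    onsets = 10.0 + 10.0 * np.arange(10)
    x = np.zeros(int(130 * FS))
    tmpl = transient_template(FS)
    for o in onsets[:n_resp]:
        i = int((o + 0.1) * FS)
        x[i : i + len(tmpl)] += 0.3 * tmpl[: len(x) - i]
    out = bbn_reliability(_trace(x), onsets)
    assert out["success_rate"] == pytest.approx(expect_rate)
    assert out["active"] == (n_resp > 0)
    assert out["reliable"] == expect_reliable


def test_invalid_params():
    with pytest.raises(ValueError):
        DetectionParams(noise_k=-1)
    with pytest.raises(ValueError):
        DetectionParams(noise_window_s=0)
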