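"""FRA construction, classification, BF, shapes, bandwidths, MI."""

import numpy as np
import pandas as pd
import pytest

from tonopipe.pipeline import analyze_neuron
from tonopipe.synthetic import sample_tuned, standard_protocol
from tonopipe.transients import TransientEvent
from tonopipe.tuning import (
    FRA,
    bandwidths,
    best_frequency,
    classify_neuron,
    classify_shape,
    monotonicity,
)

STEP = np.log2(20) / 10


def _fra(mean_resp, region=None, sig=None, protocol=None):
    mean_resp = np.asarray(mean_resp, float)
    sig = np.asarray(sig, bool) if sig is not None else mean_resp > 0
    region = np.asarray(region, bool) if region is not None else sig
    return FRA(mean_resp, np.repeat(mean_resp[..., None], 5, axis=2), sig, region,
               protocol or standard_protocol(seed=0))


def _region_from_widths(widths_by_level, bf_idx=5, n_freq=11):
    """Boolean (freq, level) region with the given per-level widths in
    frequencies, centered on bf_idx."""
    region = np.zeros((n_freq, len(widths_by_level)), dtype=bool)
    for l, w in enumerate(widths_by_level):
        if w <= 0:
            continue
        lo = max(0, min(bf_idx - (w - 1) // 2, n_freq - w))
        region[lo : lo + w, l] = True
    return region


@pytest.fixture(scope="module")
def measured():
    from tonopipe.synthetic import get_preset

    protocol = standard_protocol(seed=0)
    neus = sample_tuned(get_preset("TR"), 25, seed=11, protocol=protocol)
    rows = [
        analyze_neuron(n, protocol, seed=11, noise_scale=0.0, trial_jitter_sd=0.0)
        for n in neus
    ]
    return neus, pd.DataFrame(rows)


class TestNoiselessRecovery:
    """On noiseless synthetic neurons the measured FRA equals the truth."""

    def test_bf_recovery_exact(self, measured):
        neus, df = measured
        assert (df["bf_khz"].to_numpy() == [n.bf_khz for n in neus]).all()

    def test_bwmax_equals_generating_width(self, measured):
        neus, df = measured
        truth = np.array([n.bwmax_steps * STEP for n in neus])
        assert np.allclose(df["bwmax_oct"].to_numpy(), truth)

    def test_all_classified_tuned(self, measured):
        _, df = measured
        assert (df["cls"] == "tuned").all()


def test_silent_trace_classifies_silent(protocol):
    from tonopipe.transients import peel
    from tonopipe.twophoton import DffTrace

    dff = DffTrace(np.zeros(int(protocol.duration_s * 30)), 30.0, 1.0)
    res = peel(dff)
    from tonopipe.tuning import build_fra

    fra = build_fra(dff, protocol, events=res)
    assert not fra.sig_mask.any()
    assert classify_neuron(fra, res) == "silent"


def test_largest_region_wins_ties_by_size():
    """Two disjoint significant blobs of 6 and 3 cells: the 6-cell blob is
    kept as the FRA."""
    sig = np.zeros((11, 6), dtype=bool)
    sig[0:2, 0:3] = True  # 6-cell blob
    sig[8, 4:6] = True
    sig[9, 4] = True  # 3-cell blob
    mean = sig.astype(float)
    from tonopipe.tuning import _largest_component

    region = _largest_component(sig, mean)
    assert region.sum() == 6
    assert region[0:2, 0:3].all()


def test_best_frequency_single_column_and_ties(protocol):
    mean = np.zeros((11, 6))
    mean[7] = 1.0
    assert best_frequency(_fra(mean)) == pytest.approx(protocol.frequencies_khz[7])
    mean2 = np.zeros((11, 6))
    mean2[3] = 1.0
    mean2[6] = 1.0  # exact tie -> lower frequency
    assert best_frequency(_fra(mean2)) == pytest.approx(protocol.frequencies_khz[3])


def test_best_frequency_requires_region():
    mean = np.zeros((11, 6))
    with pytest.raises(ValueError):
        best_frequency(_fra(mean, region=np.zeros((11, 6), bool), sig=np.zeros((11, 6), bool)))


class TestShapeRule:
    def test_v_shape_growing_widths(self):
        region = _region_from_widths([1, 1, 2, 3, 4, 5])
        mean = region.astype(float) * np.linspace(0.5, 1.0, 6)[None, :]
        assert classify_shape(_fra(mean, region=region)) == "V"

    def test_i_shape_constant_widths(self):
        region = _region_from_widths([2, 2, 2, 2, 2, 2])
        mean = region.astype(float)
        assert classify_shape(_fra(mean, region=region)) == "I"

    def test_o_shape_interior_band(self):
        """Region spanning 40-60 dB only with its peak at 50 dB."""
        region = _region_from_widths([0, 2, 3, 2, 0, 0])
        mean = region.astype(float)
        mean[:, 2] *= 2.0  # peak at 50 dB
        assert classify_shape(_fra(mean, region=region)) == "O"


def test_bandwidth_arithmetic(protocol):
    """Region 5 frequencies wide at one level -> BW_max = 4 steps = 1.73 oct."""
    region = _region_from_widths([0, 0, 0, 0, 0, 5])
    mean = region.astype(float)
    bf = best_frequency(_fra(mean, region=region))
    hp, q, bwmax = bandwidths(_fra(mean, region=region), bf)
    assert bwmax == pytest.approx(4 * STEP, abs=1e-9)
    assert bwmax == pytest.approx(1.729, abs=2e-3)


def test_single_effective_frequency_degenerate(protocol):
    region = _region_from_widths([0, 0, 0, 0, 0, 1])
    mean = region.astype(float)
    bf = best_frequency(_fra(mean, region=region))
    hp, q, bwmax = bandwidths(_fra(mean, region=region), bf)
    assert hp == 0.0
    assert q is None
    assert bwmax == 0.0


def test_q_value_khz_convention(protocol):
    """BF 8.94 kHz with effective band 6.63-12.07 kHz -> Q = 1.64."""
    mean = np.zeros((11, 6))
    mean[4:7, :] = 0.8  # effective: indices 4..6 = 6.63, 8.94, 12.07 kHz
    mean[5, :] = 1.0
    fra = _fra(mean)
    bf = best_frequency(fra)
    assert bf == pytest.approx(8.94, abs=0.01)
    hp, q, _ = bandwidths(fra, bf)
    assert hp == pytest.approx(2 * STEP)
    width = protocol.frequencies_khz[6] - protocol.frequencies_khz[4]
    assert q == pytest.approx(bf / width)
    assert q == pytest.approx(1.64, abs=0.01)


class TestMonotonicity:
    def test_max_at_top_level(self):
        mean = np.zeros((11, 6))
        mean[5] = [0.1, 0.2, 0.4, 0.6, 0.8, 1.0]
        fra = _fra(mean)
        mi, mono = monotonicity(fra, best_frequency(fra))
        assert mi == pytest.approx(1.0)
        assert mono is True

    def test_zero_at_top_level(self):
        mean = np.zeros((11, 6))
        mean[5] = [0.2, 0.5, 1.0, 0.5, 0.2, 0.0]
        fra = _fra(mean)
        mi, mono = monotonicity(fra, best_frequency(fra))
        assert mi == pytest.approx(0.0)
        assert mono is False

    def test_by_hand_example(self):
        """BF-column responses (2,4,8,6,3,1) -> MI = 1/8, non-monotonic."""
        mean = np.zeros((11, 6))
        mean[5] = [2, 4, 8, 6, 3, 1]
        fra = _fra(mean)
        mi, mono = monotonicity(fra, best_frequency(fra))
        assert mi == pytest.approx(0.125)
        assert mono is False

    def test_mi_clamped_to_unit_interval(self, rng):
        for _ in range(50):
            mean = rng.normal(0, 1, (11, 6))
            fra = _fra(mean, region=np.ones((11, 6), bool), sig=np.ones((11, 6), bool))
            mi, _ = monotonicity(fra, best_frequency(fra))
            if mi is not None:
                assert 0.0 <= mi <= 1.0

    def test_all_zero_reports_missing(self):
        mean = np.zeros((11, 6))
        fra = _fra(mean, region=np.ones((11, 6), bool), sig=np.ones((11, 6), bool))
        mi, mono = monotonicity(fra, 8.94)
        assert mi is None and mono is None
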