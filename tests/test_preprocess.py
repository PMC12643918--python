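import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

from pulsefeat import ScreenReason, lowpass_filter, normalize_minmax, screen_window

from conftest import FS, make_window


def pulse_like(n_peaks, n=1024, base=80.0, amp=40.0):
    """Positive window with exactly n_peaks prominent peaks."""
    t = np.linspace(0, 1, n, endpoint=False)
    y = np.full(n, base)
    for k in range(n_peaks):
        c = (k + 0.5) / n_peaks
        y += amp * np.exp(-0.5 * ((t - c) / 0.02) ** 2)
    return y


class TestScreening:
    def test_negative_sample_rejected(self):
        y = pulse_like(5)
        y[100] = -1.0
        res = screen_window(make_window(y))
        assert not res.accepted and res.reason == ScreenReason.NONPOSITIVE_VALUES

    def test_zero_sample_rejected(self):
        y = pulse_like(5)
        y[0] = 0.0
        assert screen_window(make_window(y)).reason == ScreenReason.NONPOSITIVE_VALUES

    @pytest.mark.parametrize(
        "n_peaks,reason",
        [
            (2, ScreenReason.TOO_FEW_PEAKS),
            (5, ScreenReason.OK),
            (11, ScreenReason.TOO_MANY_PEAKS),
        ],
    )
    def test_peak_count_rules(self, n_peaks, reason):
        res = screen_window(make_window(pulse_like(n_peaks)))
        assert res.reason == reason
        assert res.accepted == (reason == ScreenReason.OK)

    @given(scale=st.floats(0.1, 50.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_verdict_invariant_to_positive_rescaling(self, scale):
        y = pulse_like(5)
        v1 = screen_window(make_window(y))
        v2 = screen_window(make_window(scale * y))
        assert v1.reason == v2.reason

    def test_empty_window_error(self):
        with pytest.raises(ValueError):
            screen_window(make_window([]))


class TestLowpass:
    def test_dc_gain_is_unity(self):
        y = np.full(1024, 95.0)
        out = lowpass_filter(make_window(y))
        np.testing.assert_allclose(out.samples, y, atol=1e-9)

    def test_sinusoid_attenuation_matches_transfer_function(self):
        # zero-phase application squares the magnitude response
        f0 = 50.0
        t = np.arange(1024) / FS
        y = np.sin(2 * np.pi * f0 * t)
        out = lowpass_filter(make_window(y)).samples
        sos = sps.butter(4, 16.0, btype="low", fs=FS, output="sos")
        _, h = sps.sosfreqz(sos, worN=[f0], fs=FS)
        expected = np.abs(h[0]) ** 2
        measured = np.max(np.abs(out[256:768])) / np.max(np.abs(y[256:768]))
        assert measured == pytest.approx(expected, rel=0.05)

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="cutoff"):
            lowpass_filter(make_window(np.zeros(100)), cutoff=128.0)


class TestNormalize:
    def test_basic(self):
        out = normalize_minmax(make_window([2.0, 4.0, 6.0]))
        np.testing.assert_allclose(out.samples, [0.0, 0.5, 1.0])
        assert out.y_min == 2.0 and out.y_max == 6.0

    def test_unit_span_input_unchanged(self):
        y = np.linspace(0, 1, 11)
        out = normalize_minmax(make_window(y))
        np.testing.assert_allclose(out.samples, y)

    def test_constant_input_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            normalize_minmax(make_window(np.full(10, 3.0)))

    @given(a=st.floats(0.01, 100.0), b=st.floats(-500.0, 500.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(7)
        y = rng.random(64) * 10
        n1 = normalize_minmax(make_window(y)).samples
        n2 = normalize_minmax(make_window(a * y + b)).samples
        np.testing.assert_allclose(n1, n2, atol=1e-9)
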