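import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulsefeat import (
    AnnotationSet,
    bland_altman,
    compute_metrics,
    evaluate_annotations,
    match_landmarks,
)

FS = 256.0


def ann(**marks):
    return AnnotationSet(marks={k: np.array(v, dtype=int) for k, v in marks.items()})


class TestMatching:
    def test_within_two_samples_is_tp(self):
        c = match_landmarks(ann(SPO=[102]), ann(SPO=[100]), fs=FS)
        assert (c.tp["SPO"], c.fp["SPO"], c.fn["SPO"]) == (1, 0, 0)

    def test_three_samples_away_is_fp_plus_fn(self):
        c = match_landmarks(ann(SPO=[103]), ann(SPO=[100]), fs=FS)
        assert (c.tp["SPO"], c.fp["SPO"], c.fn["SPO"]) == (0, 1, 1)

    def test_one_to_one_double_detection(self):
        c = match_landmarks(ann(SPP=[99, 101]), ann(SPP=[100]), fs=FS)
        assert (c.tp["SPP"], c.fp["SPP"], c.fn["SPP"]) == (1, 1, 0)

    def test_nearest_detection_wins(self):
        c = match_landmarks(ann(DN=[100, 150]), ann(DN=[101, 149]), fs=FS)
        assert c.tp["DN"] == 2
        assert sorted(c.pairs["DN"]) == [(101 / FS, 100 / FS), (149 / FS, 150 / FS)]

    def test_invalid_fs(self):
        with pytest.raises(ValueError):
            match_landmarks(ann(), ann(), fs=0.0)

    @given(
        det=st.lists(st.integers(0, 5000), max_size=25),
        ref=st.lists(st.integers(0, 5000), max_size=25),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_count_totals_are_conserved(self, det, ref):
        d, r = ann(SPO=det), ann(SPO=ref)
        c = match_landmarks(d, r, fs=FS)
        assert c.tp["SPO"] + c.fn["SPO"] == len(r["SPO"])
        assert c.tp["SPO"] + c.fp["SPO"] == len(d["SPO"])


class TestMetrics:
    def test_worked_example_nine_one_zero(self):
        m = compute_metrics(tp=9, fp=1, fn=0)
        assert m.se == pytest.approx(1.0)
        assert m.ppv == pytest.approx(0.9)
        assert m.f1 == pytest.approx(2 * 1.0 * 0.9 / 1.9)
        assert m.er == pytest.approx(0.1)

    def test_balanced_counts(self):
        m = compute_metrics(tp=1, fp=1, fn=1)
        assert (m.se, m.ppv, m.f1) == (0.5, 0.5, 0.5)
        assert m.er == pytest.approx(1.0)  # asymmetric denominator TP+FP

    def test_symmetric_error_rate_variant(self):
        m = compute_metrics(tp=1, fp=1, fn=1, symmetric_er=True)
        assert m.er == pytest.approx(2 / 3)

    def test_all_zero_counts_warn_and_nan(self):
        with pytest.warns(RuntimeWarning):
            m = compute_metrics(tp=0, fp=0, fn=0)
        assert np.isnan(m.se) and np.isnan(m.ppv) and np.isnan(m.f1) and np.isnan(m.er)

    @given(k=st.integers(1, 50))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_invariant_under_count_scaling(self, k):
        a = compute_metrics(tp=6, fp=2, fn=1)
        b = compute_metrics(tp=6 * k, fp=2 * k, fn=1 * k)
        assert a.se == pytest.approx(b.se)
        assert a.ppv == pytest.approx(b.ppv)
        assert a.f1 == pytest.approx(b.f1)
        assert a.er == pytest.approx(b.er)


class TestBlandAltman:
    def test_identical_times_zero_bias_zero_loa(self):
        s = bland_altman([(1.0, 1.0), (2.0, 2.0), (3.0, 3.0)])
        assert s.bias == 0.0 and s.loa_lower == 0.0 and s.loa_upper == 0.0

    def test_plus_minus_one_closed_form(self):
        s = bland_altman([(0.0, -1.0), (0.0, 1.0)])
        assert s.bias == pytest.approx(0.0)
        assert s.sd == pytest.approx(np.sqrt(2.0))
        assert s.loa_upper == pytest.approx(1.96 * np.sqrt(2.0))
        assert s.loa_lower == pytest.approx(-1.96 * np.sqrt(2.0))

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([(0.0, 0.0)])

    def test_loa_brackets_bias(self):
        rng = np.random.default_rng(0)
        pairs = [(t, t + rng.normal(0.001, 0.002)) for t in np.arange(50.0)]
        s = bland_altman(pairs)
        assert s.loa_lower <= s.bias <= s.loa_upper


class TestEvaluateTable:
    def test_pooled_row_aggregates(self):
        det = ann(SPO=[100, 200], SPP=[110, 210], DN=[130], DPP=[150, 250])
        ref = ann(SPO=[100, 200], SPP=[110, 210], DN=[130, 230], DPP=[150, 250])
        table = evaluate_annotations(det, ref, fs=FS)
        assert table["SPO"]["se"] == 1.0
        assert table["DN"]["fn"] == 1
        pooled = table["pooled"]
        assert pooled["tp"] == 7 and pooled["fn"] == 1 and pooled["fp"] == 0
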