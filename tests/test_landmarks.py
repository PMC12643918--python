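import numpy as np
import pytest

from pulsefeat import (
    AnnotationSet,
    CycleLandmarks,
    LandmarkParams,
    delineate_cycles,
    find_signed_extrema,
    landmarks_to_record,
)
from pulsefeat.landmarks import Polarity

from conftest import FS, detect_on_window, make_window


class TestSignedExtrema:
    def test_single_sine_period(self):
        t = np.linspace(0, 1, 101, endpoint=False)
        ext = find_signed_extrema(np.sin(2 * np.pi * t))
        peaks = [e for e in ext if e.polarity == Polarity.PEAK]
        valleys = [e for e in ext if e.polarity == Polarity.VALLEY]
        assert len(peaks) == 1 and peaks[0].value > 0
        assert len(valleys) == 1 and valleys[0].value < 0

    def test_constant_sequence_has_none(self):
        assert find_signed_extrema(np.zeros(50)) == []

    def test_plateau_collapses_to_first_index(self):
        y = np.array([0, 1, 2, 2, 2, 1, 0], dtype=float)
        ext = find_signed_extrema(y)
        assert [e.index for e in ext if e.polarity == Polarity.PEAK] == [2]

    def test_boundaries_excluded(self):
        y = np.array([5.0, 1.0, 4.0])
        ext = find_signed_extrema(y)
        assert [e.index for e in ext] == [1]


class TestCycleLandmarksType:
    def test_ordering_enforced(self):
        with pytest.raises(ValueError, match="order"):
            CycleLandmarks(spo=10, spp=5, dn=20, dpe=30)

    def test_optional_dpp(self):
        c = CycleLandmarks(spo=0, spp=10, dn=40, dpe=100, dpp=None)
        assert c.as_dict()["DPP"] is None


class TestDelineation:
    def test_synthetic_window_recovers_all_cycles(self, clean_window):
        """Every ground-truth landmark is found within +-2 samples."""
        window, truth = clean_window
        detected, cycles, dec, _ = detect_on_window(window)
        assert len(cycles) >= 3
        for cyc in cycles:
            d = cyc.as_dict()
            order = [d["SPO"], d["SPP"], d["DN"]]
            if d["DPP"] is not None:
                order.append(d["DPP"])
            order.append(d["DPE"])
            assert all(b > a for a, b in zip(order, order[1:]))
        for lm in ("SPO", "SPP", "DN", "DPP", "DPE"):
            ref = truth.annotations[lm]
            det = detected[lm]
            assert len(det) > 0
            for r in ref:
                assert np.min(np.abs(det - r)) <= 2, f"{lm} at {r} missed"

    def test_sign_conditions_hold_on_nsts(self, clean_window):
        window, _ = clean_window
        _, cycles, dec, _ = detect_on_window(window)
        y = dec.nsts
        for cyc in cycles:
            assert y[cyc.spp] > 0
            assert y[cyc.spo] < 0 and y[cyc.dn] < 0 and y[cyc.dpe] < 0
            if cyc.dpp is not None:
                assert y[cyc.dpp] > 0

    def test_separation_conditions_hold(self, clean_window):
        window, _ = clean_window
        _, cycles, _, _ = detect_on_window(window)
        min_sep = round(0.1 * FS)
        for cyc in cycles:
            assert cyc.dn - cyc.spp >= min_sep
            if cyc.dpp is not None:
                assert cyc.dpe - cyc.dpp >= min_sep

    def test_adjacent_cycles_share_boundary(self, clean_window):
        window, _ = clean_window
        _, cycles, _, _ = detect_on_window(window)
        for a, b in zip(cycles, cycles[1:]):
            assert a.dpe == b.spo

    def test_notch_separation_rule_picks_second_candidate(self):
        """A DN candidate 0.05 s after SPP is rejected for one 0.15 s after."""
        fs = 256.0
        n = 600
        y = np.zeros(n)

        def bump(center, width, amp):
            i = np.arange(n)
            return amp * np.exp(-0.5 * ((i - center) / width) ** 2)

        # two cycles anchored by prominent positive peaks at 100 and 450
        y += bump(100, 8, 1.0) + bump(450, 8, 1.0)
        y -= bump(60, 6, 0.9) + bump(410, 6, 0.9)     # onset valleys
        y -= bump(113, 3, 0.35)                        # 0.05 s after SPP: too close
        y -= bump(138, 3, 0.30)                        # 0.15 s after SPP: qualifies
        y -= bump(320, 6, 0.6)                         # endpoint valley region
        cycles = delineate_cycles(y, fs, LandmarkParams(smooth_window=5))
        assert len(cycles) >= 1
        assert abs(cycles[0].dn - 138) <= 3

    def test_flat_nsts_yields_nothing(self):
        assert delineate_cycles(np.zeros(1024), FS) == []

    def test_signal_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            delineate_cycles(np.zeros(100), FS, signal=np.zeros(50))


class TestToRecord:
    def test_offset_arithmetic(self):
        cyc = CycleLandmarks(spo=10, spp=20, dn=40, dpe=80, dpp=60)
        window = make_window(np.zeros(100), start=1024)
        ann = landmarks_to_record([cyc], window)
        assert ann["SPO"].tolist() == [1034]
        assert ann["DPE"].tolist() == [1104]

    def test_empty_cycles(self):
        ann = landmarks_to_record([], make_window(np.zeros(10)))
        assert ann.total() == 0

    def test_out_of_range_rejected(self):
        cyc = CycleLandmarks(spo=10, spp=20, dn=40, dpe=120, dpp=60)
        with pytest.raises(ValueError, match="outside"):
            landmarks_to_record([cyc], make_window(np.zeros(100)))

    def test_shared_boundary_deduplicates(self):
        c1 = CycleLandmarks(spo=0, spp=10, dn=40, dpe=80)
        c2 = CycleLandmarks(spo=80, spp=90, dn=120, dpe=160)
        ann = landmarks_to_record([c1, c2], make_window(np.zeros(200)))
        merged = AnnotationSet(marks={"SPO": np.concatenate([ann["SPO"], ann["DPE"]])})
        assert merged["SPO"].tolist() == [0, 80, 160]
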