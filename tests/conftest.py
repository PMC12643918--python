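import numpy as np
import pytest

from pulsefeat import (
    IEMParams,
    SynthParams,
    Window,
    build_manifest,
    decompose,
    delineate_cycles,
    iter_windows,
    landmarks_to_record,
    lowpass_filter,
    normalize_minmax,
    screen_window,
    synth_pulse_train,
)

FS = 256.0


@pytest.fixture(scope="session")
def manifest():
    return build_manifest("ABP")


@pytest.fixture()
def clean_window():
    """One accepted 4-s synthetic window with its ground truth."""
    params = SynthParams(duration_s=4.0, heart_rate_bpm=75.0, seed=11)
    record, truth = synth_pulse_train(params)
    window = next(iter_windows(record, 4.0))
    assert screen_window(window).accepted
    return window, truth


def detect_on_window(window):
    """Run preprocess -> IEM -> delineation on one window."""
    nw = normalize_minmax(lowpass_filter(window))
    dec = decompose(nw.samples, IEMParams())
    cycles = delineate_cycles(dec.nsts, window.fs, signal=nw.samples)
    return landmarks_to_record(cycles, window), cycles, dec, nw


def make_window(samples, fs=FS, start=0):
    return Window(start_index=start, samples=np.asarray(samples, dtype=float), fs=fs)
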