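import numpy as np
import pytest

from thalcortex.io_formats import EventTable, Modality, Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def lfp_recording(rng):
    return Recording(rng.standard_normal((2, 15000)), 250.0,
                     ["lfp_left", "lfp_right"], Modality.LFP,
                     meta={"hemisphere": {"lfp_left": "left",
                                          "lfp_right": "right"}})


@pytest.fixture
def eeg_recording(rng):
    return Recording(rng.standard_normal((4, 50000)) * 20.0, 5000.0,
                     ["Fz", "Cz", "Pz", "Oz"], Modality.EEG)


@pytest.fixture
def event_table():
    return EventTable.from_records([
        {"onset": 1.0, "offset": 1.2, "kind": "artifact_sync",
         "tic_type": "", "condition": ""},
        {"onset": 3.5, "offset": 4.0, "kind": "tic",
         "tic_type": "blink", "condition": "tic_freely"},
        {"onset": 8.0, "offset": 8.4, "kind": "movement",
         "tic_type": "", "condition": ""},
    ])


def make_tf(phases, amplitudes=None, rate=250.0, freqs=(10.0,), labels=("ch",)):
    """TFDecomposition stub from explicit per-trial phase arrays.

    ``phases``: (trials, channels, freqs, samples) or broadcastable; the
    coefficients are unit phasors (times an optional amplitude), with the
    full valid mask so tests control every sample entering a PSI.
    """
    from thalcortex.spectral import TFDecomposition

    phases = np.asarray(phases, dtype=float)
    coeffs = np.exp(1j * phases)
    if amplitudes is not None:
        coeffs = coeffs * np.asarray(amplitudes)
    freqs = np.asarray(freqs, dtype=float)
    n = coeffs.shape[-1]
    tf = TFDecomposition(coeffs, freqs, rate,
                         np.arange(n) / rate, list(labels), n_cycles=5.0,
                         valid=np.ones((freqs.size, n), dtype=bool))
    return tf
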