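"""Shared fixtures: synthetic records at known noise levels.

Everything is generated programmatically; session scope keeps the cost of
the heavier signal-processing fixtures to a single evaluation.
"""

import numpy as np
import pytest

from fibrillens.preprocess import bandpass_filter, detect_rpeaks
from fibrillens.synthetic import SynthParams, make_dataset, synth_record


@pytest.fixture(scope="session")
def clean_nonaf():
    """Nearly noise-free sinus-rhythm record plus its ground truth."""
    params = SynthParams.for_class(False, noise_snr_db=40.0)
    return synth_record(params, seed=11)


@pytest.fixture(scope="session")
def clean_af():
    params = SynthParams.for_class(True, noise_snr_db=40.0)
    return synth_record(params, seed=12)


@pytest.fixture(scope="session")
def default_nonaf():
    """Sinus-rhythm record at the default (study-condition) noise level."""
    return synth_record(SynthParams.for_class(False), seed=21)


@pytest.fixture(scope="session")
def default_af():
    return synth_record(SynthParams.for_class(True), seed=22)


@pytest.fixture(scope="session")
def small_dataset():
    """12 AF + 12 non-AF jittered records at default conditions."""
    return make_dataset(12, 12, seed=5)


@pytest.fixture(scope="session")
def filtered_with_peaks(clean_nonaf):
    """(record, truth, filtered signal, detected R peaks) for reuse."""
    rec, truth = clean_nonaf
    xf = bandpass_filter(rec.samples, rec.fs)
    rp = detect_rpeaks(xf, rec.fs)
    return rec, truth, xf, rp


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
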