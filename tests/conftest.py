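import numpy as np
import pytest

from ecgstream.preprocess import bandpass_fir
from ecgstream.synthetic import generate_record, rhythm_for, template_for


@pytest.fixture(scope="session")
def clean_record():
    """Noise-free 30 s normal-rhythm record with ground truth."""
    rec, truth = generate_record(
        rhythm_for("NORMAL", 30.0, seed=1), template_for("NORMAL")
    )
    return rec, truth


@pytest.fixture(scope="session")
def noisy_record():
    """60 s normal-rhythm record at the reference noise level (0.05 mV)."""
    rec, truth = generate_record(
        rhythm_for("NORMAL", 60.0, seed=2, noise_sd=0.05, baseline_wander_amp=0.1),
        template_for("NORMAL"),
    )
    return rec, truth


@pytest.fixture(scope="session")
def filtered_clean(clean_record):
    rec, truth = clean_record
    return bandpass_fir(rec.samples), truth


@pytest.fixture(scope="session")
def benchmark_datasets():
    """Record-disjoint synthetic train/test datasets for the three classes."""
    from ecgstream.workflows import synthetic_benchmark

    return synthetic_benchmark(seed=1, duration_s=60.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
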