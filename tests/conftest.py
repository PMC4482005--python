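import numpy as np
import pytest

from fallwave import (
    FeatureConfig,
    Recording,
    SimConfig,
    SumVectorSeries,
    compute_sv,
    pattern_to_wavelet,
    average_fall_pattern,
    simulate_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def recording_from_sv(sv_values, fs=100, label="unknown", rec_id="rec"):
    """Recording whose sum vector equals the given series (single-axis)."""
    sv_values = np.asarray(sv_values, dtype=float)
    samples = np.column_stack(
        [sv_values, np.zeros_like(sv_values), np.zeros_like(sv_values)]
    )
    return Recording(id=rec_id, fs=fs, samples=samples, label=label)


def sv_series(values, fs=100):
    return SumVectorSeries(fs=fs, values=np.asarray(values, dtype=float))


@pytest.fixture(scope="session")
def small_dataset():
    """12 falls + 24 ADLs, enough for quick cross-validation tests."""
    cfg = SimConfig(seed=99, n_falls=12, n_adls=24)
    _, recs = simulate_dataset(cfg)
    return recs


@pytest.fixture(scope="session")
def trained_wavelet(small_dataset):
    falls = [compute_sv(r) for r in small_dataset if r.label == "fall"]
    return pattern_to_wavelet(average_fall_pattern(falls))


@pytest.fixture
def feature_config():
    return FeatureConfig()
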