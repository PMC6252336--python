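import numpy as np
import pytest

from somsnn import pipeline, snn, som


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def random_spike_pattern(rng, n_units=8, n_events=20, duration_ms=500.0,
                         label=None):
    units = rng.integers(0, n_units, n_events)
    times = np.sort(rng.uniform(0.0, duration_ms, n_events))
    events = [(int(u), float(t)) for u, t in zip(units, times)]
    return som.SpikePattern(events=events, duration_ms=duration_ms,
                            n_units=n_units, label=label)


@pytest.fixture(scope="session")
def default_experiment():
    """One full training run on the synthetic study fixture (5 classes,
    20 train + 20 test clips per class, 8x8 map, default classifier)."""
    cfg = pipeline.ExperimentConfig()
    models = pipeline.run_train(cfg)
    return cfg, models


@pytest.fixture(scope="session")
def clean_test_patterns(default_experiment):
    cfg, models = default_experiment
    _, test_clips = pipeline.resolve_datasets(cfg)
    return pipeline.encode_clips(test_clips, cfg, models.som_model)


@pytest.fixture(scope="session")
def clean_accuracy(default_experiment, clean_test_patterns):
    _, models = default_experiment
    return snn.accuracy(models.neurons, clean_test_patterns)
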