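"""Shared fixtures: tone events, a small synthetic corpus, rendered images."""

import numpy as np
import pytest

from respviz import (
    AudioEvent,
    default_spec,
    generate_corpus,
    generate_event,
    images_for_event,
    standardize,
)


def make_tone(freq_hz, duration=1.0, sample_rate=20000, amplitude=0.5, label="RB"):
    """A pure sinusoid event at the analysis rate."""
    t = np.arange(int(round(duration * sample_rate))) / sample_rate
    return AudioEvent(
        samples=amplitude * np.sin(2 * np.pi * freq_hz * t),
        sample_rate=sample_rate,
        label=label,
        source_id=f"tone-{freq_hz:g}",
    )


@pytest.fixture(scope="session")
def tone_1khz():
    return make_tone(1000.0)


@pytest.fixture(scope="session")
def zero_event():
    return AudioEvent(samples=np.zeros(20000), sample_rate=20000,
                      label="wC", source_id="zero")


@pytest.fixture(scope="session")
def small_corpus():
    """Four events per class at the generation rate (44.1 kHz)."""
    events, manifest = generate_corpus(
        {"wC": 4, "dC": 4, "whC": 4, "RB": 4}, seed=11
    )
    return events, manifest


@pytest.fixture(scope="session")
def standardized_dc():
    return standardize(generate_event(default_spec("dC", seed=5)))


@pytest.fixture(scope="session")
def separable_images():
    """Wavelet images of wheeze (RB) vs dry-cough bursts: a separable pair."""
    X, y = [], []
    for label in ("RB", "dC"):
        for i in range(12):
            ev = generate_event(default_spec(label, seed=1000 + i))
            std = standardize(ev)
            img = images_for_event(std, methods=("wavelet",))["wavelet"]
            X.append(img.pixels)
            y.append(label)
    return np.stack(X), np.array(y)
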