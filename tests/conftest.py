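import numpy as np
import pytest

from fmm.intervals import Interval
from fmm.io_formats import (
    Annotation,
    AnnotationTimeline,
    MovementType,
    SensorRecording,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_recording(rng):
    """Six acoustic channels + accel, 30 s at 128 Hz, pure noise."""
    fs = 128.0
    n = int(30 * fs)
    acoustic = rng.normal(0, 0.3, size=(6, n))
    accel = np.zeros((3, n))
    accel[2] = 1.0
    return SensorRecording(subject_id="fix", acoustic=acoustic, accel=accel, fs=fs)


@pytest.fixture
def simple_timeline():
    return AnnotationTimeline(
        annotations=[
            Annotation(10.0, MovementType.STARTLE),
            Annotation(50.0, MovementType.GENERAL),
            Annotation(90.0, MovementType.BREATHE),
        ],
        probe_moves=[Interval(200.0, 210.0)],
    )


def make_burst(fs, duration, freq, amplitude, phase=0.0):
    """Gaussian-windowed sinusoid test burst."""
    t = np.arange(int(duration * fs)) / fs
    c = duration / 2
    sigma = duration / 6
    return amplitude * np.exp(-0.5 * ((t - c) / sigma) ** 2) * np.sin(
        2 * np.pi * freq * (t - c) + phase
    )
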