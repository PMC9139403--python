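import logging

import numpy as np
import pytest

import topogru as tg

logging.getLogger("topogru").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def montage16():
    return tg.load_montage("standard-1020-16")


@pytest.fixture(scope="session")
def layout16(montage16):
    return tg.aep_project(montage16)


@pytest.fixture(scope="session")
def small_cohort():
    """Six subjects, 10 s at 100 Hz, moderate posterior α/θ elevation."""
    spec = tg.CohortSpec(n_subjects=6, depressed_fraction=0.5, fs=100.0,
                         duration=10.0, seed=11,
                         effect=tg.BandEffect(theta=2.0, alpha=2.0))
    return spec, tg.generate_cohort(spec)


@pytest.fixture()
def sinusoid_segment(montage16):
    """1-s 16-channel segment holding a pure 10 Hz unit sinusoid."""
    fs = 250.0
    t = np.arange(int(fs)) / fs
    data = np.tile(np.sin(2 * np.pi * 10.0 * t), (16, 1))
    return tg.Segment(data, fs, "synthetic", 0, list(montage16.channel_names))
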