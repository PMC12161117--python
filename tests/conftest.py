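"""Shared fixtures: small synthetic recordings and cohorts kept deliberately
short so the suite runs quickly; full-scale cohorts appear only in the
acceptance tests."""

import numpy as np
import pytest

from bdeeg.core import MONTAGE_19, Recording
from bdeeg.synthetic import (
    CohortSpec,
    CouplingEdge,
    GroupParams,
    default_cohort_spec,
)

FS = 250.0


def tone(freq, duration=12.0, fs=FS, amplitude=1.0, phase=0.0):
    t = np.arange(int(duration * fs)) / fs
    return amplitude * np.cos(2 * np.pi * freq * t + phase)


def make_recording(rows, fs=FS, labels=None, **kw):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    if labels is None:
        labels = MONTAGE_19[: rows.shape[0]]
    return Recording(data=rows, fs=fs, channel_labels=labels, **kw)


def montage_noise_recording(seed=0, duration=12.0, fs=FS, scale=10.0):
    rng = np.random.default_rng(seed)
    data = scale * rng.standard_normal((19, int(duration * fs)))
    return Recording(data=data, fs=fs, channel_labels=MONTAGE_19)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_spec():
    """4+4 subjects, 18 s (3 epochs) per paradigm; default-style contrasts."""
    spec = default_cohort_spec(n_bd=4, n_hc=4, duration=18.0, seed=7)
    return spec


def single_edge_spec(band="alpha", strength=1.0, lag=np.pi / 4, amplitude=5.0,
                     noise=0.0, duration=60.0, seed=0, pac=0.0,
                     pair=("O1", "O2")):
    grp = GroupParams({band: amplitude},
                      (CouplingEdge(pair[0], pair[1], band, lag, strength),), pac)
    return CohortSpec(n_bd=2, n_hc=2,
                      params={"eyes_closed": {"BD": grp, "HC": grp}},
                      one_over_f_scale=noise, duration=duration, seed=seed)
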