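"""Preprocessing chain: average re-reference, broadband + notch filtering,
6-s epoching and per-band zero-phase Butterworth decomposition.

All filters are applied forward-backward (``sosfiltfilt``/``filtfilt``), so
the chain is zero-phase: a narrowband probe cross-correlates with its
filtered version at lag 0.  Band decomposition of 6-s epochs uses 1 s of
reflection padding per side to suppress edge transients in the slow bands.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .core import BandDefinition, EpochSet, Recording

#: Butterworth order applied forward-backward (effective order doubles).
FILTER_ORDER = 4
#: Mains notch.
NOTCH_HZ = 50.0
NOTCH_Q = 30.0
#: Broadband analysis band.
BROADBAND = (1.0, 49.0)
#: Epoch length in seconds.
EPOCH_S = 6.0
#: Reflection padding (seconds per side) for epoch-wise band filtering.
BAND_PAD_S = 1.0


def rereference_average(rec: Recording) -> Recording:
    """Subtract the instantaneous mean across channels (average reference).

    Idempotent; after application the per-sample mean over channels is zero.
    """
    if rec.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return rec.copy_with(data=data)


def _broadband_sos(fs: float) -> np.ndarray:
    low, high = BROADBAND
    return signal.butter(FILTER_ORDER, [low, high], btype="bandpass", fs=fs, output="sos")


def filter_broadband(rec: Recording) -> Recording:
    """1-49 Hz zero-phase bandpass plus 50 Hz notch on the continuous signal."""
    if rec.fs < 2 * BROADBAND[1]:
        raise ValueError(f"fs={rec.fs} too low for a {BROADBAND[1]} Hz bandpass")
    sos = _broadband_sos(rec.fs)
    data = signal.sosfiltfilt(sos, rec.data, axis=-1)
    b, a = signal.iirnotch(NOTCH_HZ, NOTCH_Q, fs=rec.fs)
    data = signal.filtfilt(b, a, data, axis=-1)
    return rec.copy_with(data=data)


def epoch(rec: Recording, epoch_s: float = EPOCH_S) -> EpochSet:
    """Cut into non-overlapping, contiguous epochs; remainder discarded."""
    n_per = int(round(epoch_s * rec.fs))
    n_epochs = rec.n_samples // n_per
    if n_epochs < 1:
        raise ValueError(
            f"recording of {rec.duration:.1f} s shorter than one {epoch_s:.0f}-s epoch"
        )
    trimmed = rec.data[:, : n_epochs * n_per]
    epochs = trimmed.reshape(rec.n_channels, n_epochs, n_per).transpose(1, 0, 2)
    return EpochSet(epochs=epochs.copy(), fs=rec.fs,
                    channel_labels=rec.channel_labels, band=None)


def concatenate_epochs(es: EpochSet) -> Recording:
    """Inverse of :func:`epoch` up to the discarded remainder."""
    data = es.epochs.transpose(1, 0, 2).reshape(es.n_channels, -1)
    return Recording(data=data, fs=es.fs, channel_labels=es.channel_labels)


def band_filter(es: EpochSet, band: BandDefinition, order: int = FILTER_ORDER) -> EpochSet:
    """Zero-phase Butterworth bandpass of each epoch to ``band``.

    Epochs are reflection-padded by :data:`BAND_PAD_S` seconds per side before
    filtering and trimmed afterwards.
    """
    if es.band is not None:
        raise ValueError(f"epochs already band-filtered to {es.band.name}")
    nyq = es.fs / 2
    if band.high_hz >= nyq:
        raise ValueError(f"band edge {band.high_hz} Hz at or above Nyquist {nyq} Hz")
    sos = signal.butter(order, [band.low_hz, band.high_hz],
                        btype="bandpass", fs=es.fs, output="sos")
    pad = min(int(round(BAND_PAD_S * es.fs)), es.n_samples - 1)
    padded = np.pad(es.epochs, ((0, 0), (0, 0), (pad, pad)), mode="reflect")
    filtered = signal.sosfiltfilt(sos, padded, axis=-1)
    if pad:
        filtered = filtered[..., pad:-pad]
    return EpochSet(epochs=filtered, fs=es.fs,
                    channel_labels=es.channel_labels, band=band)


def preprocess_recording(rec: Recording, epoch_s: float = EPOCH_S) -> EpochSet:
    """Full chain: average reference -> broadband+notch -> 6-s epochs."""
    return epoch(filter_broadband(rereference_average(rec)), epoch_s=epoch_s)
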