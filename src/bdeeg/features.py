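"""Per-channel EEG features and phase-lag-index connectivity.

Twelve feature families are extracted per channel: band power (Welch PSD
integrated over each of the five bands), differential entropy per band,
delta-beta amplitude-amplitude coupling (AAC), and debiased delta-phase to
beta-amplitude coupling (dPAC).  Connectivity is the phase lag index (PLI)

    PLI = | (1/M) sum_m sgn(dphi_m) |

with dphi the phase difference wrapped to (-pi, pi]: the fraction of time the
phase difference is consistently on one side of zero.  sgn(0) = 0, so
zero-lag (volume-conduction-like) coupling contributes nothing.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .core import (
    BAND_ORDER,
    BANDS,
    AnalyticSignal,
    BandDefinition,
    ConnectivityTensor,
    EpochSet,
    Recording,
)
from .preprocess import band_filter, preprocess_recording

#: Deterministic feature-family order for feature-matrix columns.
FEATURE_FAMILIES: tuple[str, ...] = tuple(
    [f"psd_{b}" for b in BAND_ORDER] + [f"de_{b}" for b in BAND_ORDER] + ["aac", "dpac"]
)

#: Welch estimator settings: 2-s Hamming segments, 50% overlap.
WELCH_SEG_S = 2.0
WELCH_OVERLAP = 0.5


def feature_columns(channel_labels: Sequence[str]) -> list[str]:
    """Deterministic column names: family x channel, family-major."""
    return [f"{fam}__{ch}" for fam in FEATURE_FAMILIES for ch in channel_labels]


def analytic(es: EpochSet) -> AnalyticSignal:
    """Hilbert analytic signal of band-filtered epochs.

    Broadband (unfiltered) input is rejected: phase is only meaningful for a
    narrowband signal.
    """
    if es.band is None:
        raise ValueError("analytic() requires band-filtered epochs")
    z = _signal.hilbert(es.epochs, axis=-1)
    return AnalyticSignal(
        phase=np.angle(z),
        amplitude=np.abs(z),
        fs=es.fs,
        channel_labels=es.channel_labels,
        band=es.band,
    )


def _mean_sgn_wrapped(dphi: np.ndarray) -> np.ndarray:
    """Mean over the last axis of sgn(dphi wrapped to (-pi, pi]).

    Phases from np.angle lie in (-pi, pi], so dphi lies in (-2pi, 2pi); the
    wrapped difference is positive iff dphi is in (0, pi] or (-2pi, -pi],
    which is evaluated with comparisons instead of trigonometry.
    """
    pos = ((dphi > 0) & (dphi <= np.pi)) | (dphi <= -np.pi)
    neg = ((dphi < 0) & (dphi > -np.pi)) | (dphi > np.pi)
    return pos.mean(axis=-1) - neg.mean(axis=-1)


def pli_from_phases(phase: np.ndarray) -> np.ndarray:
    """PLI matrix from a (n_epochs, n_channels, n_samples) phase stack.

    Per epoch the sign of the wrapped phase difference is averaged over time;
    epoch means are averaged and the modulus taken last, so phase-lag reversals
    across epochs cancel rather than add.
    """
    phase = np.asarray(phase, dtype=np.float64)
    if phase.ndim != 3:
        raise ValueError("phase stack must be (n_epochs, n_channels, n_samples)")
    n_ch = phase.shape[1]
    if n_ch < 2:
        raise ValueError("PLI needs at least 2 channels")
    ia, ib = np.triu_indices(n_ch, k=1)
    # per-epoch time mean of the sign, then epoch mean; epoch-wise loop keeps
    # the (n_pairs, n_samples) workspace cache-resident
    acc = np.zeros(len(ia))
    for e in range(phase.shape[0]):
        acc += _mean_sgn_wrapped(phase[e][ia] - phase[e][ib])
    pli_pairs = np.abs(acc / phase.shape[0])
    mat = np.zeros((n_ch, n_ch))
    mat[ia, ib] = pli_pairs
    mat[ib, ia] = pli_pairs
    return mat


def pli_matrix(phases: AnalyticSignal) -> np.ndarray:
    """Symmetric zero-diagonal PLI matrix for one band."""
    return pli_from_phases(phases.phase)


def psd_band_power(es: EpochSet, band: BandDefinition) -> np.ndarray:
    """Band power per channel (uV^2): Welch density integrated over
    [low_hz, high_hz), computed per epoch and averaged over epochs.
    """
    if es.band is not None:
        raise ValueError("psd_band_power expects broadband epochs")
    nper = int(round(WELCH_SEG_S * es.fs))
    nper = min(nper, es.n_samples)
    freqs, psd = _signal.welch(
        es.epochs, fs=es.fs, window="hamming", nperseg=nper,
        noverlap=int(nper * WELCH_OVERLAP), axis=-1, scaling="density",
    )
    if band.low_hz >= freqs[-1]:
        raise ValueError(f"band {band.name} outside the spectral range")
    df = freqs[1] - freqs[0]
    mask = (freqs >= band.low_hz) & (freqs < band.high_hz)
    power = psd[..., mask].sum(axis=-1) * df      # (n_epochs, n_channels)
    return power.mean(axis=0)


def differential_entropy(es: EpochSet) -> np.ndarray:
    """Gaussian differential entropy per channel, in nats.

    DE = 1/2 ln(2 pi e sigma^2) with sigma^2 the per-epoch sample variance of
    the band-filtered signal, averaged over epochs.  For a Gaussian band
    process this is the true differential entropy; in general it is a
    log-variance feature.
    """
    if es.band is None:
        raise ValueError("differential_entropy expects band-filtered epochs")
    var = es.epochs.var(axis=-1)                  # (n_epochs, n_channels)
    if np.any(var <= 0):
        raise ValueError("zero-variance epoch: differential entropy undefined")
    de = 0.5 * np.log(2 * np.pi * np.e * var)
    return de.mean(axis=0)


def _concat(a: np.ndarray) -> np.ndarray:
    # (n_epochs, n_channels, n_samples) -> (n_channels, n_epochs*n_samples)
    return a.transpose(1, 0, 2).reshape(a.shape[1], -1)


def dpac(delta: AnalyticSignal, beta: AnalyticSignal, normalize: bool = False) -> np.ndarray:
    """Debiased phase-amplitude coupling of beta envelope to delta phase.

    Per channel, over all samples pooled across epochs,

        dPAC = | mean(a e^{i phi}) - mean(a) mean(e^{i phi}) |

    i.e. the amplitude-weighted mean phase vector with the phase-clustering
    bias subtracted.  With ``normalize`` the result is divided by the mean
    envelope, making it dimensionless.
    """
    if delta.phase.shape != beta.amplitude.shape:
        raise ValueError("delta phase and beta amplitude are not aligned")
    phi = _concat(delta.phase)
    amp = _concat(beta.amplitude)
    e = np.exp(1j * phi)
    raw = (amp * e).mean(axis=-1) - amp.mean(axis=-1) * e.mean(axis=-1)
    out = np.abs(raw)
    if normalize:
        out = out / amp.mean(axis=-1)
    return out


def aac(delta: AnalyticSignal, beta: AnalyticSignal) -> np.ndarray:
    """Amplitude-amplitude coupling: Pearson r between delta and beta
    envelopes, per channel, over samples pooled across epochs."""
    if delta.amplitude.shape != beta.amplitude.shape:
        raise ValueError("envelopes are not aligned")
    a = _concat(delta.amplitude)
    b = _concat(beta.amplitude)
    a = a - a.mean(axis=-1, keepdims=True)
    b = b - b.mean(axis=-1, keepdims=True)
    denom = np.sqrt((a ** 2).sum(axis=-1) * (b ** 2).sum(axis=-1))
    if np.any(denom == 0):
        raise ValueError("constant envelope: AAC undefined")
    return (a * b).sum(axis=-1) / denom


def subject_features(es: EpochSet) -> np.ndarray:
    """Flat 12x n_channels feature vector for one preprocessed subject,
    ordered as :func:`feature_columns`."""
    psd = [psd_band_power(es, BANDS[b]) for b in BAND_ORDER]
    banded = {b: band_filter(es, BANDS[b]) for b in ("delta", "beta")}
    de = []
    for b in BAND_ORDER:
        fes = banded.get(b) or band_filter(es, BANDS[b])
        de.append(differential_entropy(fes))
    d_an = analytic(banded["delta"])
    b_an = analytic(banded["beta"])
    return np.concatenate(psd + de + [aac(d_an, b_an), dpac(d_an, b_an)])


def subject_connectivity(es: EpochSet, bands: Optional[Iterable[str]] = None,
                         subject_id: str = "", paradigm: str = "") -> ConnectivityTensor:
    """Per-band PLI matrices from broadband epochs."""
    if es.band is not None:
        raise ValueError("subject_connectivity expects broadband epochs")
    bands = tuple(bands) if bands is not None else BAND_ORDER
    pli = {}
    for b in bands:
        pli[b] = pli_matrix(analytic(band_filter(es, BANDS[b])))
    return ConnectivityTensor(pli=pli, n_epochs=es.n_epochs,
                              channel_labels=es.channel_labels,
                              subject_id=subject_id, paradigm=paradigm)


def build_feature_matrix(
    recordings: Sequence[Recording],
    metadata: Optional[pd.DataFrame] = None,
    paradigm: Optional[str] = None,
) -> pd.DataFrame:
    """Subjects x (12 families x channels) feature table for one paradigm.

    ``metadata`` (indexed or keyed by ``subject_id``) contributes group
    labels and cognitive scores.  Subjects whose recording is too short for a
    single epoch are excluded with a warning.
    """
    if paradigm is not None:
        recordings = [r for r in recordings if r.paradigm == paradigm]
    if not recordings:
        raise ValueError("no recordings for the requested paradigm")
    rows, index = [], []
    for rec in recordings:
        try:
            es = preprocess_recording(rec)
        except ValueError as exc:
            warnings.warn(f"subject {rec.subject_id}: excluded ({exc})")
            continue
        rows.append(subject_features(es))
        index.append(rec.subject_id)
    cols = feature_columns(recordings[0].channel_labels)
    fm = pd.DataFrame(np.vstack(rows), index=pd.Index(index, name="subject_id"),
                      columns=cols)
    fm.insert(0, "paradigm", recordings[0].paradigm)
    if metadata is not None:
        meta = metadata.set_index("subject_id") if "subject_id" in metadata.columns else metadata
        meta_cols = [c for c in meta.columns if c not in fm.columns]
        fm = fm.join(meta[meta_cols], how="left")
        # keep metadata first, features last, deterministic order
        fm = fm[["paradigm"] + meta_cols + cols]
    return fm
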