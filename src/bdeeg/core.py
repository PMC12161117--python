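"""Core containers shared by every stage of the pipeline.

The analysis operates on 19 scalp electrodes of the 10-20 system sampled at
250 Hz, decomposed into the five canonical EEG bands.  All stages exchange
data through the small dataclasses below; arrays are float64, channels are
always ordered by :data:`MONTAGE_19`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

#: Canonical electrode order used everywhere (connectivity matrices, feature
#: columns).  Case-insensitive matching is applied on input.
MONTAGE_19: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz",
    "T7", "T8", "P7", "P8",
    "C3", "C4", "Cz", "P3", "P4", "Pz",
    "O1", "O2",
)

#: Lobe grouping used when reporting per-electrode significance tables.
REGIONS: dict[str, tuple[str, ...]] = {
    "F": ("Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz"),
    "P": ("C3", "C4", "Cz", "P3", "P4", "P7", "P8", "Pz"),
    "O": ("O1", "O2"),
    "T": ("T7", "T8"),
}

PARADIGMS: tuple[str, ...] = ("eyes_closed", "eyes_open", "free_viewing")

GROUPS: tuple[str, ...] = ("BD", "HC")

#: Cognitive scores carried in cohort metadata.
COGNITIVE_SCORES: tuple[str, ...] = ("TMT-A", "TMT-B", "DST", "SDMT")


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band [low_hz, high_hz)."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not self.low_hz < self.high_hz:
            raise ValueError(
                f"band {self.name!r}: low_hz={self.low_hz} must be < high_hz={self.high_hz}"
            )


#: Canonical band table.  The gamma band is bounded above at 49 Hz because the
#: broadband filter removes everything beyond 49 Hz.
BANDS: dict[str, BandDefinition] = {
    "delta": BandDefinition("delta", 1.0, 4.0),
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 12.0),
    "beta": BandDefinition("beta", 12.0, 30.0),
    "gamma": BandDefinition("gamma", 30.0, 49.0),
}

BAND_ORDER: tuple[str, ...] = ("delta", "theta", "alpha", "beta", "gamma")


def canonical_channel_indices(labels: list[str]) -> list[int]:
    """Indices that reorder/restrict ``labels`` to :data:`MONTAGE_19`.

    Raises ``ValueError`` naming every montage channel absent from ``labels``
    (case-insensitive match).
    """
    lower = [str(l).strip().lower() for l in labels]
    indices = []
    missing = []
    for target in MONTAGE_19:
        try:
            indices.append(lower.index(target.lower()))
        except ValueError:
            missing.append(target)
    if missing:
        raise ValueError(f"missing montage channel(s): {', '.join(missing)}")
    return indices


@dataclass
class Recording:
    """One subject x paradigm multichannel signal.

    data : (n_channels, n_samples) array, microvolts
    """

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    subject_id: str = ""
    paradigm: str = "eyes_closed"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("Recording.data must be 2-D (channels x samples)")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Recording contains non-finite samples")
        self.channel_labels = tuple(self.channel_labels)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, **changes) -> "Recording":
        return replace(self, **changes)


@dataclass
class EpochSet:
    """Stack of fixed-length epochs: (n_epochs, n_channels, n_samples)."""

    epochs: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    band: Optional[BandDefinition] = None

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=np.float64)
        if self.epochs.ndim != 3:
            raise ValueError("EpochSet.epochs must be 3-D")
        if len(self.channel_labels) != self.epochs.shape[1]:
            raise ValueError("channel label count mismatch")
        self.channel_labels = tuple(self.channel_labels)

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[2]


@dataclass
class AnalyticSignal:
    """Hilbert phase/envelope stacks aligned with an :class:`EpochSet`."""

    phase: np.ndarray       # (n_epochs, n_channels, n_samples), radians in (-pi, pi]
    amplitude: np.ndarray   # same shape, envelope in microvolts, >= 0
    fs: float
    channel_labels: tuple[str, ...]
    band: BandDefinition

    def __post_init__(self) -> None:
        if self.phase.shape != self.amplitude.shape:
            raise ValueError("phase/amplitude shape mismatch")
        self.channel_labels = tuple(self.channel_labels)


@dataclass
class ConnectivityTensor:
    """Per-band symmetric PLI matrices for one subject x paradigm."""

    pli: dict[str, np.ndarray]
    n_epochs: int
    channel_labels: tuple[str, ...] = field(default=MONTAGE_19)
    subject_id: str = ""
    paradigm: str = ""

    def __post_init__(self) -> None:
        n = len(self.channel_labels)
        for band, mat in self.pli.items():
            if mat.shape != (n, n):
                raise ValueError(f"PLI matrix for {band} has shape {mat.shape}")
        self.channel_labels = tuple(self.channel_labels)
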