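"""Recording I/O: EDF and delimited-matrix formats.

Two on-disk layouts are supported:

* **EDF** (European Data Format), read through :func:`mne.io.read_raw_edf`.
  A minimal EDF+ compliant writer is provided for export (16-bit samples,
  1-s data records), since a full-featured EDF export backend is not a
  dependency of this package.
* **matrix** — a plain tab-separated table, one row per channel, first column
  the channel label, remaining columns samples in microvolts.  An optional
  leading comment line ``# fs=<Hz>`` records the sampling rate.

On load, channels are restricted and reordered (case-insensitively) to the
19-electrode montage; a missing montage channel raises an error naming it.
"""

from __future__ import annotations

import io as _stdio
import warnings
from pathlib import Path
from typing import Optional

import numpy as np

from .core import MONTAGE_19, Recording, canonical_channel_indices

__all__ = ["read_recording", "write_matrix", "write_edf"]


def read_recording(
    path,
    format: Optional[str] = None,
    fs: Optional[float] = None,
    subject_id: str = "",
    paradigm: str = "eyes_closed",
) -> Recording:
    """Load one subject x paradigm recording and canonicalize the montage.

    Parameters
    ----------
    path : file path (``.edf`` or delimited matrix).
    format : ``"edf"`` or ``"matrix"``; inferred from the suffix if omitted.
    fs : expected sampling rate; an error is raised if the file disagrees.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if format == "edf":
        data, file_fs, labels = _read_edf(path)
    elif format == "matrix":
        data, file_fs, labels = _read_matrix(path)
    else:
        raise ValueError(f"unknown format {format!r}")

    if file_fs is None:
        if fs is None:
            raise ValueError(f"{path}: sampling rate not in file; pass fs=")
        file_fs = float(fs)
    elif fs is not None and abs(file_fs - fs) > 1e-6:
        raise ValueError(f"{path}: file fs={file_fs} Hz != configured fs={fs} Hz")

    idx = canonical_channel_indices(labels)
    data = np.ascontiguousarray(data[idx])
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: non-finite samples after load")
    return Recording(data=data, fs=file_fs, channel_labels=MONTAGE_19,
                     subject_id=subject_id, paradigm=paradigm)


def _read_matrix(path: Path):
    fs = None
    labels: list[str] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ").strip()
                if body.startswith("fs="):
                    fs = float(body[3:])
                continue
            label, _, rest = line.partition("\t")
            labels.append(label.strip())
            rows.append(np.array(rest.split("\t"), dtype=np.float64))
    if not rows:
        raise ValueError(f"{path}: empty matrix file")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"{path}: ragged rows (lengths {sorted(lengths)})")
    return np.vstack(rows), fs, labels


def _read_edf(path: Path):
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    # mne stores EEG in volts; the pipeline works in microvolts.
    data = raw.get_data() * 1e6
    return data, float(raw.info["sfreq"]), list(raw.ch_names)


def write_matrix(path, rec: Recording) -> None:
    """Write a recording as the tab-separated matrix layout."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs:g}\n")
        for label, row in zip(rec.channel_labels, rec.data):
            fh.write(label + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def write_edf(path, rec: Recording) -> None:
    """Write a recording as 16-bit EDF with 1-s data records.

    Samples are scaled per channel to the full digital range; a trailing
    partial second is dropped (EDF records are fixed-length).
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    spr = int(round(fs))                       # samples per 1-s record
    n_records = rec.n_samples // spr
    if n_records < 1:
        raise ValueError("recording shorter than one EDF data record")
    data = rec.data[:, : n_records * spr]
    n_sig = rec.n_channels

    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-6)
    phys_min = -phys_max
    dig_max, dig_min = 32767, -32767
    scale = dig_max / phys_max

    def fixed(text: str, width: int) -> bytes:
        b = text.encode("ascii", "replace")[:width]
        return b + b" " * (width - len(b))

    header = _stdio.BytesIO()
    header.write(fixed("0", 8))
    header.write(fixed(rec.subject_id or "X", 80))
    header.write(fixed(f"Startdate 01-JAN-2000 {rec.paradigm}", 80))
    header.write(fixed("01.01.00", 8))
    header.write(fixed("00.00.00", 8))
    header.write(fixed(str(256 * (1 + n_sig)), 8))
    header.write(fixed("EDF+C", 44))
    header.write(fixed(str(n_records), 8))
    header.write(fixed("1", 8))
    header.write(fixed(str(n_sig), 4))
    for field_width, values in (
        (16, list(rec.channel_labels)),
        (80, ["AgAgCl electrode"] * n_sig),
        (8, ["uV"] * n_sig),
        (8, [f"{v:.6g}"[:8] for v in phys_min]),
        (8, [f"{v:.6g}"[:8] for v in phys_max]),
        (8, [str(dig_min)] * n_sig),
        (8, [str(dig_max)] * n_sig),
        (80, [""] * n_sig),
        (8, [str(spr)] * n_sig),
        (32, [""] * n_sig),
    ):
        for v in values:
            header.write(fixed(str(v), field_width))

    with open(path, "wb") as fh:
        fh.write(header.getvalue())
        for r in range(n_records):
            chunk = data[:, r * spr : (r + 1) * spr]
            digital = np.round(chunk * scale[:, None]).astype("<i2")
            fh.write(digital.tobytes())
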