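"""Reading/writing EEG signals and labels, and cutting recordings into epochs.

Signals are handled as plain numpy arrays of amplitudes in microvolts (uV).
Two on-disk signal formats are supported: European Data Format (EDF/EDF+,
read-only, via :mod:`mne`) and CSV with one column per channel, a header row
of channel names and no timestamps; the sampling rate of a CSV signal must be
supplied by the caller because the format carries none.

Label files (CSV or JSON) assign each epoch one class out of
``{normal, sharp, ssw, unlabeled}`` and may additionally carry within-epoch
wave annotations (``wave_type``, inclusive 0-based ``start_index`` /
``end_index``) used for threshold calibration.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._exceptions import (
    LabelValidationError,
    MissingParameterError,
    SignalFormatError,
)

EPOCH_LABELS = ("normal", "sharp", "ssw", "unlabeled")
WAVE_TYPES = ("sharp", "sw")

_LABEL_COLUMNS = ["epoch_index", "label", "wave_type", "start_index", "end_index"]


@dataclass
class Epoch:
    """One fixed-length signal segment.

    Parameters
    ----------
    samples : ndarray
        Amplitude values in uV.
    fs : float
        Sampling rate in Hz (> 0).
    label : str
        One of ``{normal, sharp, ssw, unlabeled}``.
    channel_id : str, optional
        Identifier of the source channel.
    start_time : float
        Offset of the epoch from the start of the recording, in seconds.
    """

    samples: np.ndarray
    fs: float
    label: str = "unlabeled"
    channel_id: str | None = None
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("epoch samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("epoch samples must be finite")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if self.label not in EPOCH_LABELS:
            raise LabelValidationError(
                f"unknown epoch label {self.label!r}; expected one of {EPOCH_LABELS}"
            )

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class WaveAnnotation:
    """A manually or synthetically annotated wave range within an epoch.

    Indices are 0-based and inclusive on both ends.
    """

    epoch_index: int
    wave_type: str
    start_index: int
    end_index: int

    def __post_init__(self) -> None:
        if self.wave_type not in WAVE_TYPES:
            raise LabelValidationError(
                f"unknown wave type {self.wave_type!r}; expected one of {WAVE_TYPES}"
            )
        if self.epoch_index < 0:
            raise LabelValidationError("epoch_index must be >= 0")
        if not 0 <= self.start_index <= self.end_index:
            raise LabelValidationError(
                f"annotation range [{self.start_index}, {self.end_index}] is invalid"
            )


def read_signal(
    path: str | Path,
    fmt: str | None = None,
    fs: float | None = None,
) -> tuple[list[np.ndarray], float, list[str]]:
    """Read a multichannel signal file.

    Parameters
    ----------
    path : path
        Signal file, ``.edf`` or ``.csv``.
    fmt : {"edf", "csv"}, optional
        Format override; inferred from the file suffix when omitted.
    fs : float, optional
        Sampling rate in Hz; required for CSV (the format has no header field
        for it), ignored for EDF (taken from the EDF header).

    Returns
    -------
    (channels, fs, names)
        List of equal-length 1-d float arrays in uV, the sampling rate, and
        the channel names.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lower().lstrip(".")
    if fmt == "edf":
        return _read_edf(path)
    if fmt == "csv":
        if fs is None:
            raise MissingParameterError(
                "reading a CSV signal requires an explicit sampling rate (fs)"
            )
        return _read_csv_signal(path, float(fs))
    raise SignalFormatError(f"unsupported signal format {fmt!r}")


def _read_edf(path: Path) -> tuple[list[np.ndarray], float, list[str]]:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - mne is a hard dependency
        raise SignalFormatError("EDF support requires the mne package") from exc
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:
        raise SignalFormatError(f"could not parse {path} as EDF: {exc}") from exc
    data = raw.get_data() * 1e6  # mne returns Volts; convert to uV
    fs = float(raw.info["sfreq"])
    return [np.asarray(row, dtype=float) for row in data], fs, list(raw.ch_names)


def _read_csv_signal(path: Path, fs: float) -> tuple[list[np.ndarray], float, list[str]]:
    try:
        frame = pd.read_csv(path)
    except Exception as exc:
        raise SignalFormatError(f"could not parse {path} as CSV: {exc}") from exc
    if frame.shape[0] == 0 or frame.shape[1] == 0:
        raise SignalFormatError(f"{path} contains no samples")
    channels = []
    for name in frame.columns:
        col = pd.to_numeric(frame[name], errors="coerce").to_numpy(dtype=float)
        if np.isnan(col).any():
            raise SignalFormatError(f"non-numeric samples in column {name!r} of {path}")
        channels.append(col)
    return channels, fs, [str(c) for c in frame.columns]


def write_signal(path: str | Path, channels: Sequence[np.ndarray], names: Sequence[str] | None = None) -> None:
    """Write channels as the CSV dialect read by :func:`read_signal`."""
    channels = [np.asarray(c, dtype=float) for c in channels]
    if not channels:
        raise ValueError("no channels to write")
    if len({c.size for c in channels}) != 1:
        raise ValueError("all channels must have the same length")
    if names is None:
        names = [f"ch{i}" for i in range(len(channels))]
    frame = pd.DataFrame({n: c for n, c in zip(names, channels)})
    frame.to_csv(path, index=False)


def segment_epochs(
    signal: Sequence[float] | np.ndarray,
    fs: float,
    epoch_seconds: float = 5.0,
    label: str = "unlabeled",
    channel_id: str | None = None,
) -> list[Epoch]:
    """Cut a continuous signal into non-overlapping consecutive epochs.

    A trailing remainder shorter than one epoch is dropped. An epoch longer
    than the whole signal yields an empty list.
    """
    if not epoch_seconds > 0:
        raise ValueError("epoch_seconds must be positive")
    signal = np.asarray(signal, dtype=float)
    n_len = int(round(epoch_seconds * fs))
    n_epochs = signal.size // n_len
    return [
        Epoch(
            samples=signal[i * n_len : (i + 1) * n_len],
            fs=fs,
            label=label,
            channel_id=channel_id,
            start_time=i * epoch_seconds,
        )
        for i in range(n_epochs)
    ]


def write_labels(
    path: str | Path,
    labels: Iterable[tuple[int, str]],
    annotations: Iterable[WaveAnnotation] = (),
) -> None:
    """Write epoch labels and optional wave annotations to CSV or JSON.

    The CSV layout has one row per record with columns
    ``epoch_index,label,wave_type,start_index,end_index``; label rows leave
    the wave columns empty and annotation rows leave ``label`` empty.
    """
    labels = list(labels)
    annotations = list(annotations)
    for idx, lab in labels:
        if lab not in EPOCH_LABELS:
            raise LabelValidationError(f"unknown epoch label {lab!r}")
        if idx < 0:
            raise LabelValidationError("epoch_index must be >= 0")
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "labels": [{"epoch_index": int(i), "label": l} for i, l in labels],
            "annotations": [
                {
                    "epoch_index": a.epoch_index,
                    "wave_type": a.wave_type,
                    "start_index": a.start_index,
                    "end_index": a.end_index,
                }
                for a in annotations
            ],
        }
        path.write_text(json.dumps(payload, indent=1))
        return
    rows = [
        {"epoch_index": int(i), "label": l, "wave_type": "", "start_index": "", "end_index": ""}
        for i, l in labels
    ]
    rows += [
        {
            "epoch_index": a.epoch_index,
            "label": "",
            "wave_type": a.wave_type,
            "start_index": a.start_index,
            "end_index": a.end_index,
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=_LABEL_COLUMNS).to_csv(path, index=False)


def read_labels(path: str | Path) -> tuple[list[tuple[int, str]], list[WaveAnnotation]]:
    """Read a label file written by :func:`write_labels` (lossless round-trip)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        labels = [(int(r["epoch_index"]), str(r["label"])) for r in payload.get("labels", [])]
        annotations = [
            WaveAnnotation(
                epoch_index=int(r["epoch_index"]),
                wave_type=str(r["wave_type"]),
                start_index=int(r["start_index"]),
                end_index=int(r["end_index"]),
            )
            for r in payload.get("annotations", [])
        ]
    else:
        try:
            frame = pd.read_csv(path, keep_default_na=False, dtype=str)
        except Exception as exc:
            raise SignalFormatError(f"could not parse {path} as a label CSV: {exc}") from exc
        labels = []
        annotations = []
        for _, row in frame.iterrows():
            if row.get("label", ""):
                labels.append((int(row["epoch_index"]), str(row["label"])))
            else:
                annotations.append(
                    WaveAnnotation(
                        epoch_index=int(row["epoch_index"]),
                        wave_type=str(row["wave_type"]),
                        start_index=int(row["start_index"]),
                        end_index=int(row["end_index"]),
                    )
                )
    for _, lab in labels:
        if lab not in EPOCH_LABELS:
            raise LabelValidationError(f"unknown epoch label {lab!r}")
    return labels, annotations
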