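"""Reading, validating and segmenting EEG recordings.

An :class:`EEGRecord` is a multi-channel voltage time series with a sampling
rate and a seizure-onset time (seconds from record start).  The analysis
operates on the *preictal* portion of a single focal channel, extracted by
:func:`extract_preictal` as a :class:`PreictalSegment` whose time axis is
re-expressed relative to seizure onset (negative = before onset).

Supported on-disk formats: delimited text (one sample per row, one channel
per column; whitespace, comma or tab auto-detected) and flat channel-
interleaved signed 16-bit binary as produced by clinical EEG exports with
16-bit analog-to-digital conversion.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import (
    FormatError,
    InsufficientHistoryError,
    ParseError,
    TruncationError,
)

__all__ = [
    "EEGRecord",
    "PreictalSegment",
    "SegmentSpec",
    "read_eeg_text",
    "read_eeg_int16",
    "write_eeg_text",
    "extract_preictal",
]


@dataclass
class EEGRecord:
    """A sampled voltage time series, one row per channel.

    Parameters
    ----------
    samples
        Array of shape ``(n_channels, n_samples)`` in arbitrary amplitude
        units (clinical exports are raw ADC counts).
    sampling_rate_hz
        Samples per second per channel; must be positive.
    seizure_onset_s
        Seizure onset in seconds from the start of the record.
    channel_labels
        One identifier per channel; defaults to ``ch0, ch1, ...``.
    record_id
        Patient/seizure key used to name output files.
    """

    samples: np.ndarray
    sampling_rate_hz: float
    seizure_onset_s: float
    channel_labels: list[str] = field(default_factory=list)
    record_id: str = "record"

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.ndim != 2 or self.samples.shape[1] < 1:
            raise ValueError("samples must be a (n_channels, n_samples>=1) array")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.seizure_onset_s < 0:
            raise ValueError("seizure_onset_s must be non-negative")
        if self.seizure_onset_s > self.duration_s + 0.5 / self.sampling_rate_hz:
            raise ValueError(
                f"seizure onset at {self.seizure_onset_s} s lies beyond the "
                f"record duration of {self.duration_s} s"
            )
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("one label per channel required")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def channel(self, key: int | str) -> np.ndarray:
        """Return one channel's samples by index or label."""
        if isinstance(key, str):
            try:
                key = self.channel_labels.index(key)
            except ValueError:
                raise KeyError(
                    f"channel {key!r} not in {self.channel_labels}"
                ) from None
        if not 0 <= key < self.n_channels:
            raise KeyError(f"channel index {key} out of range")
        return self.samples[key]


@dataclass(frozen=True)
class SegmentSpec:
    """Preictal window, in minutes before seizure onset.

    The default fitting window runs from 32 to 4 minutes before onset; the
    display window (used for the moving average) runs to onset itself.
    """

    start_min_before_onset: float = 32.0
    end_min_before_onset: float = 4.0

    def __post_init__(self) -> None:
        if not self.start_min_before_onset > self.end_min_before_onset:
            raise ValueError("segment start must precede its end")
        if self.end_min_before_onset < 0:
            raise ValueError("segment end cannot lie after onset")

    @property
    def duration_min(self) -> float:
        return self.start_min_before_onset - self.end_min_before_onset


@dataclass
class PreictalSegment:
    """A single-channel segment with its time axis anchored to onset."""

    samples: np.ndarray
    sampling_rate_hz: float
    start_s_rel_onset: float
    record_id: str = "record"
    channel_label: str = "ch0"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()

    @property
    def n_samples(self) -> int:
        return self.samples.size


_DELIMS = {",": ",", "\t": "\t"}


def _detect_delimiter(first_line: str) -> str | None:
    """Return ',' or '\\t' if present in the header line, else None (whitespace)."""
    for d in _DELIMS:
        if d in first_line:
            return d
    return None


def _diagnose_text(lines: list[str], delim: str | None) -> None:
    """Locate the offending cell/row for a precise error message."""
    width = None
    for i, line in enumerate(lines):
        cells = line.split(delim) if delim else line.split()
        if width is None:
            width = len(cells)
        elif len(cells) != width:
            raise FormatError(
                f"ragged row {i + 1}: expected {width} columns, found {len(cells)}"
            )
        for j, cell in enumerate(cells):
            try:
                float(cell)
            except ValueError:
                raise ParseError(
                    f"non-numeric value {cell!r} at row {i + 1}, column {j + 1}"
                ) from None


def read_eeg_text(
    path: str | Path,
    sampling_rate_hz: float,
    onset_s: float,
    record_id: str | None = None,
    channel_labels: Sequence[str] | None = None,
) -> EEGRecord:
    """Read a delimited-text EEG file (one sample per row, one channel per column).

    The delimiter (whitespace, comma or tab) is auto-detected from the first
    line.  Lines starting with ``#`` are ignored.
    """
    path = Path(path)
    raw = path.read_text()
    lines = [ln for ln in raw.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise FormatError(f"{path}: no data rows")
    delim = _detect_delimiter(lines[0])
    try:
        data = np.loadtxt(io.StringIO("\n".join(lines)), delimiter=delim, ndmin=2)
    except ValueError:
        _diagnose_text(lines, delim)  # raises with row/column detail
        raise  # pragma: no cover - diagnosis always raises first
    return EEGRecord(
        samples=data.T,
        sampling_rate_hz=sampling_rate_hz,
        seizure_onset_s=onset_s,
        channel_labels=list(channel_labels) if channel_labels else [],
        record_id=record_id or path.stem,
    )


def write_eeg_text(record: EEGRecord, path: str | Path, fmt: str = "%.6f") -> Path:
    """Write a record as tab-separated text; inverse of :func:`read_eeg_text`."""
    path = Path(path)
    np.savetxt(path, record.samples.T, fmt=fmt, delimiter="\t")
    return path


def read_eeg_int16(
    path: str | Path,
    n_channels: int,
    sampling_rate_hz: float,
    onset_s: float,
    byte_order: str = "little",
    record_id: str | None = None,
) -> EEGRecord:
    """Read flat channel-interleaved signed 16-bit samples.

    Matches the raw export of clinical acquisition systems that digitize with
    a 16-bit converter and store frames of ``n_channels`` consecutive int16
    values.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if byte_order not in ("little", "big"):
        raise ValueError("byte_order must be 'little' or 'big'")
    path = Path(path)
    nbytes = path.stat().st_size
    frame = 2 * n_channels
    if nbytes % frame:
        raise TruncationError(
            f"{path}: {nbytes} bytes is not a whole number of "
            f"{frame}-byte frames ({n_channels} channels x int16)"
        )
    dtype = "<i2" if byte_order == "little" else ">i2"
    data = np.fromfile(path, dtype=dtype).reshape(-1, n_channels)
    return EEGRecord(
        samples=data.T.astype(float),
        sampling_rate_hz=sampling_rate_hz,
        seizure_onset_s=onset_s,
        record_id=record_id or path.stem,
    )


def extract_preictal(
    record: EEGRecord, channel: int | str, spec: SegmentSpec
) -> PreictalSegment:
    """Extract the half-open preictal window [onset-start, onset-end).

    The returned segment's sample count is ``duration_min * 60 * rate``
    rounded down, and its time axis is relative to seizure onset (so the
    first sample sits at ``-start_min_before_onset * 60`` seconds).
    """
    sig = record.channel(channel)
    rate = record.sampling_rate_hz
    start_s = record.seizure_onset_s - spec.start_min_before_onset * 60.0
    if start_s < -0.5 / rate:
        raise InsufficientHistoryError(
            f"window starts {-start_s:.1f} s before the record does "
            f"({spec.start_min_before_onset} min requested, onset at "
            f"{record.seizure_onset_s / 60:.1f} min)"
        )
    i0 = int(round(start_s * rate))
    n = int(np.floor(spec.duration_min * 60.0 * rate))
    if i0 + n > record.n_samples:
        raise InsufficientHistoryError(
            f"window extends {i0 + n - record.n_samples} samples past record end"
        )
    label = channel if isinstance(channel, str) else record.channel_labels[channel]
    return PreictalSegment(
        samples=sig[i0 : i0 + n].copy(),
        sampling_rate_hz=rate,
        start_s_rel_onset=-spec.start_min_before_onset * 60.0,
        record_id=record.record_id,
        channel_label=label,
    )
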