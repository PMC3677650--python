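"""Windowed normalized spectral entropy (SEN).

The band-filtered signal is cut into non-overlapping 16 s windows (4096
samples at 256 Hz).  Each window's power spectrum is taken at the positive
DFT frequencies and aggregated into 1024 uniform bins spanning (0, rate/2]:
a 4096-point real DFT yields 2048 positive-frequency values, so adjacent
pairs are summed.  No taper is applied before the FFT.

The spectral entropy of a window restricted to a band is

    SEN = - sum_k P_k log P_k / log(N)

where the P_k are the in-band bin powers normalized to sum to 1 and N is
the number of in-band bins.  Normalizing by log N bounds SEN to [0, 1]
(1 = flat spectrum, 0 = all power in one bin) and makes the value
independent of the logarithm base.  N counts the bins of the analyzed band,
not of the whole spectrum: entropy is computed per band-filtered vector,
and a full-spectrum N would prevent an in-band-flat spectrum from reaching
SEN = 1.  A window with zero in-band power has undefined entropy and is
reported as NaN (missing), never silently as 0 or 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .bands import BandDefinition

__all__ = [
    "SpectralWindow",
    "EntropySeries",
    "window_signal",
    "power_spectrum",
    "spectral_entropy",
    "entropy_series",
    "DEFAULT_WINDOW_SAMPLES",
    "DEFAULT_N_BINS",
]

log = logging.getLogger(__name__)

DEFAULT_WINDOW_SAMPLES = 4096
DEFAULT_N_BINS = 1024


@dataclass
class SpectralWindow:
    """One analysis window: its placement and (once computed) its spectrum."""

    start_s_rel_onset: float
    length_samples: int
    slice_start: int
    power: np.ndarray | None = None
    bin_freqs_hz: np.ndarray | None = None

    @property
    def center_s_rel_onset(self) -> float:
        return self.start_s_rel_onset + 0.5 * self.duration_s

    @property
    def duration_s(self) -> float:
        # set by entropy_series / window_signal via _rate
        return self.length_samples / self._rate

    _rate: float = field(default=256.0, repr=False)


@dataclass
class EntropySeries:
    """Per-window SEN values for one band; times are window centers in minutes
    relative to seizure onset (negative = preictal).  Undefined windows are NaN."""

    band: str
    times_min_rel_onset: np.ndarray
    sen: np.ndarray
    n_bins_used: int
    record_id: str = "record"

    def __post_init__(self) -> None:
        self.times_min_rel_onset = np.asarray(self.times_min_rel_onset, dtype=float)
        self.sen = np.asarray(self.sen, dtype=float)
        if self.times_min_rel_onset.shape != self.sen.shape:
            raise ValueError("times and sen must have the same length")
        finite = self.sen[np.isfinite(self.sen)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("SEN values must lie in [0, 1]")

    def __len__(self) -> int:
        return self.sen.size


def window_signal(
    signal: np.ndarray,
    rate_hz: float,
    window_samples: int = DEFAULT_WINDOW_SAMPLES,
    start_s_rel_onset: float = 0.0,
) -> list[SpectralWindow]:
    """Cut a signal into non-overlapping windows; the trailing remainder is
    discarded.  Returns an empty list (with a warning) if the signal is
    shorter than one window."""
    if window_samples < 2:
        raise ValueError("window_samples must be >= 2")
    signal = np.asarray(signal)
    n_win = signal.size // window_samples
    if n_win == 0:
        log.warning(
            "signal of %d samples shorter than one %d-sample window; no windows",
            signal.size,
            window_samples,
        )
        return []
    dur = window_samples / rate_hz
    return [
        SpectralWindow(
            start_s_rel_onset=start_s_rel_onset + i * dur,
            length_samples=window_samples,
            slice_start=i * window_samples,
            _rate=rate_hz,
        )
        for i in range(n_win)
    ]


def power_spectrum(
    window: SpectralWindow,
    signal_slice: np.ndarray,
    rate_hz: float,
    n_bins: int = DEFAULT_N_BINS,
) -> SpectralWindow:
    """Fill the window with its binned power spectrum.

    Squared-magnitude DFT at positive frequencies, summed into ``n_bins``
    uniform bins spanning (0, rate/2].  The DC component is excluded;
    total power is preserved across the aggregation.
    """
    x = np.asarray(signal_slice, dtype=float)
    if x.size != window.length_samples:
        raise ValueError(
            f"slice of {x.size} samples does not match window length "
            f"{window.length_samples}"
        )
    spec = np.abs(np.fft.rfft(x)) ** 2
    pos = spec[1:]  # drop DC; keeps window_samples//2 positive-frequency values
    if pos.size % n_bins:
        raise ValueError(
            f"{pos.size} positive frequencies cannot be aggregated into "
            f"{n_bins} uniform bins"
        )
    group = pos.size // n_bins
    window.power = pos.reshape(n_bins, group).sum(axis=1)
    bin_width = (rate_hz / 2.0) / n_bins
    window.bin_freqs_hz = (np.arange(n_bins) + 0.5) * bin_width
    window._rate = rate_hz
    return window


def spectral_entropy(window: SpectralWindow, band: BandDefinition) -> float:
    """Normalized Shannon entropy of the in-band spectrum; NaN if the band
    carries no power."""
    if window.power is None or window.bin_freqs_hz is None:
        raise ValueError("power spectrum not computed for this window")
    mask = (window.bin_freqs_hz >= band.f_lo_hz) & (window.bin_freqs_hz < band.f_hi_hz)
    n_band = int(mask.sum())
    if n_band < 2:
        raise ValueError(
            f"band {band.name!r} covers {n_band} bin(s); need at least 2"
        )
    p = window.power[mask]
    total = p.sum()
    if total <= 0:
        return float("nan")
    p = p / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / math.log(n_band))


def band_bin_count(
    band: BandDefinition,
    rate_hz: float,
    n_bins: int = DEFAULT_N_BINS,
) -> int:
    """Number of spectrum bins whose centers fall inside the band."""
    bin_width = (rate_hz / 2.0) / n_bins
    centers = (np.arange(n_bins) + 0.5) * bin_width
    return int(((centers >= band.f_lo_hz) & (centers < band.f_hi_hz)).sum())


def entropy_series(
    band_signal: np.ndarray,
    band: BandDefinition,
    rate_hz: float,
    window_samples: int = DEFAULT_WINDOW_SAMPLES,
    start_s_rel_onset: float = 0.0,
    n_bins: int = DEFAULT_N_BINS,
    record_id: str = "record",
) -> EntropySeries:
    """Windowed SEN of one band-filtered signal.

    Composition of :func:`window_signal`, :func:`power_spectrum` and
    :func:`spectral_entropy`; windows with undefined entropy are carried
    as NaN.
    """
    band_signal = np.asarray(band_signal, dtype=float)
    windows = window_signal(band_signal, rate_hz, window_samples, start_s_rel_onset)
    times = np.empty(len(windows))
    sen = np.empty(len(windows))
    for i, w in enumerate(windows):
        sl = band_signal[w.slice_start : w.slice_start + w.length_samples]
        power_spectrum(w, sl, rate_hz, n_bins=n_bins)
        times[i] = w.center_s_rel_onset / 60.0
        sen[i] = spectral_entropy(w, band)
        w.power = None  # release; only the entropy is kept
    return EntropySeries(
        band=band.name,
        times_min_rel_onset=times,
        sen=sen,
        n_bins_used=band_bin_count(band, rate_hz, n_bins),
        record_id=record_id,
    )
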