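"""Synthetic single-channel preictal EEG with known spectral ground truth.

The generator emulates the gross features of an invasive focal-EEG record
digitized at 256 Hz: a 1/f^alpha Gaussian background, optional 50 Hz line
contamination, Poisson-timed biphasic spike transients, and -- the part the
analysis is built to detect -- a programmed linear drift of the normalized
spectral entropy (SEN) inside chosen frequency bands.  Seizure onset is
placed at the end of the record, so the default 50-minute record always
covers the 32-to-4-minute preictal analysis window.

Drift mechanism
---------------
SEN responds to spectral *shape*, not power, so a drift is realized as a
time-varying convex power mixture between two unit-variance in-band
processes: a narrowband one (concentrated spectrum, low SEN) and a
broadband one (flat in-band spectrum, high SEN).  Writing the expected
in-band spectrum of background + mixture as a function of the mixing
weight m gives a monotone curve SEN(m); the generator inverts this curve
numerically so that the expected SEN trajectory is *exactly* linear with
the requested slope (in SEN units per minute).  A requested trajectory
that leaves the achievable [SEN(0), SEN(1)] range raises
:class:`~eegsen.errors.InfeasibleDriftError`.

All randomness derives from a single integer seed; identical specs produce
bit-identical signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .bands import DEFAULT_BANDS, BandDefinition
from .eeg_io import EEGRecord
from .entropy import DEFAULT_N_BINS
from .errors import InfeasibleDriftError

__all__ = [
    "SyntheticSpec",
    "BandGroundTruth",
    "GroundTruth",
    "generate",
    "pink_noise",
    "inject_spikes",
    "spike_template",
]

_GEN_NUMTAPS = 1025  # generator-internal FIR length (sharp, independent of the analysis filters)


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic record.

    Amplitudes are relative to the unit-variance background.  ``drift`` maps
    a band name to a signed SEN rate in entropy units per minute; bands not
    listed contain background only.  ``band_power_ratio`` sets the in-band
    power of a drifting band's mixture component relative to the in-band
    background power (intracranial focal rhythms typically dominate the
    broadband floor severalfold).
    """

    duration_min: float = 50.0
    rate_hz: float = 256.0
    background_exponent: float = 1.0
    line_noise_amp: float = 0.0
    spike_rate_per_min: float = 0.0
    spike_amp: float = 8.0
    drift: dict[str, float] = field(default_factory=dict)
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    band_power_ratio: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.duration_min * 60.0 * self.rate_hz
        if abs(n - round(n)) > 1e-6:
            raise ValueError("duration_min * 60 * rate_hz must be an integer sample count")
        known = {b.name for b in self.bands}
        unknown = set(self.drift) - known
        if unknown:
            raise ValueError(f"drift names unknown bands {sorted(unknown)}")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_min * 60.0 * self.rate_hz))


@dataclass(frozen=True)
class BandGroundTruth:
    """Programmed SEN trajectory of one band."""

    band: str
    drift_per_min: float
    sen_start: float
    sen_end: float
    sen_range: tuple[float, float]  # achievable [SEN(m=0), SEN(m=1)]


@dataclass(frozen=True)
class GroundTruth:
    seizure_onset_s: float
    bands: dict[str, BandGroundTruth]
    spec: SyntheticSpec


def pink_noise(n: int, alpha: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise with power spectral density ~ 1/f^alpha.

    Built by shaping a white complex spectrum with f^(-alpha/2) and inverse
    transforming; DC is zeroed.
    """
    n_freq = n // 2 + 1
    shape = np.zeros(n_freq)
    freqs = np.fft.rfftfreq(n, d=1.0)  # units cancel in the shaping
    shape[1:] = freqs[1:] ** (-alpha / 2.0)
    spec = shape * (rng.standard_normal(n_freq) + 1j * rng.standard_normal(n_freq))
    spec[0] = 0.0
    if n % 2 == 0:
        spec[-1] = spec[-1].real
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def spike_template(rate_hz: float) -> np.ndarray:
    """Epileptiform transient, ~70 ms, peak amplitude 1.

    The sharp apex is modeled as a Gabor atom -- a damped 60 Hz cosine with
    an 8 ms Gaussian envelope -- superimposed on a slower negative
    after-wave.  The oscillatory core places the transient's power in the
    20-80 Hz range where intracranial epileptiform spikes concentrate
    theirs, so injected spikes visibly perturb the high-band spectrum.
    """
    sigma = 8e-3
    t = np.arange(-4.0 * sigma, 4.0 * sigma, 1.0 / rate_hz)
    core = np.exp(-(t**2) / (2 * sigma**2)) * np.cos(2 * np.pi * 60.0 * t)
    slow = -0.4 * np.exp(-((t - 0.02) ** 2) / (2 * 0.012**2))
    tpl = core + slow
    return tpl / np.abs(tpl).max()


def inject_spikes(
    signal: np.ndarray,
    rate_hz: float,
    rate_per_min: float,
    amp: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Add Poisson-timed biphasic spike transients to a signal.

    The expected spike count is ``rate_per_min`` times the duration in
    minutes.  ``rate_per_min = 0`` returns the signal unchanged.
    """
    if rate_per_min < 0:
        raise ValueError("rate_per_min must be >= 0")
    x = np.asarray(signal, dtype=float).copy()
    if rate_per_min == 0:
        return x
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    duration_min = x.size / rate_hz / 60.0
    count = rng.poisson(rate_per_min * duration_min)
    template = amp * spike_template(rate_hz)
    starts = rng.integers(0, x.size, size=count)
    for s in np.sort(starts):
        end = min(s + template.size, x.size)
        x[s:end] += template[: end - s]
    return x


def _bin_centers(rate_hz: float, n_bins: int) -> np.ndarray:
    return (np.arange(n_bins) + 0.5) * (rate_hz / 2.0) / n_bins


def _power_response(taps: np.ndarray, freqs_hz: np.ndarray, rate_hz: float) -> np.ndarray:
    _, h = sps.freqz(taps, worN=freqs_hz, fs=rate_hz)
    return np.abs(h) ** 2


def _sen(power: np.ndarray) -> float:
    p = power / power.sum()
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(p.size))


def _narrow_edges(band: BandDefinition) -> tuple[float, float]:
    """A narrow sub-band near the band's lower third, wide enough to design."""
    width = max(0.5, 0.03 * (band.f_hi_hz - band.f_lo_hz))
    center = band.f_lo_hz + 0.3 * (band.f_hi_hz - band.f_lo_hz)
    return center - width / 2.0, center + width / 2.0


class _DriftComponent:
    """Precomputed SEN(m) inversion machinery for one drifting band."""

    def __init__(self, band: BandDefinition, spec: SyntheticSpec):
        rate = spec.rate_hz
        nyq = rate / 2.0
        centers = _bin_centers(rate, DEFAULT_N_BINS)
        in_band = (centers >= band.f_lo_hz) & (centers < band.f_hi_hz)

        if band.f_hi_hz >= nyq - 1e-9:
            self.broad_taps = sps.firwin(
                _GEN_NUMTAPS, band.f_lo_hz, window="hamming", pass_zero=False, fs=rate
            )
        else:
            self.broad_taps = sps.firwin(
                _GEN_NUMTAPS, [band.f_lo_hz, band.f_hi_hz], window="hamming",
                pass_zero=False, fs=rate,
            )
        lo, hi = _narrow_edges(band)
        self.narrow_taps = sps.firwin(
            _GEN_NUMTAPS, [lo, hi], window="hamming", pass_zero=False, fs=rate
        )

        # expected in-band bin powers: unit-variance 1/f^alpha background plus
        # the two mixture components scaled to band_power_ratio x background
        bg = centers ** (-spec.background_exponent)
        bg /= bg.sum()  # fraction of unit background variance per bin
        bg_band = bg[in_band]
        v_comp = spec.band_power_ratio * bg_band.sum()

        narrow = _power_response(self.narrow_taps, centers[in_band], rate)
        broad = _power_response(self.broad_taps, centers[in_band], rate)
        narrow /= narrow.sum()
        broad /= broad.sum()

        self.m_grid = np.linspace(0.0, 1.0, 401)
        self.sen_grid = np.array(
            [
                _sen(bg_band + v_comp * ((1 - m) * narrow + m * broad))
                for m in self.m_grid
            ]
        )
        if not np.all(np.diff(self.sen_grid) > 0):
            # guard: the mixture curve must be monotone for inversion
            order = np.argsort(self.sen_grid)
            self.m_grid, self.sen_grid = self.m_grid[order], self.sen_grid[order]
        self.v_comp = v_comp

    @property
    def sen_range(self) -> tuple[float, float]:
        return float(self.sen_grid[0]), float(self.sen_grid[-1])

    def mixing_for_sen(self, sen_target: np.ndarray) -> np.ndarray:
        lo, hi = self.sen_range
        if sen_target.min() < lo - 1e-9 or sen_target.max() > hi + 1e-9:
            raise InfeasibleDriftError(
                f"requested SEN trajectory [{sen_target.min():.3f}, "
                f"{sen_target.max():.3f}] leaves the achievable range "
                f"[{lo:.3f}, {hi:.3f}]"
            )
        return np.interp(sen_target, self.sen_grid, self.m_grid)


def generate(spec: SyntheticSpec) -> tuple[EEGRecord, GroundTruth]:
    """Generate one synthetic record and its ground truth.

    The record is single-channel with seizure onset at the record end.
    """
    n = spec.n_samples
    rate = spec.rate_hz
    seeds = np.random.SeedSequence(spec.seed).spawn(3 + 2 * len(spec.drift))
    rng_bg = np.random.default_rng(seeds[0])
    rng_line = np.random.default_rng(seeds[1])

    x = pink_noise(n, spec.background_exponent, rng_bg)

    if spec.line_noise_amp > 0:
        t = np.arange(n) / rate
        phase = rng_line.uniform(0, 2 * np.pi)
        x = x + spec.line_noise_amp * np.sin(2 * np.pi * 50.0 * t + phase)

    t_min = np.arange(n) / rate / 60.0
    t_mid = spec.duration_min / 2.0
    truth_bands: dict[str, BandGroundTruth] = {}
    band_by_name = {b.name: b for b in spec.bands}
    for i, (name, drift) in enumerate(sorted(spec.drift.items())):
        comp = _DriftComponent(band_by_name[name], spec)
        lo, hi = comp.sen_range
        sen_mid = (lo + hi) / 2.0
        sen_target = sen_mid + drift * (t_min - t_mid)
        m = comp.mixing_for_sen(sen_target)
        rng_n = np.random.default_rng(seeds[3 + 2 * i])
        rng_b = np.random.default_rng(seeds[4 + 2 * i])
        narrow_u = sps.fftconvolve(rng_n.standard_normal(n), comp.narrow_taps, mode="full")[:n]
        broad_u = sps.fftconvolve(rng_b.standard_normal(n), comp.broad_taps, mode="full")[:n]
        narrow_u /= np.sqrt(np.sum(comp.narrow_taps ** 2))
        broad_u /= np.sqrt(np.sum(comp.broad_taps ** 2))
        x = x + np.sqrt(comp.v_comp) * (
            np.sqrt(1.0 - m) * narrow_u + np.sqrt(m) * broad_u
        )
        truth_bands[name] = BandGroundTruth(
            band=name,
            drift_per_min=drift,
            sen_start=float(sen_target[0]),
            sen_end=float(sen_target[-1]),
            sen_range=(lo, hi),
        )

    if spec.spike_rate_per_min > 0:
        x = inject_spikes(
            x, rate, spec.spike_rate_per_min, spec.spike_amp,
            np.random.default_rng(seeds[2]),
        )

    onset_s = spec.duration_min * 60.0
    record = EEGRecord(
        samples=x[np.newaxis, :],
        sampling_rate_hz=rate,
        seizure_onset_s=onset_s,
        channel_labels=["synthetic"],
        record_id=f"synthetic-seed{spec.seed}",
    )
    return record, GroundTruth(seizure_onset_s=onset_s, bands=truth_bands, spec=spec)
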