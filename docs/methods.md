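# Methods

## Signal model and analysis pipeline

The analysis treats a single focal intracranial EEG channel, sampled at
256 Hz, in the half-open preictal window `[onset − 32 min, onset)`. Stage
order is fixed: segment extraction → 50 Hz notch → band decomposition →
windowed spectral entropy → trend fit and moving average. Entropy varies
with the *shape* of the spectrum, not its power, so the analysis is
invariant to amplitude calibration; raw ADC counts are acceptable input.

### Band decomposition

Three bands: low 0.1–12 Hz, mid 12–32 Hz, high 32–128 Hz. Each filter is a
windowed-sinc linear-phase FIR of order 40 (41 taps) with a Hamming taper
(`scipy.signal.firwin`). At 256 Hz the high band's upper edge is the
Nyquist frequency, so that filter is designed as a highpass at 32 Hz; a
bandpass with an edge at Nyquist is ill-posed. Filtering is causal
single-pass convolution with zero-padding at the segment start; the first
40 samples (< 0.2 s of a ≥ 28-min segment) are retained, and the ~80 ms
group delay is not compensated — it is common to all bands and negligible
against 16 s windows. A 41-tap Hamming design has a transition band of
roughly `3.3·fs/41 ≈ 21 Hz`, which matters twice:

* the low band's 0.1 Hz lower edge cannot be realized at this order; the
  filter passes down to DC with near-unity gain. Since the entropy is
  later restricted to bins at or above 0.1 Hz, this has no effect on SEN.
* no 41-tap FIR can notch 50 Hz by 20 dB while passing 45/55 Hz within
  3 dB. The notch is therefore a second-order IIR notch
  (`scipy.signal.iirnotch`, Q = 30, −3 dB width ≈ 1.7 Hz), the standard
  line-noise tool; it attenuates a steady 50 Hz tone by > 200 dB and
  5 Hz-distant components by far less than 3 dB.

### Spectral entropy

Each band-filtered segment is cut into non-overlapping 4096-sample (16 s)
windows; the trailing remainder is discarded. No taper is applied before
the FFT (the Hamming window belongs to the filter design, not the
spectrum). The 2048 positive-frequency squared magnitudes are summed in
adjacent pairs into 1024 uniform bins spanning (0, 128] Hz — the frequency
resolution is then 0.125 Hz per bin — and DC is excluded. Within a band
`[f_lo, f_hi)` (bin membership by bin center), with normalized powers
`P_k` over the `N` in-band bins,

    SEN = − Σ P_k ln P_k / ln N .

`N` is the in-band bin count (95 low, 160 mid, 768 high at defaults), not
the full 1024: the entropy is computed per band-filtered vector, and a
full-spectrum `N` would prevent an in-band-flat spectrum from reaching
SEN = 1. Both the binning (1024 vs raw 2048) and the normalization are
configurable. Zero-power windows yield NaN ("undefined"), which is carried
through and excluded from fits and averages — never imputed as 0 or 1.

### Trend and smoothing

The per-band trend is the OLS line of SEN on window-center time (minutes
relative to onset, negative preictal) over the half-open interval
[−32, −4) min, excluding the final 4 minutes where entropy can surge; `r`
is the Pearson correlation of the same points. Slopes are reported per
minute. Zero-variance series report slope 0 and are flagged degenerate
rather than dividing by zero. The 4-minute moving average is centered
(± 2 min, up to 15 windows at 16 s spacing), computed over the whole
segment including the final 4 minutes, with shrinking one-sided
neighborhoods at the edges.

### Cohort table

Per-patient `(slope, |r|)` triplets aggregate into a table with unweighted
column means and strict-positivity sign counts. Means are computed in
decimal arithmetic and displayed with round-half-up (slopes to 6 decimals,
|r| to 2), so a mean of 0.0054105 prints as 0.005411; float `round()`
would print 0.005410 at this knife edge. A packaged reference table of 20
published per-patient triplets (invasive focal-epilepsy cohort, Freiburg
seizure prediction dataset; the recordings themselves are not
redistributable) exercises this arithmetic: its column means are
0.000177 / 0.000188 / 0.005411 (slopes) and 0.20 / 0.15 / 0.07 (|r|), all
20 high-band slopes are positive, and exactly one low-band slope (patient
15) is negative.

## Synthetic records

The generator emulates the features of the preictal recordings the
pipeline must handle; defaults are one 50-minute single-channel record at
256 Hz with seizure onset at the record end (so the 32-minute analysis
window always fits).

* **Background**: unit-variance Gaussian noise with PSD ∝ 1/f^α, α = 1 by
  default, built by spectral shaping.
* **Line noise**: optional 50 Hz sinusoid with seeded random phase,
  amplitude relative to the background SD.
* **Spikes**: Poisson-timed fixed-waveform transients, ~70 ms, default
  peak amplitude 8× background SD. The waveform is a damped 60 Hz cosine
  (Gabor atom, σ = 8 ms) over a slow negative after-wave. The oscillatory
  core is deliberate: intracranial epileptiform spikes concentrate their
  power in the tens-of-Hz range, and it is that in-band content which
  perturbs the high-band spectrum. (A piecewise-linear biphasic wave of
  the same duration was evaluated first; its high-band energy is so small
  that injected spikes left the high-band entropy statistically
  unchanged, defeating the waveform's purpose.)
* **Entropy drift**: per band, a time-varying convex power mixture
  between two unit-variance in-band processes — narrowband (concentrated
  spectrum, low SEN) and broadband (flat in-band spectrum, high SEN) —
  each realized by sharp 1025-tap FIR filtering of white noise and scaled
  to 4× the in-band background power. Writing the expected in-band
  spectrum as a function of the mixing weight `m` gives a monotone curve
  SEN(m), computed analytically from the 1/f background and the
  generators' filter responses on the analysis binning; inverting it makes
  the expected SEN trajectory exactly linear with the requested rate
  (SEN/min), centered in the achievable range. Requests outside
  [SEN(0), SEN(1)] raise an infeasibility error, which also enforces the
  [0, 1] bound. Linearity of SEN in time is the modeling assumption of the
  trend analysis itself.

All randomness derives from one integer seed through spawned
`SeedSequence` streams; identical specs give bit-identical records.

What the generator does *not* model: multichannel spatial structure,
physiological rhythms (spindles, alpha), nonstationary artifacts,
reference changes, or the seizure itself. Passing pipeline tests on these
records demonstrates that the *estimator* recovers programmed spectral
drift under realistic noise — not that real preictal EEG drifts this way.
In particular, synthetic drifting records produce |r| near 0.9, an order
of magnitude above the ~0.07–0.2 reported on clinical data, because the
generator's drift is far cleaner than biological entropy fluctuations.

## Numerical choices and scale of the validation runs

* Windowed-FFT bins are aggregated pairwise exactly, preserving total
  power (Parseval ratio `N/2` against the sum of squares, DC removed).
* Natural logarithms are used internally; the ratio form makes SEN
  base-invariant (property-tested against a brute-force oracle).
* Boundary conventions are half-open throughout (segments, fit interval,
  band membership) to prevent double counting.
* The moving-average neighborhood test uses a 1e-9 min tolerance at the
  ±2 min boundary to absorb float jitter in window timestamps.
* Monte-Carlo validations use 20 seeds per condition: zero-drift records
  (slope within 3 standard errors of 0), +0.005 SEN/min high-band drift
  (sign recovery and median magnitude within 50%), and paired
  spike-injection runs at 10 spikes/min (high-band SEN variance
  increase). A 28-minute white-noise record per seed keeps each condition
  under a minute on one CPU; recovered drift slopes run ~7–11% above the
  programmed rate because the analysis band filter slightly reshapes the
  in-band spectrum relative to the generator's idealized expectation.

## Known limitations

* The notch and band filters are not zero-phase; absolute window
  timestamps carry a common ~80 ms delay.
* The low band's nominal 0.1 Hz lower edge is enforced by bin selection,
  not by the order-40 filter.
* Focal-channel choice is a required user input; the package applies no
  artifact rejection, re-referencing or montage logic.
* No seizure-detection threshold is provided; the outputs are the slopes
  and correlations themselves.
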