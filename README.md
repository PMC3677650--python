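# eegsen

Preictal EEG analysis by banded spectral entropy: decompose an
intracranial EEG channel into low (0.1–12 Hz), mid (12–32 Hz) and high
(32–128 Hz) frequency bands, track each band's normalized spectral entropy
in non-overlapping 16 s windows, and quantify its drift over the
32-to-4-minute interval before a seizure with a regression slope and
Pearson correlation. The package is aimed at seizure-prediction research:
a rising high-band entropy slope in the preictal period is the candidate
predictor this analysis measures.

## The statistic

For each 16 s window (4096 samples at 256 Hz) the power spectrum is
aggregated into 1024 uniform bins; within a band with `N` bins and
normalized bin powers `P_k` (`Σ P_k = 1`) the **spectral entropy** is

```
SEN = − Σ_k P_k log P_k / log N       ∈ [0, 1]
```

SEN is 1 for a flat in-band spectrum, 0 when all power sits in one bin, and
is invariant to amplitude scaling and to the logarithm base. Per band, an
ordinary least-squares line of SEN on time over the interval [−32, −4)
minutes relative to seizure onset gives the slope *p* (SEN/min) and the
correlation *r*; a 4-minute centered moving average is computed for
display. Per-patient `(p, |r|)` triplets aggregate into a cohort table with
column means and slope-sign counts.

Because clinical recordings of this kind are not redistributable, the
package includes a synthetic generator that produces 1/f background EEG
with optional 50 Hz line noise, epileptiform spike transients, and a
*programmed* linear SEN drift per band — giving known ground truth for
every pipeline stage.

## Worked example

Generate a 50-minute record with a programmed +0.005 SEN/min high-band
drift and run the full pipeline:

```python
from eegsen import SyntheticSpec, generate, PipelineConfig, run_record

rec, truth = generate(SyntheticSpec(seed=3, drift={"high": 0.005}))
bt = truth.bands["high"]
print(f"programmed high-band SEN drift: {bt.drift_per_min:+.3f}/min "
      f"({bt.sen_start:.3f} -> {bt.sen_end:.3f})")
for name, res in run_record(PipelineConfig(), rec, channel=0).items():
    tr = res.trend
    print(f"{name:>4}: slope {tr.slope_per_min:+.6f} SEN/min, "
          f"|r| {tr.abs_r:.2f}, n={tr.n_points}")
```

prints

```
programmed high-band SEN drift: +0.005/min (0.698 -> 0.948)
 low: slope +0.000246 SEN/min, |r| 0.05, n=105
 mid: slope +0.000052 SEN/min, |r| 0.08, n=105
high: slope +0.005345 SEN/min, |r| 0.91, n=105
```

The high band recovers the programmed drift (+0.005345 vs +0.005 per
minute) from the 105 entropy windows inside the fit interval, while the
two undriven bands show near-zero slopes. The same analysis is available
from the shell:

```
eegsen simulate --out rec.tsv --seed 3 --drift high=0.005
eegsen analyze rec.tsv --onset-s 3000 --out-dir out/
eegsen cohort out/ --out cohort.tsv
eegsen fixtures            # print the packaged 20-patient reference table
```

`analyze` writes per-band entropy series (`<id>.<band>.sen.tsv`), a trend
table and a JSON run manifest; `cohort` aggregates trend tables into the
per-patient summary with an Average row.

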