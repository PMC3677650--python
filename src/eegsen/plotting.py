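"""Optional visualization: entropy traces with regression line and moving average.

Requires matplotlib (install the ``plot`` extra). Cosmetic only; nothing in
the analysis depends on this module.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .pipeline import BandResult

__all__ = ["plot_record"]


def plot_record(results: dict[str, BandResult], path: str | Path) -> Path:
    """One panel per band: SEN trace, 4-min moving average, fitted line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(len(results), 1, figsize=(8, 2.4 * len(results)),
                             sharex=True, squeeze=False)
    for ax, (name, res) in zip(axes.ravel(), results.items()):
        t = res.series.times_min_rel_onset
        ax.plot(t, res.series.sen, lw=0.6, color="0.4", label="SEN")
        ax.plot(res.smoothed.times_min_rel_onset, res.smoothed.value,
                lw=1.2, ls=":", color="C1", label="4-min mean")
        lo, hi = res.trend.fit_interval_min
        tt = np.linspace(lo, hi, 2)
        ax.plot(tt, res.trend.intercept + res.trend.slope_per_min * tt,
                lw=1.2, color="C0",
                label=f"fit: {res.trend.slope_per_min:+.4f}/min, |r|={res.trend.abs_r:.2f}")
        ax.set_ylabel(f"SEN ({name})")
        ax.set_ylim(0, 1.05)
        ax.legend(loc="lower left", fontsize=7)
    axes.ravel()[-1].set_xlabel("time relative to seizure onset (min)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
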