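"""End-to-end per-record and cohort orchestration.

Stage order is fixed: extract preictal segment -> 50 Hz notch -> band
decomposition -> windowed spectral entropy -> trend fit and moving average.
All stage parameters live in :class:`PipelineConfig`, whose defaults are
the standard analysis settings (bands 0.1-12 / 12-32 / 32-128 Hz, order-40
Hamming FIR, 4096-sample windows, fit interval [-32, -4) min, 4-minute
moving average, 50 Hz notch).  The pipeline is deterministic; re-running
with identical config and input produces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from . import __version__
from .bands import DEFAULT_BANDS, BandDefinition, FilterSpec, notch_50hz, split_bands
from .cohort import CohortTable, build_cohort, render_table
from .eeg_io import EEGRecord, SegmentSpec, extract_preictal
from .entropy import (
    DEFAULT_N_BINS,
    DEFAULT_WINDOW_SAMPLES,
    EntropySeries,
    entropy_series,
)
from .errors import EegsenError
from .trend import (
    DEFAULT_FIT_INTERVAL_MIN,
    MovingAverageSeries,
    TrendSummary,
    fit_trend,
    moving_average,
)

__all__ = ["PipelineConfig", "BandResult", "run_record", "run_cohort", "StageError"]

log = logging.getLogger(__name__)


class StageError(EegsenError):
    """A pipeline stage failed; names the stage and record."""

    def __init__(self, stage: str, record_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for record {record_id!r}: {cause}")
        self.stage = stage
        self.record_id = record_id
        self.__cause__ = cause


@dataclass
class PipelineConfig:
    """All tunable analysis parameters, with standard defaults."""

    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    filter: FilterSpec = field(default_factory=FilterSpec)
    window_samples: int = DEFAULT_WINDOW_SAMPLES
    n_bins: int = DEFAULT_N_BINS
    segment: SegmentSpec = field(default_factory=lambda: SegmentSpec(32.0, 0.0))
    fit_interval_min: tuple[float, float] = DEFAULT_FIT_INTERVAL_MIN
    moving_avg_min: float = 4.0
    notch_hz: float = 50.0
    notch_q: float = 30.0
    apply_notch: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "bands" in kwargs:
            kwargs["bands"] = tuple(
                BandDefinition(b["name"], b["f_lo_hz"], b["f_hi_hz"])
                for b in kwargs["bands"]
            )
        if "filter" in kwargs:
            kwargs["filter"] = FilterSpec(**kwargs["filter"])
        if "segment" in kwargs:
            kwargs["segment"] = SegmentSpec(**kwargs["segment"])
        if "fit_interval_min" in kwargs:
            kwargs["fit_interval_min"] = tuple(kwargs["fit_interval_min"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "bands": [
                {"name": b.name, "f_lo_hz": b.f_lo_hz, "f_hi_hz": b.f_hi_hz}
                for b in self.bands
            ],
            "filter": {"order": self.filter.order, "taper": self.filter.taper},
            "window_samples": self.window_samples,
            "n_bins": self.n_bins,
            "segment": {
                "start_min_before_onset": self.segment.start_min_before_onset,
                "end_min_before_onset": self.segment.end_min_before_onset,
            },
            "fit_interval_min": list(self.fit_interval_min),
            "moving_avg_min": self.moving_avg_min,
            "notch_hz": self.notch_hz,
            "notch_q": self.notch_q,
            "apply_notch": self.apply_notch,
            "seed": self.seed,
        }

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path


@dataclass
class BandResult:
    """All per-band outputs of one record's analysis."""

    series: EntropySeries
    trend: TrendSummary
    smoothed: MovingAverageSeries


def _write_sen_tsv(series: EntropySeries, path: Path) -> None:
    with path.open("w") as fh:
        fh.write("band\tt_min_rel_onset\tsen\n")
        for t, s in zip(series.times_min_rel_onset, series.sen):
            fh.write(f"{series.band}\t{t:.6f}\t{'' if np.isnan(s) else f'{s:.6f}'}\n")


def _append_trend_tsv(trend: TrendSummary, path: Path) -> None:
    new = not path.exists()
    with path.open("a") as fh:
        if new:
            fh.write("record_id\tband\tslope\tr\tabs_r\tn_points\n")
        fh.write(
            f"{trend.record_id}\t{trend.band}\t{trend.slope_per_min:.8g}\t"
            f"{trend.r:.6f}\t{trend.abs_r:.6f}\t{trend.n_points}\n"
        )


def run_record(
    config: PipelineConfig,
    record: EEGRecord,
    channel: int | str = 0,
    out_dir: str | Path | None = None,
) -> dict[str, BandResult]:
    """Analyze one record: per-band entropy series, trend and moving average.

    If ``out_dir`` is given, writes ``<record_id>.<band>.sen.tsv`` per band,
    a ``<record_id>.trends.tsv`` table and a JSON run manifest.
    """

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except EegsenError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(name, record.record_id, exc) from exc

    try:
        segment = extract_preictal(record, channel, config.segment)
    except (EegsenError, KeyError) as exc:
        raise StageError("eeg_io", record.record_id, exc) from exc

    sig = segment.samples
    if config.apply_notch:
        sig = stage(
            "notch", notch_50hz, sig, record.sampling_rate_hz,
            notch_hz=config.notch_hz, q=config.notch_q,
        )
    band_signals = stage(
        "band_decomposition", split_bands, sig, config.bands, config.filter,
        record.sampling_rate_hz,
    )

    results: dict[str, BandResult] = {}
    for band in config.bands:
        series = stage(
            "entropy_engine", entropy_series, band_signals[band.name], band,
            record.sampling_rate_hz, config.window_samples,
            segment.start_s_rel_onset, config.n_bins, record.record_id,
        )
        trend = stage("trend_analysis", fit_trend, series, config.fit_interval_min)
        smoothed = stage("trend_analysis", moving_average, series, config.moving_avg_min)
        results[band.name] = BandResult(series, trend, smoothed)
        log.info(
            "record %s band %s: %d windows, %d fit points, slope %.3g",
            record.record_id, band.name, len(series), trend.n_points,
            trend.slope_per_min,
        )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        trends_path = out_dir / f"{record.record_id}.trends.tsv"
        trends_path.unlink(missing_ok=True)
        for name, res in results.items():
            _write_sen_tsv(res.series, out_dir / f"{record.record_id}.{name}.sen.tsv")
            _append_trend_tsv(res.trend, trends_path)
        digest = hashlib.sha256(np.ascontiguousarray(record.samples).tobytes()).hexdigest()
        manifest = {
            "record_id": record.record_id,
            "eegsen_version": __version__,
            "config": config.to_dict(),
            "input_sha256": digest,
            "channel": channel,
            "windows_per_band": {k: len(v.series) for k, v in results.items()},
        }
        (out_dir / f"{record.record_id}.manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str) + "\n"
        )
    return results


def run_cohort(
    config: PipelineConfig,
    records: Sequence[tuple[EEGRecord, int | str]] | Iterable[tuple[EEGRecord, int | str]],
    out_path: str | Path | None = None,
) -> CohortTable:
    """Analyze several records and aggregate their trends into a cohort table."""
    records = list(records)
    if not records:
        raise EegsenError("cohort requires at least one record")
    rows = []
    for record, channel in records:
        results = run_record(config, record, channel)
        rows.append(
            (record.record_id, {name: res.trend for name, res in results.items()})
        )
    table = build_cohort(rows, bands=tuple(b.name for b in config.bands))
    if out_path is not None:
        render_table(table, out_path)
    return table
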