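"""Cohort aggregation of per-patient entropy trends.

Assembles per-patient (slope, |r|) triplets -- one per frequency band --
into a cohort table with unweighted column means and slope-sign counts,
mirroring the per-patient results tables of preictal entropy studies.

A packaged reference cohort ships with the library: the published
per-patient slopes and absolute correlations for the 20-patient invasive
focal-epilepsy cohort of the Freiburg seizure prediction dataset (records
themselves are not redistributable).  It exercises the cohort arithmetic
and serves as a realistic fixture.

Column means are computed in decimal arithmetic and displayed with
round-half-up, so a mean of 0.0054105 prints as 0.005411.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import IncompleteCohortError
from .trend import TrendSummary

__all__ = [
    "CohortTable",
    "BAND_ORDER",
    "build_cohort",
    "render_table",
    "parse_table",
    "load_reference_cohort",
]

BAND_ORDER: tuple[str, ...] = ("low", "mid", "high")


def _dec_mean(values: Sequence[float]) -> Decimal:
    """Exact-decimal mean of floats via their shortest decimal representation."""
    total = sum((Decimal(repr(v)) for v in values), Decimal(0))
    return total / Decimal(len(values))


def round_half_up(value: float | Decimal, quantum: str) -> Decimal:
    if not isinstance(value, Decimal):
        value = Decimal(repr(value))
    return value.quantize(Decimal(quantum), rounding=ROUND_HALF_UP)


@dataclass
class CohortTable:
    """Per-patient trend triplets plus cohort statistics."""

    rows: dict[str, dict[str, TrendSummary]]
    bands: tuple[str, ...] = BAND_ORDER

    @property
    def n_patients(self) -> int:
        return len(self.rows)

    @property
    def mean_slope(self) -> dict[str, float]:
        return {
            b: float(_dec_mean([r[b].slope_per_min for r in self.rows.values()]))
            for b in self.bands
        }

    @property
    def mean_abs_r(self) -> dict[str, float]:
        return {
            b: float(_dec_mean([r[b].abs_r for r in self.rows.values()]))
            for b in self.bands
        }

    @property
    def n_positive_slope(self) -> dict[str, int]:
        return {
            b: sum(r[b].slope_per_min > 0 for r in self.rows.values())
            for b in self.bands
        }

    @property
    def n_negative_slope(self) -> dict[str, int]:
        return {
            b: sum(r[b].slope_per_min < 0 for r in self.rows.values())
            for b in self.bands
        }


def build_cohort(
    rows: Iterable[tuple[str, Mapping[str, TrendSummary]]]
    | Mapping[str, Mapping[str, TrendSummary]],
    bands: tuple[str, ...] = BAND_ORDER,
) -> CohortTable:
    """Assemble per-patient trend summaries into a :class:`CohortTable`.

    Each patient must contribute exactly one :class:`TrendSummary` per band.
    """
    if isinstance(rows, Mapping):
        rows = rows.items()
    table: dict[str, dict[str, TrendSummary]] = {}
    for patient, summaries in rows:
        missing = [b for b in bands if b not in summaries]
        if missing:
            raise IncompleteCohortError(
                f"patient {patient!r} is missing band(s) {missing}"
            )
        table[str(patient)] = {b: summaries[b] for b in bands}
    return CohortTable(rows=table, bands=bands)


def _fmt_row(patient: str, slopes: Sequence[Decimal], rs: Sequence[Decimal]) -> list[str]:
    return [patient, *[f"{s:f}" for s in slopes], *[f"{r:f}" for r in rs]]


def render_table(table: CohortTable, path: str | Path) -> Path:
    """Write the cohort table as TSV: one patient per row, slope columns then
    |r| columns, and a final Average row.

    Slopes are printed to 6 decimals and |r| to 2, both round-half-up;
    averages are computed at full precision and rounded only for display.
    """
    path = Path(path)
    header = [
        "patient",
        *[f"slope_{b}" for b in table.bands],
        *[f"abs_r_{b}" for b in table.bands],
    ]
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(header)
        if table.n_patients == 0:
            warnings.warn("rendering an empty cohort table", stacklevel=2)
            return path
        for patient, summaries in table.rows.items():
            w.writerow(
                _fmt_row(
                    patient,
                    [round_half_up(summaries[b].slope_per_min, "0.000001") for b in table.bands],
                    [round_half_up(summaries[b].abs_r, "0.01") for b in table.bands],
                )
            )
        w.writerow(
            _fmt_row(
                "Average",
                [round_half_up(_dec_mean([r[b].slope_per_min for r in table.rows.values()]), "0.000001") for b in table.bands],
                [round_half_up(_dec_mean([r[b].abs_r for r in table.rows.values()]), "0.01") for b in table.bands],
            )
        )
    return path


def parse_table(path: str | Path, bands: tuple[str, ...] = BAND_ORDER) -> CohortTable:
    """Read back a TSV produced by :func:`render_table` (Average row ignored)."""
    rows: list[tuple[str, dict[str, TrendSummary]]] = []
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for rec in reader:
            patient = rec["patient"]
            if patient == "Average":
                continue
            summaries = {
                b: TrendSummary(
                    band=b,
                    slope_per_min=float(rec[f"slope_{b}"]),
                    intercept=float("nan"),
                    r=float(rec[f"abs_r_{b}"]),
                    stderr=float("nan"),
                    n_points=0,
                    record_id=patient,
                )
                for b in bands
            }
            rows.append((patient, summaries))
    return build_cohort(rows, bands=bands)


def load_reference_cohort() -> CohortTable:
    """The packaged 20-patient reference cohort (published per-patient slopes
    and |r| for the low/mid/high bands)."""
    ref = resources.files("eegsen.data").joinpath("reference_cohort.tsv")
    with resources.as_file(ref) as path:
        return parse_table(path)
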