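"""Baselines, tolerance ranges, and control charts for the QC parameters.

A baseline (BL) for each parameter is established from five consecutive
phantom acquisitions:

.. math::

    BL = \\mathrm{mean}(x_1, \\dots, x_5), \\qquad
    \\text{tolerance width} = 2 \\times SD(x_1, \\dots, x_5),

with the sample (n−1) standard deviation, and the tolerance range is
``BL ± width``.  Monthly measurements are appended to per-parameter
control charts and flagged ``within``/``above``/``below`` against the
range (closed interval: a value exactly on a bound is within).  A drift
report for one month partitions the monitored parameters into in- and
out-of-tolerance sets with the direction of each excursion.

Clinical CT practice instead uses BL ± 20 % for the noise parameter; that
rule is available as an explicit comparison mode but the 2×SD band is the
default everywhere, because it is tight enough to catch the subtle
instrumental drifts that corrupt small-animal densitometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ChartOrderError, ValidationError
from .qc_metrics import QC_PARAMETERS, QcMeasurement

__all__ = [
    "BaselineRecord",
    "ControlChart",
    "DriftReport",
    "compute_baseline",
    "clinical_noise_baseline",
    "evaluate_point",
    "update_chart",
    "drift_report",
    "chart_to_csv",
    "chart_from_csv",
    "charts_to_csv",
    "charts_from_csv",
    "baselines_to_json",
    "baselines_from_json",
    "plot_chart",
]


@dataclass(frozen=True)
class BaselineRecord:
    """Per-parameter baseline and tolerance range."""

    parameter: str
    baseline: float
    tolerance_width: float
    lower: float
    upper: float
    n_baseline: int = 5

    def __post_init__(self) -> None:
        if self.tolerance_width < 0:
            raise ValidationError("tolerance width must be >= 0")
        if self.n_baseline < 2:
            raise ValidationError("baseline needs at least 2 measurements")

    @classmethod
    def from_bl_width(
        cls, parameter: str, baseline: float, width: float, n_baseline: int = 5
    ) -> "BaselineRecord":
        """Build a record from an already-established BL ± width pair."""
        return cls(
            parameter=parameter,
            baseline=float(baseline),
            tolerance_width=float(width),
            lower=float(baseline) - float(width),
            upper=float(baseline) + float(width),
            n_baseline=n_baseline,
        )


def compute_baseline(
    measures: Sequence[float],
    parameter: str,
    protocol_mode: bool = True,
) -> BaselineRecord:
    """Baseline from repeated acquisitions: BL = mean, width = 2 × sample SD.

    ``protocol_mode`` enforces the five-scan protocol; disable it for
    exploratory baselines with another count (still ≥ 2).
    """
    values = np.asarray(measures, dtype=np.float64)
    if values.ndim != 1 or values.size < 2:
        raise ValidationError(
            f"{parameter}: baseline needs at least 2 values, got {values.size}"
        )
    if protocol_mode and values.size != 5:
        raise ValidationError(
            f"{parameter}: the baseline protocol uses 5 consecutive scans, "
            f"got {values.size} (pass protocol_mode=False to override)"
        )
    if not np.all(np.isfinite(values)):
        raise ValidationError(f"{parameter}: baseline values must be finite")
    bl = float(values.mean())
    width = 2.0 * float(values.std(ddof=1))
    return BaselineRecord.from_bl_width(parameter, bl, width, n_baseline=values.size)


def clinical_noise_baseline(
    measures: Sequence[float], parameter: str = "noise"
) -> BaselineRecord:
    """Comparison mode: the clinical BL ± 20 % rule for the noise parameter."""
    values = np.asarray(measures, dtype=np.float64)
    if values.size < 2 or not np.all(np.isfinite(values)):
        raise ValidationError("baseline needs >= 2 finite values")
    bl = float(values.mean())
    return BaselineRecord.from_bl_width(
        parameter, bl, 0.2 * abs(bl), n_baseline=values.size
    )


def evaluate_point(measurement: QcMeasurement, baseline: BaselineRecord) -> str:
    """Flag one measurement: ``within`` iff lower ≤ value ≤ upper (closed)."""
    if measurement.parameter != baseline.parameter:
        raise ValidationError(
            f"parameter mismatch: measurement {measurement.parameter!r} vs "
            f"baseline {baseline.parameter!r}"
        )
    if measurement.value > baseline.upper:
        return "above"
    if measurement.value < baseline.lower:
        return "below"
    return "within"


@dataclass(frozen=True)
class ControlChart:
    """Time-ordered measurements of one parameter against its baseline."""

    parameter: str
    baseline: BaselineRecord
    series: tuple[QcMeasurement, ...] = ()
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.baseline.parameter != self.parameter:
            raise ValidationError("chart and baseline parameter names differ")
        if len(self.series) != len(self.flags):
            raise ValidationError("flags length must equal series length")

    @property
    def dates(self) -> tuple[int, ...]:
        return tuple(m.date for m in self.series)

    def at(self, date: int) -> tuple[QcMeasurement, str]:
        for m, f in zip(self.series, self.flags):
            if m.date == date:
                return m, f
        raise KeyError(f"{self.parameter}: no measurement at date {date}")


def update_chart(chart: ControlChart, measurement: QcMeasurement) -> ControlChart:
    """Append one measurement, flagging it against the chart's baseline.

    Dates are ordinal month labels and must strictly increase.
    """
    if measurement.parameter != chart.parameter:
        raise ValidationError(
            f"measurement for {measurement.parameter!r} cannot extend a "
            f"{chart.parameter!r} chart"
        )
    if chart.series:
        last = chart.series[-1].date
        if measurement.date == last:
            raise ChartOrderError(
                f"{chart.parameter}: duplicate date {measurement.date}"
            )
        if measurement.date < last:
            raise ChartOrderError(
                f"{chart.parameter}: date {measurement.date} precedes "
                f"last charted date {last}"
            )
    flag = evaluate_point(measurement, chart.baseline)
    return replace(
        chart,
        series=chart.series + (measurement,),
        flags=chart.flags + (flag,),
    )


@dataclass(frozen=True)
class DriftReport:
    """Partition of the monitored parameters at one date."""

    date: int
    out_of_tolerance: tuple[tuple[str, float, float, str], ...]
    within: tuple[str, ...]

    @property
    def out_parameters(self) -> tuple[str, ...]:
        return tuple(entry[0] for entry in self.out_of_tolerance)


def drift_report(
    charts: Mapping[str, ControlChart] | Sequence[ControlChart], date: int
) -> DriftReport:
    """Partition all charted parameters at ``date`` into within/out sets.

    Each out-of-tolerance entry carries ``(parameter, value, bound
    exceeded, direction)``.
    """
    if isinstance(charts, Mapping):
        chart_list = list(charts.values())
    else:
        chart_list = list(charts)
    out = []
    within = []
    for chart in chart_list:
        try:
            measurement, flag = chart.at(date)
        except KeyError as exc:
            raise ValidationError(str(exc)) from exc
        if flag == "within":
            within.append(chart.parameter)
        else:
            bound = chart.baseline.upper if flag == "above" else chart.baseline.lower
            out.append((chart.parameter, measurement.value, bound, flag))
    return DriftReport(
        date=date, out_of_tolerance=tuple(out), within=tuple(within)
    )


# -- persistence ----------------------------------------------------------


def chart_to_csv(chart: ControlChart) -> pd.DataFrame:
    """One row per charted month: date, value, flag."""
    return pd.DataFrame(
        {
            "parameter": [chart.parameter] * len(chart.series),
            "date": [m.date for m in chart.series],
            "value": [m.value for m in chart.series],
            "source": [m.source for m in chart.series],
            "flag": list(chart.flags),
        }
    )


def charts_to_csv(
    charts: Mapping[str, ControlChart], path: str | Path
) -> Path:
    frames = [chart_to_csv(c) for c in charts.values()]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return Path(path)


def chart_from_csv(
    frame: pd.DataFrame, baseline: BaselineRecord
) -> ControlChart:
    chart = ControlChart(parameter=baseline.parameter, baseline=baseline)
    for row in frame.sort_values("date").itertuples():
        source = "" if pd.isna(row.source) else str(row.source)
        chart = update_chart(
            chart,
            QcMeasurement(
                parameter=baseline.parameter,
                value=float(row.value),
                date=int(row.date),
                source=source,
            ),
        )
    return chart


def charts_from_csv(
    path: str | Path, baselines: Mapping[str, BaselineRecord]
) -> dict[str, ControlChart]:
    frame = pd.read_csv(path, float_precision="round_trip")
    charts = {}
    for parameter, group in frame.groupby("parameter"):
        if parameter not in baselines:
            raise ValidationError(f"no baseline record for {parameter!r}")
        charts[str(parameter)] = chart_from_csv(group, baselines[str(parameter)])
    return charts


def baselines_to_json(
    baselines: Mapping[str, BaselineRecord], path: str | Path | None = None
) -> str:
    payload = {
        name: {
            "parameter": b.parameter,
            "baseline": b.baseline,
            "tolerance_width": b.tolerance_width,
            "lower": b.lower,
            "upper": b.upper,
            "n_baseline": b.n_baseline,
        }
        for name, b in baselines.items()
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def baselines_from_json(source: str | Path) -> dict[str, BaselineRecord]:
    if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
        source = Path(source).read_text()
    payload = json.loads(source)
    return {
        name: BaselineRecord(
            parameter=b["parameter"],
            baseline=b["baseline"],
            tolerance_width=b["tolerance_width"],
            lower=b["lower"],
            upper=b["upper"],
            n_baseline=b["n_baseline"],
        )
        for name, b in payload.items()
    }


def plot_chart(chart: ControlChart, path: str | Path | None = None):
    """Render a control chart: points, BL line, dotted tolerance limits."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3))
    dates = list(chart.dates)
    values = [m.value for m in chart.series]
    colors = ["tab:red" if f != "within" else "tab:blue" for f in chart.flags]
    ax.scatter(dates, values, c=colors, marker="s", zorder=3)
    ax.axhline(chart.baseline.baseline, color="green", lw=1.2, label="BL")
    ax.axhline(chart.baseline.upper, color="green", lw=1.0, ls=":")
    ax.axhline(chart.baseline.lower, color="green", lw=1.0, ls=":")
    ax.set_xlabel("month")
    ax.set_ylabel(chart.parameter)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return Path(path)
    return fig
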