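import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microct_qc.control_charts import (
    BaselineRecord,
    ControlChart,
    baselines_from_json,
    baselines_to_json,
    charts_from_csv,
    charts_to_csv,
    chart_to_csv,
    clinical_noise_baseline,
    compute_baseline,
    drift_report,
    evaluate_point,
    update_chart,
)
from microct_qc.errors import ChartOrderError, ValidationError
from microct_qc.qc_metrics import QcMeasurement

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def measurement(parameter="noise", value=124.0, date=1):
    return QcMeasurement(parameter=parameter, value=value, date=date)


class TestBaseline:
    def test_identical_values_give_zero_width(self):
        record = compute_baseline([124] * 5, "noise")
        assert record.baseline == 124.0
        assert record.tolerance_width == 0.0
        assert (record.lower, record.upper) == (124.0, 124.0)

    def test_range_is_bl_plus_minus_two_sd(self):
        values = [122.0, 123.0, 124.0, 125.0, 126.0]
        record = compute_baseline(values, "noise")
        sd = np.std(values, ddof=1)
        assert record.tolerance_width == pytest.approx(2 * sd)
        assert record.upper - record.lower == pytest.approx(2 * record.tolerance_width)

    def test_protocol_mode_requires_five_scans(self):
        with pytest.raises(ValidationError, match="5 consecutive"):
            compute_baseline([1.0, 2.0, 3.0], "noise")
        record = compute_baseline([1.0, 2.0, 3.0], "noise", protocol_mode=False)
        assert record.n_baseline == 3

    @pytest.mark.parametrize("bad", [[124.0], [1.0, np.nan, 2.0, 3.0, 4.0]])
    def test_invalid_measure_sets_rejected(self, bad):
        with pytest.raises(ValidationError):
            compute_baseline(bad, "noise", protocol_mode=False)

    def test_clinical_rule_is_twenty_percent_band(self):
        record = clinical_noise_baseline([124.0] * 5)
        assert record.tolerance_width == pytest.approx(0.2 * 124.0)

    def test_recovery_of_population_parameters(self, rng):
        """BL converges to µ and the width to 2·c4(5)·σ (the sample SD of
        five draws is biased by the c4 factor) over many repeats."""
        mu, sigma, reps = 124.0, 4.0, 1000
        records = [
            compute_baseline(rng.normal(mu, sigma, size=5), "noise")
            for _ in range(reps)
        ]
        c4 = math.sqrt(2 / 4) * math.gamma(2.5) / math.gamma(2.0)
        bl_mean = np.mean([r.baseline for r in records])
        width_mean = np.mean([r.tolerance_width for r in records])
        assert abs(bl_mean - mu) < 3 * sigma / math.sqrt(5 * reps)
        width_se = 2 * sigma * math.sqrt(1 - c4**2) / math.sqrt(reps)
        assert abs(width_mean - 2 * c4 * sigma) < 3 * width_se


class TestEvaluatePoint:
    baseline = BaselineRecord.from_bl_width("noise", 124.0, 2.0)

    @pytest.mark.parametrize(
        "value, expected",
        [(135.0, "above"), (121.9, "below"), (124.0, "within"),
         (126.0, "within"), (122.0, "within")],
    )
    def test_closed_interval_flagging(self, value, expected):
        assert evaluate_point(measurement(value=value), self.baseline) == expected

    def test_uniformity_excursion_below_range(self):
        baseline = BaselineRecord.from_bl_width("uniformity", -41.0, 22.0)
        flag = evaluate_point(
            measurement("uniformity", value=-106.0), baseline
        )
        assert flag == "below"

    def test_parameter_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="mismatch"):
            evaluate_point(measurement("water", 2000.0), self.baseline)

    @given(st.floats(-50, 50), st.floats(-50, 50))
    def test_flagging_is_monotone(self, v1, v2):
        baseline = BaselineRecord.from_bl_width("noise", 0.0, 10.0)
        lo, hi = sorted([v1, v2])
        if evaluate_point(measurement(value=lo), baseline) == "above":
            assert evaluate_point(measurement(value=hi), baseline) == "above"
        if evaluate_point(measurement(value=hi), baseline) == "below":
            assert evaluate_point(measurement(value=lo), baseline) == "below"


class TestChart:
    baseline = BaselineRecord.from_bl_width("noise", 124.0, 2.0)

    def chart_with(self, values):
        chart = ControlChart(parameter="noise", baseline=self.baseline)
        for month, value in enumerate(values, start=1):
            chart = update_chart(chart, measurement(value=value, date=month))
        return chart

    def test_twelve_within_then_one_above(self, rng):
        values = list(rng.uniform(123.0, 125.0, size=12)) + [135.0]
        chart = self.chart_with(values)
        assert chart.flags == ("within",) * 12 + ("above",)

    def test_first_point_starts_series(self):
        chart = self.chart_with([124.0])
        assert len(chart.series) == 1

    def test_duplicate_date_rejected(self):
        chart = self.chart_with([124.0])
        with pytest.raises(ChartOrderError, match="duplicate"):
            update_chart(chart, measurement(value=125.0, date=1))

    def test_out_of_order_date_rejected(self):
        chart = self.chart_with([124.0, 124.5])
        with pytest.raises(ChartOrderError, match="precedes"):
            update_chart(chart, measurement(value=125.0, date=1))

    def test_update_leaves_original_chart_unchanged(self):
        chart = self.chart_with([124.0])
        update_chart(chart, measurement(value=125.0, date=2))
        assert len(chart.series) == 1


class TestDriftReport:
    def build_charts(self, values_by_parameter):
        charts = {}
        for name, (bl, width, value) in values_by_parameter.items():
            baseline = BaselineRecord.from_bl_width(name, bl, width)
            chart = ControlChart(parameter=name, baseline=baseline)
            chart = update_chart(chart, measurement(name, value, date=1))
            charts[name] = chart
        return charts

    def test_partition_and_directions(self):
        charts = self.build_charts(
            {
                "water": (2000, 17, 2174.0),
                "noise": (124, 2, 135.0),
                "uniformity": (-41, 22, -106.0),
                "mtf_5": (42, 17, 40.0),
            }
        )
        report = drift_report(charts, date=1)
        assert set(report.out_parameters) == {"water", "noise", "uniformity"}
        assert report.within == ("mtf_5",)
        directions = {p: d for p, _, _, d in report.out_of_tolerance}
        assert directions == {"water": "above", "noise": "above",
                              "uniformity": "below"}
        assert set(report.out_parameters) | set(report.within) == set(charts)

    def test_all_within_gives_empty_out_list(self):
        charts = self.build_charts({"water": (2000, 17, 2001.0)})
        assert drift_report(charts, 1).out_of_tolerance == ()

    def test_missing_date_rejected(self):
        charts = self.build_charts({"water": (2000, 17, 2001.0)})
        with pytest.raises(ValidationError, match="no measurement"):
            drift_report(charts, 2)


class TestPersistence:
    def test_chart_csv_round_trip_is_exact(self, tmp_path, rng):
        baseline = BaselineRecord.from_bl_width("water", 2000.0, 17.0)
        chart = ControlChart(parameter="water", baseline=baseline)
        for month in range(1, 14):
            chart = update_chart(
                chart,
                measurement("water", float(rng.normal(2000, 5)), month),
            )
        path = tmp_path / "charts.csv"
        charts_to_csv({"water": chart}, path)
        restored = charts_from_csv(path, {"water": baseline})["water"]
        assert [m.value for m in restored.series] == [
            m.value for m in chart.series
        ]
        assert restored.flags == chart.flags

    def test_baseline_json_round_trip_is_exact(self, tmp_path):
        records = {
            "noise": compute_baseline([122.2, 123.7, 124.1, 124.9, 126.3],
                                      "noise"),
            "water": BaselineRecord.from_bl_width("water", 2000.0, 17.0),
        }
        path = tmp_path / "bl.json"
        baselines_to_json(records, path)
        assert baselines_from_json(path) == records
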