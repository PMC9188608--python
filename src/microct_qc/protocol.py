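"""The monthly QC protocol, end to end, on synthetic phantom scans.

This module wires the generator, the ROI maps, the QC statistics, and the
control charts into the routine a physicist would run each month:

1. scan the water, bar-pattern, and low-contrast phantoms;
2. extract the ten monitored parameters (water, air, noise, uniformity,
   three contrast levels, three MTF frequencies);
3. append each value to its control chart and flag it against the
   tolerance range.

It also provides a complete *drift rehearsal*: a multi-month simulated
campaign in which the scanner behaves itself for N−1 months and then
drifts — grey levels float upward, noise rises, and the radial
non-uniformity deepens — reproducing the signature failure mode in which
water, air, noise, and uniformity leave their tolerance ranges while
low-contrast detectability and spatial resolution stay within bounds.

Baselines for the rehearsal are anchored on a noiseless reference
acquisition of the same synthetic scanner (the noise baseline is the
scanner's configured noise level), and the tolerance widths are the
packaged reference-chart presets established for the scanner the
protocol was developed on.  Five-scan measured baselines
(:func:`microct_qc.control_charts.compute_baseline`) remain the right
tool when commissioning a real scanner; for a simulated campaign the
preset widths define the study conditions directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .control_charts import (
    BaselineRecord,
    ControlChart,
    DriftReport,
    drift_report,
    update_chart,
)
from .phantom_rois import (
    air_roi_map,
    extract_roi_stats,
    low_contrast_roi_map,
    uniformity_roi_map,
    water_roi_map,
)
from .qc_metrics import (
    QC_PARAMETERS,
    QcMeasurement,
    air_value,
    contrast_insert,
    contrast_level,
    extract_line_profile,
    mtf,
    noise,
    profile_bar_means,
    uniformity,
    water_value,
)
from .synthetic_phantoms import (
    BAR_AIR_ROI_XY,
    DriftSpec,
    GroundTruth,
    PhantomSpec,
    gen_phantom,
    inject_drift,
)
from .volumes_io import Volume

__all__ = [
    "ScannerScenario",
    "RehearsalResult",
    "PRESET_TOLERANCE_WIDTHS",
    "WATER_GRADIENT_BASELINE",
    "WATER_GRADIENT_DRIFTED",
    "DRIFT_GREY_SHIFT",
    "DRIFT_NOISE_SCALE",
    "measure_water_phantom",
    "measure_bar_phantom",
    "measure_low_contrast_phantom",
    "reference_baselines",
    "run_drift_rehearsal",
]

#: Reference-chart tolerance widths (config presets) for the scanner the
#: protocol was established on; grey levels for water/air/noise/uniformity,
#: percentage points for contrast and MTF.
PRESET_TOLERANCE_WIDTHS: dict[str, float] = {
    "water": 17.0,
    "air": 33.0,
    "noise": 2.0,
    "uniformity": 22.0,
    "contrast_-9": 3.0,
    "contrast_-6": 1.0,
    "contrast_-3": 1.0,
    "mtf_3.3": 19.0,
    "mtf_5": 17.0,
    "mtf_10": 14.0,
}

#: Radial non-uniformity (grey levels per mm) of the healthy synthetic
#: scanner: with the standard uniformity ROI layout it reads −41 grey
#: levels, the reference chart's anchor.
WATER_GRADIENT_BASELINE = 6.25
#: Deepened non-uniformity of the drifted scanner, reading about −106.
WATER_GRADIENT_DRIFTED = 16.15
#: Grey-level shift of the drifted scanner: pushes water from 2000 to
#: about 2174 and air from 449 to well above its upper limit.
DRIFT_GREY_SHIFT = 174.0
#: Extra-noise scale of the drifted scanner; the superimposed independent
#: noise takes the measured noise from 124 to about 135 grey levels.
DRIFT_NOISE_SCALE = 1.44


@dataclass(frozen=True)
class ScannerScenario:
    """Study conditions of a simulated QC campaign.

    The grey anchors (water 2000, air 449), the noise level (124), and
    the baseline non-uniformity are those of the reference scanner's
    charts.  The phantom-specific voxel spacings are the simulation's
    problem sizes: coarse enough to keep a full campaign fast, fine
    enough that every ROI holds thousands of voxels (and the bar phantom
    keeps ≥ 1 voxel per 50 µm line).
    """

    grey_water: float = 2000.0
    grey_air: float = 449.0
    grey_background: float = 1800.0
    noise_sd: float = 124.0
    water_gradient: float = WATER_GRADIENT_BASELINE
    blur_sigma: float = 0.04
    spacing_water: float = 0.1
    spacing_bar: float = 0.05
    spacing_low_contrast: float = 0.1

    def phantom_spec(self, kind: str, seed: int, gradient: float | None = None,
                     noise_sd: float | None = None) -> PhantomSpec:
        spacing = {
            "water": self.spacing_water,
            "bar_pattern": self.spacing_bar,
            "low_contrast": self.spacing_low_contrast,
        }[kind]
        return PhantomSpec(
            kind=kind,
            grey_water=self.grey_water,
            grey_air=self.grey_air,
            grey_background=self.grey_background,
            noise_sd=self.noise_sd if noise_sd is None else noise_sd,
            gradient=(
                (self.water_gradient if gradient is None else gradient)
                if kind == "water"
                else 0.0
            ),
            blur_sigma=self.blur_sigma,
            spacing=spacing,
            seed=seed,
        )


# -- per-phantom measurement ----------------------------------------------


def measure_water_phantom(volume: Volume, center_slice: int | None = None,
                          phantom_diameter: float = 32.0) -> dict[str, float]:
    """Water grey level, noise, and uniformity from one water-phantom scan."""
    water_map = water_roi_map(volume, center_slice, phantom_diameter)
    stats = extract_roi_stats(volume, water_map["water"])
    uni_map = uniformity_roi_map(volume, center_slice, phantom_diameter)
    central = extract_roi_stats(volume, uni_map["a"])
    peripheral = [extract_roi_stats(volume, uni_map[n]) for n in "bcde"]
    return {
        "water": water_value(stats),
        "noise": noise(stats),
        "uniformity": uniformity(central, peripheral),
    }


def measure_bar_phantom(
    volume: Volume,
    truth: GroundTruth,
    center_slice: int | None = None,
    phantom_diameter: float = 20.0,
    n_repeats: int = 3,
) -> dict[str, float]:
    """Air grey level and the three MTF values from one bar-phantom scan.

    For each bar pattern, ``n_repeats`` parallel line profiles are taken
    at one-voxel offsets along the bars and the plateau/valley means
    averaged, standing in for repeated manual line-profile measurements.
    """
    air_map = air_roi_map(volume, center_slice, phantom_diameter,
                          center_xy=BAR_AIR_ROI_XY)
    stats = extract_roi_stats(volume, air_map["air"])
    values = {"air": air_value(stats)}
    z = volume.n_slices // 2
    voxel = volume.spacing[2]
    offsets = [(k - (n_repeats - 1) / 2.0) * voxel for k in range(n_repeats)]
    for segment in truth.bar_segments:
        ux, uy = segment.offset_direction
        profiles = []
        for off in offsets:
            start = (segment.start_xy[0] + off * ux, segment.start_xy[1] + off * uy)
            end = (segment.end_xy[0] + off * ux, segment.end_xy[1] + off * uy)
            profiles.append(extract_line_profile(volume, start, end, z))
        bg_mean, bars_mean = profile_bar_means(profiles)
        label = f"{segment.frequency:g}"
        values[f"mtf_{label}"] = mtf(bg_mean, bars_mean)
    return values


def measure_low_contrast_phantom(
    volume: Volume,
    truth: GroundTruth,
    start_slice: int = 2,
) -> dict[str, float]:
    """The three contrast-level values from one low-contrast scan."""
    roi_map = low_contrast_roi_map(volume, layout=truth.layout,
                                   start_slice=start_slice)
    means = {
        roi.name: float(np.mean(extract_roi_stats(volume, roi).per_slice_mean))
        for roi in roi_map
    }
    bg = means["background"]
    air = means["air"]
    values: dict[str, float] = {}
    by_level: dict[float, list[float]] = {}
    for site in truth.layout.inserts:
        by_level.setdefault(site.nominal_contrast_pct, []).append(
            contrast_insert(means[site.name], bg, air)
        )
    for nominal, inserts in by_level.items():
        level = contrast_level(inserts, nominal)
        values[f"contrast_{nominal:+.0f}".replace("+", "")] = level.level_value
    return values


# -- baselines and the rehearsal ------------------------------------------


def reference_baselines(
    scenario: ScannerScenario | None = None,
    widths: Mapping[str, float] | None = None,
) -> dict[str, BaselineRecord]:
    """Baseline records of the synthetic scanner in its healthy state.

    BL values are measured on a noiseless reference acquisition (the
    noise BL is the scanner's configured noise level, since a noiseless
    scan has none); tolerance widths come from the packaged chart presets
    unless overridden.
    """
    scenario = scenario or ScannerScenario()
    widths = dict(widths or PRESET_TOLERANCE_WIDTHS)
    values: dict[str, float] = {}
    water_vol, _ = gen_phantom(
        scenario.phantom_spec("water", seed=0, noise_sd=0.0)
    )
    values.update(measure_water_phantom(water_vol))
    values["noise"] = scenario.noise_sd
    bar_vol, bar_truth = gen_phantom(
        scenario.phantom_spec("bar_pattern", seed=0, noise_sd=0.0)
    )
    values.update(measure_bar_phantom(bar_vol, bar_truth))
    lc_vol, lc_truth = gen_phantom(
        scenario.phantom_spec("low_contrast", seed=0, noise_sd=0.0)
    )
    values.update(measure_low_contrast_phantom(lc_vol, lc_truth))
    return {
        name: BaselineRecord.from_bl_width(name, values[name], widths[name])
        for name in QC_PARAMETERS
    }


@dataclass
class RehearsalResult:
    """Outcome of a simulated multi-month QC campaign."""

    baselines: dict[str, BaselineRecord]
    charts: dict[str, ControlChart]
    report: DriftReport
    monthly_values: dict[int, dict[str, float]]


def _measure_month(
    scenario: ScannerScenario,
    seed: int,
    gradient: float,
    drift: DriftSpec | None,
) -> dict[str, float]:
    values: dict[str, float] = {}
    water_vol, _ = gen_phantom(
        scenario.phantom_spec("water", seed=seed, gradient=gradient)
    )
    bar_vol, bar_truth = gen_phantom(
        scenario.phantom_spec("bar_pattern", seed=seed + 1)
    )
    lc_vol, lc_truth = gen_phantom(
        scenario.phantom_spec("low_contrast", seed=seed + 2)
    )
    if drift is not None:
        water_vol = inject_drift(water_vol, drift, seed + 3,
                                 original_noise=scenario.noise_sd)
        bar_vol = inject_drift(bar_vol, drift, seed + 4,
                               original_noise=scenario.noise_sd)
        lc_vol = inject_drift(lc_vol, drift, seed + 5,
                              original_noise=scenario.noise_sd)
    values.update(measure_water_phantom(water_vol))
    values.update(measure_bar_phantom(bar_vol, bar_truth))
    values.update(measure_low_contrast_phantom(lc_vol, lc_truth))
    return values


def run_drift_rehearsal(
    seed: int = 0,
    n_months: int = 13,
    drift_month: int | None = None,
    scenario: ScannerScenario | None = None,
    drift: DriftSpec | None = None,
    drifted_gradient: float = WATER_GRADIENT_DRIFTED,
) -> RehearsalResult:
    """Simulate a QC campaign with a scanner drift in the final month.

    Months ``1 .. drift_month−1`` scan the healthy scanner; in
    ``drift_month`` (default: the last month) the campaign injects the
    drifted condition: grey shift ``+174``, extra noise (measured noise
    ≈ 135), and a deepened radial non-uniformity (uniformity ≈ −106).
    Every monthly value is charted and the final month's drift report is
    returned.
    """
    scenario = scenario or ScannerScenario()
    if drift is None:
        drift = DriftSpec(grey_shift=DRIFT_GREY_SHIFT,
                          noise_scale=DRIFT_NOISE_SCALE)
    if drift_month is None:
        drift_month = n_months
    if not 1 <= drift_month <= n_months:
        raise ValueError(f"drift_month {drift_month} outside 1..{n_months}")
    baselines = reference_baselines(scenario)
    charts = {
        name: ControlChart(parameter=name, baseline=record)
        for name, record in baselines.items()
    }
    monthly_values: dict[int, dict[str, float]] = {}
    for month in range(1, n_months + 1):
        month_seed = (seed * 1009 + month * 17) % (2**31 - 1)
        drifted = month == drift_month
        values = _measure_month(
            scenario,
            month_seed,
            gradient=(drifted_gradient if drifted else scenario.water_gradient),
            drift=drift if drifted else None,
        )
        monthly_values[month] = values
        for name, value in values.items():
            charts[name] = update_chart(
                charts[name],
                QcMeasurement(parameter=name, value=value, date=month,
                              source=f"month-{month}"),
            )
    report = drift_report(charts, drift_month)
    return RehearsalResult(
        baselines=baselines,
        charts=charts,
        report=report,
        monthly_values=monthly_values,
    )
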