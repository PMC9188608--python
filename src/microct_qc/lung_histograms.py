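"""Lung density histograms and the drift-impact group comparison.

Healthy, well-aerated mouse lungs are segmented from micro-CT scans by a
fixed grey-level window: every voxel whose value lies in
``[lower, upper]``, restricted to the largest connected component so that
background air and isolated speckle are excluded.  This is a documented
stand-in for the full semi-automatic protocol used on real scans; its key
property — fixed thresholds on the scanner grey scale — is exactly what
makes densitometry vulnerable to scanner drift: a global upward grey
shift pushes aerated parenchyma out of the window and the segmented
volume shrinks.

From the masked voxels a density histogram is built and summarized by

* **AUC** — the histogram integral, operationalized as masked voxel
  count × voxel volume (mm³); it equals the total segmented lung volume
  and is independent of the binning;
* **skewness** — third standardized moment of the raw masked values;
* **kurtosis** — fourth standardized moment, Pearson convention
  (a Gaussian scores 3).

Groups of scans acquired before and after a drift are compared per the
protocol's statistical plan: Shapiro–Wilk normality per group, a
one-tailed unpaired t-test for AUC (drift is expected to *shrink* the
segmented volume), a two-tailed unpaired t-test for kurtosis, and a
Mann–Whitney test for skewness, all at alpha 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage, stats

from .errors import SegmentationError, ValidationError
from .volumes_io import Volume

__all__ = [
    "LungMask",
    "DensityHistogram",
    "HistogramSummary",
    "MetricComparison",
    "GroupComparison",
    "segment_lung",
    "density_histogram",
    "compare_groups",
    "DEFAULT_BIN_WIDTH",
]

#: Default histogram bin width, grey levels.
DEFAULT_BIN_WIDTH = 25.0


@dataclass(frozen=True)
class LungMask:
    """Binary lung segmentation aligned to a volume."""

    mask: np.ndarray
    lower: float
    upper: float
    voxel_count: int
    volume_mm3: float

    @classmethod
    def from_mask(cls, mask: np.ndarray, volume: Volume,
                  lower: float, upper: float) -> "LungMask":
        if mask.shape != volume.shape:
            raise ValidationError("mask shape must equal volume shape")
        count = int(mask.sum())
        return cls(
            mask=mask,
            lower=float(lower),
            upper=float(upper),
            voxel_count=count,
            volume_mm3=count * volume.voxel_volume_mm3,
        )


@dataclass(frozen=True)
class HistogramSummary:
    """The three scalar summaries of one lung histogram."""

    auc: float
    skewness: float
    kurtosis: float


@dataclass(frozen=True)
class DensityHistogram:
    """Binned grey-level distribution of the segmented lung voxels."""

    bin_edges: tuple[float, ...]
    counts: tuple[int, ...]
    auc: float
    skewness: float
    kurtosis: float

    @property
    def bin_centers(self) -> np.ndarray:
        edges = np.asarray(self.bin_edges)
        return (edges[:-1] + edges[1:]) / 2.0

    @property
    def summary(self) -> HistogramSummary:
        return HistogramSummary(
            auc=self.auc, skewness=self.skewness, kurtosis=self.kurtosis
        )


def segment_lung(volume: Volume, lower: float, upper: float) -> LungMask:
    """Fixed-window threshold segmentation, largest connected component.

    Keeps voxels with ``lower <= value <= upper`` and retains only the
    largest 26-connected component, mimicking a lung field extraction and
    discarding background air or speckle that falls inside the window.
    """
    if lower >= upper:
        raise ValidationError(
            f"lower threshold ({lower}) must be below upper ({upper})"
        )
    window = (volume.voxels >= lower) & (volume.voxels <= upper)
    if not window.any():
        raise SegmentationError(
            f"no voxels inside the grey window [{lower}, {upper}]"
        )
    structure = np.ones((3, 3, 3), dtype=bool)
    labeled, n_components = ndimage.label(window, structure=structure)
    if n_components == 0:
        raise SegmentationError(
            f"segmentation produced no components in [{lower}, {upper}]"
        )
    sizes = np.bincount(labeled.ravel())
    sizes[0] = 0
    mask = labeled == int(sizes.argmax())
    return LungMask.from_mask(mask, volume, lower, upper)


def density_histogram(
    volume: Volume,
    mask: LungMask | np.ndarray,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> DensityHistogram:
    """Histogram plus AUC / skewness / kurtosis of the masked voxels.

    Bins of fixed ``bin_width`` cover the observed grey-level range of the
    masked voxels.  The moments are computed on the raw voxel values, not
    the binned counts, and kurtosis uses the Pearson (non-excess)
    convention.  The AUC is the total segmented volume in mm³ and does
    not depend on the binning.
    """
    if bin_width <= 0:
        raise ValidationError("bin_width must be > 0")
    mask_array = mask.mask if isinstance(mask, LungMask) else np.asarray(mask)
    values = volume.voxels[mask_array].astype(np.float64)
    if values.size == 0:
        raise ValidationError("mask selects no voxels")
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = np.ceil(values.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2.0, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    auc = values.size * volume.voxel_volume_mm3
    return DensityHistogram(
        bin_edges=tuple(float(e) for e in edges),
        counts=tuple(int(c) for c in counts),
        auc=float(auc),
        skewness=float(stats.skew(values, bias=False)),
        kurtosis=float(stats.kurtosis(values, fisher=False, bias=False)),
    )


# -- group comparison -----------------------------------------------------


@dataclass(frozen=True)
class MetricComparison:
    """Before/after comparison of one histogram summary metric."""

    metric: str
    mean_before: float
    sd_before: float
    mean_after: float
    sd_after: float
    test: str
    p_value: float
    significant: bool
    normality_p_before: float
    normality_p_after: float


@dataclass(frozen=True)
class GroupComparison:
    """Statistical comparison of the three summaries across two groups."""

    metrics: tuple[MetricComparison, ...]
    alpha: float = 0.05

    def __getitem__(self, metric: str) -> MetricComparison:
        for m in self.metrics:
            if m.metric == metric:
                return m
        raise KeyError(metric)


def _as_summaries(
    group: Sequence[HistogramSummary | DensityHistogram | Mapping[str, float]],
) -> list[HistogramSummary]:
    out = []
    for item in group:
        if isinstance(item, DensityHistogram):
            out.append(item.summary)
        elif isinstance(item, HistogramSummary):
            out.append(item)
        else:
            out.append(
                HistogramSummary(
                    auc=float(item["auc"]),
                    skewness=float(item["skewness"]),
                    kurtosis=float(item["kurtosis"]),
                )
            )
    return out


def compare_groups(
    before: Sequence[HistogramSummary | DensityHistogram | Mapping[str, float]],
    after: Sequence[HistogramSummary | DensityHistogram | Mapping[str, float]],
    alpha: float = 0.05,
    auc_alternative: str = "greater",
) -> GroupComparison:
    """Compare per-subject histogram summaries before vs after a drift.

    * AUC: one-tailed unpaired t-test; ``auc_alternative="greater"``
      tests whether the *before* group is larger (the drift narrative:
      a positive grey shift shrinks the segmented volume).
    * Kurtosis: two-tailed unpaired t-test.
    * Skewness: two-tailed Mann–Whitney test.

    Shapiro–Wilk normality is reported per group per metric.  Each group
    needs at least 3 subjects.
    """
    before_s = _as_summaries(before)
    after_s = _as_summaries(after)
    if len(before_s) < 3 or len(after_s) < 3:
        raise ValidationError(
            f"each group needs >= 3 subjects, got {len(before_s)} and {len(after_s)}"
        )
    if auc_alternative not in ("greater", "less", "two-sided"):
        raise ValidationError(f"invalid auc_alternative {auc_alternative!r}")

    results = []
    for metric in ("auc", "kurtosis", "skewness"):
        a = np.array([getattr(s, metric) for s in before_s], dtype=np.float64)
        b = np.array([getattr(s, metric) for s in after_s], dtype=np.float64)
        norm_a = float(stats.shapiro(a).pvalue) if np.ptp(a) > 0 else 1.0
        norm_b = float(stats.shapiro(b).pvalue) if np.ptp(b) > 0 else 1.0
        if metric == "auc":
            test_name = "one-tailed unpaired t"
            result = stats.ttest_ind(a, b, alternative=auc_alternative)
            p = float(result.pvalue)
        elif metric == "kurtosis":
            test_name = "unpaired t"
            p = float(stats.ttest_ind(a, b).pvalue)
        else:
            test_name = "Mann–Whitney"
            if np.ptp(np.concatenate([a, b])) == 0:
                p = 1.0
            else:
                p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        results.append(
            MetricComparison(
                metric=metric,
                mean_before=float(a.mean()),
                sd_before=float(a.std(ddof=1)),
                mean_after=float(b.mean()),
                sd_after=float(b.std(ddof=1)),
                test=test_name,
                p_value=p,
                significant=bool(p < alpha),
                normality_p_before=norm_a,
                normality_p_after=norm_b,
            )
        )
    return GroupComparison(metrics=tuple(results), alpha=alpha)
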