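"""The six monthly QC statistics measured on the phantom scans.

All values live on the scanner grey-level scale except the contrast and
MTF statistics, which are percentages:

* ``noise``       — mean of the five per-slice water SDs.
* ``water``       — mean of the five per-slice water ROI means.
* ``air``         — mean of the five per-slice air ROI means.
* ``uniformity``  — central ROI mean minus the average of the four
  peripheral ROI means (each a 5-slice mean); 0 on a perfectly uniform
  image, negative when the periphery is brighter than the center.
* ``contrast``    — per insert,
  ``[1 − (m_insert − m_air)/(m_background − m_air)] × 100``; per nominal
  level, the mean of the three insert values (1/2/3 mm diameters).
* ``mtf``         — bar-pattern modulation,
  ``[(m_background − m_bars)/(m_background + m_bars)] × 100`` at
  3.3/5/10 line pairs per mm.  Only the in-plane (transversal) resolution
  is measured; the axial resolution of the scanner matches it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .phantom_rois import RoiStats
from .volumes_io import Volume

__all__ = [
    "QC_PARAMETERS",
    "QcMeasurement",
    "LineProfile",
    "ContrastLevel",
    "noise",
    "water_value",
    "air_value",
    "uniformity",
    "contrast_insert",
    "contrast_level",
    "mtf",
    "profile_bar_means",
    "extract_line_profile",
]

#: The closed set of monitored parameters, in chart order.
QC_PARAMETERS = (
    "water",
    "air",
    "noise",
    "uniformity",
    "contrast_-9",
    "contrast_-6",
    "contrast_-3",
    "mtf_3.3",
    "mtf_5",
    "mtf_10",
)


@dataclass(frozen=True)
class QcMeasurement:
    """One dated value of one QC parameter."""

    parameter: str
    value: float
    date: int
    source: str = ""

    def __post_init__(self) -> None:
        if self.parameter not in QC_PARAMETERS:
            raise ValidationError(
                f"unknown QC parameter {self.parameter!r}; "
                f"expected one of {QC_PARAMETERS}"
            )
        if not np.isfinite(self.value):
            raise ValidationError(
                f"{self.parameter}: measurement value must be finite"
            )


@dataclass(frozen=True)
class LineProfile:
    """Grey values sampled along a straight segment, ``spacing`` mm apart."""

    samples: tuple[float, ...]
    spacing: float

    def __post_init__(self) -> None:
        if len(self.samples) < 2:
            raise ValidationError("line profile needs at least 2 samples")
        if self.spacing <= 0:
            raise ValidationError("line profile spacing must be > 0")


@dataclass(frozen=True)
class ContrastLevel:
    """The three per-insert contrasts of one nominal level and their mean."""

    nominal: float
    per_insert: tuple[float, float, float]
    level_value: float


def _protocol_mean(
    values: Sequence[float], expected: int, what: str, strict: bool
) -> float:
    if len(values) != expected:
        msg = (
            f"{what}: protocol expects {expected} slices, got {len(values)}"
        )
        if strict:
            raise ValidationError(msg)
        warnings.warn(msg + " (lenient mode, non-protocol measurement)")
    return float(np.mean(values))


def noise(stats: RoiStats, strict: bool = True) -> float:
    """Image noise: the mean of the five per-slice water SDs (grey levels)."""
    return _protocol_mean(stats.per_slice_sd, 5, "noise", strict)


def water_value(stats: RoiStats, strict: bool = True) -> float:
    """Water grey level: the mean of the five per-slice ROI means."""
    return _protocol_mean(stats.per_slice_mean, 5, "water", strict)


def air_value(stats: RoiStats, strict: bool = True) -> float:
    """Air grey level: the mean of the five per-slice ROI means."""
    return _protocol_mean(stats.per_slice_mean, 5, "air", strict)


def uniformity(
    central: RoiStats, peripheral: Sequence[RoiStats], strict: bool = True
) -> float:
    """Central 5-slice mean minus the average of the four peripheral means.

    The peripheral term divides by the number of peripheral ROIs (four):
    this is the only convention consistent with a chart anchor near −41
    when the central reading is 2000 and the peripherals read about 2041.
    """
    if len(peripheral) != 4:
        raise ValidationError(
            f"uniformity needs exactly 4 peripheral ROI stats, got {len(peripheral)}"
        )
    counts = {central.n_slices} | {p.n_slices for p in peripheral}
    if len(counts) != 1:
        raise ValidationError(f"mismatched slice counts across ROIs: {counts}")
    central_mean = _protocol_mean(central.per_slice_mean, 5, "uniformity", strict)
    peripheral_means = [
        _protocol_mean(p.per_slice_mean, 5, "uniformity", strict)
        for p in peripheral
    ]
    return central_mean - float(np.mean(peripheral_means))


def contrast_insert(
    insert_mean: float, background_mean: float, air_mean: float
) -> float:
    """Low-contrast value of one insert, in %.

    ``[1 − (m_insert − m_air)/(m_background − m_air)] × 100``: 0 % when
    the insert matches the background, 100 % when it matches air.  The
    value is invariant under any affine rescaling applied to all three
    grey levels, so a global scanner shift does not move it.
    """
    denom = background_mean - air_mean
    if denom == 0:
        raise ValidationError(
            "degenerate contrast: background and air grey levels are equal"
        )
    return (1.0 - (insert_mean - air_mean) / denom) * 100.0


def contrast_level(
    inserts: Sequence[float], nominal: float
) -> ContrastLevel:
    """Average the three same-level insert contrasts (1, 2, 3 mm)."""
    if len(inserts) != 3:
        raise ValidationError(
            f"contrast level needs exactly 3 insert values, got {len(inserts)}"
        )
    values = tuple(float(v) for v in inserts)
    return ContrastLevel(
        nominal=float(nominal),
        per_insert=values,
        level_value=float(np.mean(values)),
    )


def mtf(background_mean: float, bars_mean: float) -> float:
    """Bar-pattern modulation in %, ``(bg − bars)/(bg + bars) × 100``.

    Invariant under multiplicative rescaling of both means, but *not*
    under additive grey-level shifts — a drifted scanner changes it.
    """
    denom = background_mean + bars_mean
    if denom == 0:
        raise ValidationError("degenerate MTF: background + bars means sum to 0")
    return (background_mean - bars_mean) / denom * 100.0


# -- line profiles --------------------------------------------------------


def extract_line_profile(
    volume: Volume,
    start_xy: tuple[float, float],
    end_xy: tuple[float, float],
    z: int,
    step: float | None = None,
) -> LineProfile:
    """Sample grey values along an in-plane segment by linear interpolation.

    ``step`` defaults to half the in-plane voxel spacing, fine enough to
    resolve single-voxel bar widths.
    """
    if not 0 <= z < volume.n_slices:
        raise ValidationError(f"slice {z} outside volume with {volume.n_slices} slices")
    if step is None:
        step = min(volume.spacing[1], volume.spacing[2]) / 2.0
    x0, y0 = start_xy
    x1, y1 = end_xy
    length = float(np.hypot(x1 - x0, y1 - y0))
    if length <= 0:
        raise ValidationError("line profile start and end coincide")
    n = max(int(round(length / step)) + 1, 2)
    t = np.linspace(0.0, 1.0, n)
    xs = x0 + t * (x1 - x0)
    ys = y0 + t * (y1 - y0)
    # physical mm -> fractional voxel indices
    iy = (ys - volume.origin[1]) / volume.spacing[1]
    ix = (xs - volume.origin[2]) / volume.spacing[2]
    samples = ndimage.map_coordinates(
        volume.voxels[z].astype(np.float64), [iy, ix], order=1, mode="nearest"
    )
    return LineProfile(samples=tuple(float(s) for s in samples),
                       spacing=length / (n - 1))


def profile_bar_means(
    profiles: LineProfile | Sequence[LineProfile],
    guard_width: float | None = None,
) -> tuple[float, float]:
    """Classify profile samples into plateau ('background') and valley
    ('bars') populations and return their means.

    Each profile is thresholded at its midrange ``(max + min)/2``, where
    max and min are taken as the 98th/2nd percentiles so single noisy
    samples cannot move the threshold; samples within ``guard_width`` mm
    of a threshold crossing are discarded so that blurred edges
    contaminate neither population.  ``guard_width`` defaults to two
    sample spacings.  When several profiles are given (the protocol
    records three, taken at small parallel offsets), per-profile means
    are averaged.
    """
    if isinstance(profiles, LineProfile):
        profiles = [profiles]
    if len(profiles) == 0:
        raise ValidationError("no line profiles given")
    bg_means = []
    bar_means = []
    for profile in profiles:
        samples = np.asarray(profile.samples, dtype=np.float64)
        lo, hi = np.percentile(samples, [2.0, 98.0])
        if hi - lo <= 1e-12 * max(abs(hi), 1.0):
            raise ValidationError(
                "no modulation found: line profile is constant"
            )
        threshold = (hi + lo) / 2.0
        above = samples >= threshold
        guard = guard_width if guard_width is not None else 2.0 * profile.spacing
        guard_n = max(int(np.ceil(guard / profile.spacing)), 0)
        crossings = np.flatnonzero(np.diff(above.astype(np.int8)) != 0)
        # Relax the guard if it swallows an entire population (narrow bars
        # at high spatial frequency): shrink until both classes survive.
        while True:
            keep = np.ones_like(above)
            for c in crossings:
                keep[max(c - guard_n + 1, 0) : c + guard_n + 1] = False
            bg = samples[above & keep]
            bars = samples[~above & keep]
            if bg.size > 0 and bars.size > 0:
                break
            if guard_n == 0:
                raise ValidationError(
                    "profile too short to separate plateau and valley samples"
                )
            guard_n -= 1
        bg_means.append(bg.mean())
        bar_means.append(bars.mean())
    return float(np.mean(bg_means)), float(np.mean(bar_means))
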