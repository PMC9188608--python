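"""Fixed ROI segmentation maps for the QC phantoms.

Three phantoms drive the monthly protocol:

* a 32 mm water cylinder (noise, water grey level, uniformity),
* a 20 mm air-filled bar-pattern phantom (air grey level, spatial
  resolution),
* a 20 mm low-contrast phantom with nine cylindrical inserts
  (−9/−6/−3 % nominal contrast × 1/2/3 mm diameters).

Each map is a small set of named circular ROIs positioned in physical
(mm) coordinates and propagated along a fixed slice window: 5 contiguous
slices for water/air/uniformity, 100 slices for the low-contrast test.
A voxel belongs to an ROI iff its *center* falls inside the circle; no
partial-area weighting is applied, so membership is deterministic and
identical on every slice.

The noise/water ROI area follows the 10 %-of-base-area rule: for a
cylinder of diameter ``d`` the ROI radius is ``(d/2)·sqrt(0.1)``, giving
80.4 mm² on the 32 mm phantom and 31.4 mm² on the 20 mm phantom.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import GeometryError, ValidationError
from .volumes_io import Volume

__all__ = [
    "CircularRoi",
    "RoiMap",
    "RoiStats",
    "LowContrastLayout",
    "default_low_contrast_layout",
    "radius_for_area_fraction",
    "water_roi_map",
    "uniformity_roi_map",
    "low_contrast_roi_map",
    "air_roi_map",
    "extract_roi_stats",
    "roi_mask",
    "PROTOCOL_SLICES_WATER",
    "PROTOCOL_SLICES_LOW_CONTRAST",
    "PERIPHERAL_RADIUS_FRACTION",
    "INSERT_ROI_DIAMETER_FRACTION",
]

#: Slice window of the water/air/uniformity tests (contiguous slices).
PROTOCOL_SLICES_WATER = 5
#: Slice window of the low-contrast test.
PROTOCOL_SLICES_LOW_CONTRAST = 100
#: Peripheral uniformity ROIs sit at this fraction of the phantom radius.
PERIPHERAL_RADIUS_FRACTION = 0.6
#: Insert ROI diameter as a fraction of the physical insert diameter,
#: keeping the ROI clear of the partial-volume rim.
INSERT_ROI_DIAMETER_FRACTION = 0.7


@dataclass(frozen=True)
class CircularRoi:
    """A circular ROI in physical coordinates, propagated along z.

    ``slice_range`` is an inclusive ``(first, last)`` pair of 0-based
    slice indices.
    """

    name: str
    center_xy: tuple[float, float]
    radius: float
    slice_range: tuple[int, int]

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValidationError(f"ROI {self.name!r}: radius must be > 0")
        first, last = self.slice_range
        if last < first:
            raise ValidationError(f"ROI {self.name!r}: empty slice range")

    @property
    def area(self) -> float:
        """Area in mm², π·r²."""
        return math.pi * self.radius**2

    @property
    def n_slices(self) -> int:
        return self.slice_range[1] - self.slice_range[0] + 1

    @property
    def slices(self) -> range:
        return range(self.slice_range[0], self.slice_range[1] + 1)


@dataclass(frozen=True)
class RoiMap:
    """An ordered, uniquely named collection of ROIs on one phantom."""

    phantom_kind: str
    rois: tuple[CircularRoi, ...]

    def __post_init__(self) -> None:
        names = [r.name for r in self.rois]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate ROI names in map: {names}")

    def __iter__(self):
        return iter(self.rois)

    def __getitem__(self, name: str) -> CircularRoi:
        for roi in self.rois:
            if roi.name == name:
                return roi
        raise KeyError(name)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.rois)

    def validate_inside(self, volume: Volume) -> None:
        """Check every ROI lies fully inside the volume's extent."""
        x = volume.axis_coords(2)
        y = volume.axis_coords(1)
        for roi in self.rois:
            cx, cy = roi.center_xy
            if (
                cx - roi.radius < x[0]
                or cx + roi.radius > x[-1]
                or cy - roi.radius < y[0]
                or cy + roi.radius > y[-1]
            ):
                raise GeometryError(
                    f"ROI {roi.name!r} exits the in-plane extent of the volume"
                )
            if roi.slice_range[0] < 0 or roi.slice_range[1] >= volume.n_slices:
                raise GeometryError(
                    f"ROI {roi.name!r} slice range {roi.slice_range} exits the "
                    f"{volume.n_slices}-slice volume"
                )

    # -- serialization ----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "phantom_kind": self.phantom_kind,
            "rois": [
                {
                    "name": r.name,
                    "center_xy": list(r.center_xy),
                    "radius": r.radius,
                    "slice_range": list(r.slice_range),
                }
                for r in self.rois
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RoiMap":
        if isinstance(source, Path) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ):
            source = Path(source).read_text()
        payload = json.loads(source)
        rois = tuple(
            CircularRoi(
                name=r["name"],
                center_xy=tuple(r["center_xy"]),
                radius=r["radius"],
                slice_range=tuple(r["slice_range"]),
            )
            for r in payload["rois"]
        )
        return cls(phantom_kind=payload["phantom_kind"], rois=rois)


@dataclass(frozen=True)
class RoiStats:
    """Per-slice mean and SD of grey levels inside one ROI."""

    per_slice_mean: tuple[float, ...]
    per_slice_sd: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.per_slice_mean) != len(self.per_slice_sd):
            raise ValidationError("mean/SD sequences differ in length")
        if any(sd < 0 for sd in self.per_slice_sd):
            raise ValidationError("per-slice SD must be non-negative")

    @property
    def n_slices(self) -> int:
        return len(self.per_slice_mean)


# -- construction helpers -------------------------------------------------


def radius_for_area_fraction(phantom_diameter: float, fraction: float) -> float:
    """ROI radius whose area is ``fraction`` of the phantom base area.

    Solves ``π·r² = fraction · π·(d/2)²``, i.e. ``r = (d/2)·sqrt(fraction)``.
    """
    if phantom_diameter <= 0:
        raise ValidationError("phantom_diameter must be > 0")
    if not 0 < fraction <= 1:
        raise ValidationError("fraction must be in (0, 1]")
    return (phantom_diameter / 2.0) * math.sqrt(fraction)


def _slice_window(volume: Volume, center_slice: int | None, n: int) -> tuple[int, int]:
    if center_slice is None:
        center_slice = volume.n_slices // 2
    half = n // 2
    first, last = center_slice - half, center_slice + (n - 1 - half)
    if first < 0 or last >= volume.n_slices:
        raise ValidationError(
            f"cannot center a {n}-slice window on slice {center_slice} of a "
            f"{volume.n_slices}-slice volume"
        )
    return first, last


def water_roi_map(
    volume: Volume,
    center_slice: int | None = None,
    phantom_diameter: float = 32.0,
    area_fraction: float = 0.1,
    center_xy: tuple[float, float] | None = None,
) -> RoiMap:
    """Single centered ROI for the noise test and water evaluation.

    The ROI covers ``area_fraction`` (default 10 %) of the cylinder base
    area and spans 5 contiguous slices centered on ``center_slice``
    (default: the middle slice).
    """
    first, last = _slice_window(volume, center_slice, PROTOCOL_SLICES_WATER)
    if center_xy is None:
        center_xy = volume.center_xy
    roi = CircularRoi(
        name="water",
        center_xy=center_xy,
        radius=radius_for_area_fraction(phantom_diameter, area_fraction),
        slice_range=(first, last),
    )
    roi_map = RoiMap(phantom_kind="water", rois=(roi,))
    roi_map.validate_inside(volume)
    return roi_map


def uniformity_roi_map(
    volume: Volume,
    center_slice: int | None = None,
    phantom_diameter: float = 32.0,
    area_fraction: float = 0.1,
    center_xy: tuple[float, float] | None = None,
    peripheral_fraction: float = PERIPHERAL_RADIUS_FRACTION,
) -> RoiMap:
    """Five equal-radius ROIs for the uniformity test.

    One central ROI (``a``) plus four peripheral ROIs (``b``–``e``) whose
    centers sit at ``peripheral_fraction`` of the phantom radius from the
    axis, at 0°/90°/180°/270°.  All five span the same 5 slices.
    """
    first, last = _slice_window(volume, center_slice, PROTOCOL_SLICES_WATER)
    if center_xy is None:
        center_xy = volume.center_xy
    radius = radius_for_area_fraction(phantom_diameter, area_fraction)
    phantom_radius = phantom_diameter / 2.0
    d = peripheral_fraction * phantom_radius
    if d + radius > phantom_radius:
        raise GeometryError(
            "peripheral ROIs exit the phantom interior: "
            f"offset {d:.2f} + radius {radius:.2f} > {phantom_radius:.2f} mm"
        )
    cx, cy = center_xy
    offsets = {
        "a": (0.0, 0.0),
        "b": (d, 0.0),
        "c": (0.0, d),
        "d": (-d, 0.0),
        "e": (0.0, -d),
    }
    rois = tuple(
        CircularRoi(
            name=name,
            center_xy=(cx + dx, cy + dy),
            radius=radius,
            slice_range=(first, last),
        )
        for name, (dx, dy) in offsets.items()
    )
    roi_map = RoiMap(phantom_kind="water", rois=rois)
    roi_map.validate_inside(volume)
    return roi_map


def air_roi_map(
    volume: Volume,
    center_slice: int | None = None,
    phantom_diameter: float = 20.0,
    area_fraction: float = 0.1,
    center_xy: tuple[float, float] | None = None,
) -> RoiMap:
    """Single ROI inside the bar-pattern phantom's air for the air value.

    Covers 10 % of the 20 mm phantom section (31.4 mm²) over 5 slices.
    ``center_xy`` defaults to the grid center; on the real phantom the
    operator places it in free air away from the resolution chips.
    """
    first, last = _slice_window(volume, center_slice, PROTOCOL_SLICES_WATER)
    if center_xy is None:
        center_xy = volume.center_xy
    roi = CircularRoi(
        name="air",
        center_xy=center_xy,
        radius=radius_for_area_fraction(phantom_diameter, area_fraction),
        slice_range=(first, last),
    )
    roi_map = RoiMap(phantom_kind="bar_pattern", rois=(roi,))
    roi_map.validate_inside(volume)
    return roi_map


# -- low-contrast phantom layout ------------------------------------------


@dataclass(frozen=True)
class InsertSite:
    """Physical position of one low-contrast insert."""

    name: str
    center_xy: tuple[float, float]
    diameter: float
    nominal_contrast_pct: float


@dataclass(frozen=True)
class LowContrastLayout:
    """Physical layout of the nine inserts plus background and air ROIs."""

    inserts: tuple[InsertSite, ...]
    background_xy: tuple[float, float]
    background_radius: float
    air_xy: tuple[float, float]
    air_radius: float
    phantom_diameter: float = 20.0


def default_low_contrast_layout(
    center_xy: tuple[float, float] = (0.0, 0.0),
    ring_radius: float = 6.0,
    phantom_diameter: float = 20.0,
    contrasts: Sequence[float] = (-9.0, -6.0, -3.0),
    diameters: Sequence[float] = (1.0, 2.0, 3.0),
) -> LowContrastLayout:
    """Nine inserts on a ring, grouped by contrast level.

    The manufacturer arranges three contrast levels × three diameters on a
    circle around the phantom axis; the exact angular layout is configured,
    not inferred from the image.  The air ROI sits outside the phantom, as
    the protocol places it for this test.
    """
    cx, cy = center_xy
    inserts = []
    angle = 90.0  # start at the top, go clockwise
    for contrast in contrasts:
        for diameter in diameters:
            rad = math.radians(angle)
            inserts.append(
                InsertSite(
                    name=f"insert_{contrast:+.0f}pct_{diameter:.0f}mm",
                    center_xy=(
                        cx + ring_radius * math.cos(rad),
                        cy + ring_radius * math.sin(rad),
                    ),
                    diameter=float(diameter),
                    nominal_contrast_pct=float(contrast),
                )
            )
            angle -= 40.0
    return LowContrastLayout(
        inserts=tuple(inserts),
        background_xy=center_xy,
        background_radius=2.0,
        air_xy=(cx, cy - phantom_diameter / 2.0 - 2.5),
        air_radius=1.5,
        phantom_diameter=phantom_diameter,
    )


def low_contrast_roi_map(
    volume: Volume,
    layout: LowContrastLayout | None = None,
    start_slice: int = 0,
    n_slices: int = PROTOCOL_SLICES_LOW_CONTRAST,
    roi_diameter_fraction: float = INSERT_ROI_DIAMETER_FRACTION,
) -> RoiMap:
    """Eleven ROIs for the low-contrast test.

    Nine insert ROIs with diameters proportional (default 70 %) to the
    1/2/3 mm insert diameters, one resin-background ROI, and one air ROI
    outside the phantom — each propagated over ``n_slices`` (default 100)
    image slices starting at ``start_slice``.
    """
    if layout is None:
        layout = default_low_contrast_layout(center_xy=volume.center_xy)
    last = start_slice + n_slices - 1
    if start_slice < 0 or last >= volume.n_slices:
        raise ValidationError(
            f"volume spans {volume.n_slices} slices; cannot propagate "
            f"{n_slices} slices from slice {start_slice}"
        )
    slice_range = (start_slice, last)
    rois = [
        CircularRoi(
            name=site.name,
            center_xy=site.center_xy,
            radius=roi_diameter_fraction * site.diameter / 2.0,
            slice_range=slice_range,
        )
        for site in layout.inserts
    ]
    # overlap check on the physical inserts
    for i, a in enumerate(layout.inserts):
        for b in layout.inserts[i + 1 :]:
            dist = math.hypot(
                a.center_xy[0] - b.center_xy[0], a.center_xy[1] - b.center_xy[1]
            )
            if dist < (a.diameter + b.diameter) / 2.0:
                raise GeometryError(
                    f"inserts {a.name!r} and {b.name!r} overlap "
                    f"(center distance {dist:.2f} mm)"
                )
    rois.append(
        CircularRoi(
            name="background",
            center_xy=layout.background_xy,
            radius=layout.background_radius,
            slice_range=slice_range,
        )
    )
    rois.append(
        CircularRoi(
            name="air",
            center_xy=layout.air_xy,
            radius=layout.air_radius,
            slice_range=slice_range,
        )
    )
    roi_map = RoiMap(phantom_kind="low_contrast", rois=tuple(rois))
    roi_map.validate_inside(volume)
    return roi_map


# -- statistics extraction ------------------------------------------------


def roi_mask(volume: Volume, roi: CircularRoi) -> np.ndarray:
    """2D boolean in-plane membership mask (voxel centers inside circle)."""
    x = volume.axis_coords(2)
    y = volume.axis_coords(1)
    cx, cy = roi.center_xy
    dx = x[None, :] - cx
    dy = y[:, None] - cy
    return dx * dx + dy * dy <= roi.radius**2


def extract_roi_stats(volume: Volume, roi: CircularRoi, ddof: int = 1) -> RoiStats:
    """Per-slice mean and sample SD (``ddof=1``) of grey levels in the ROI.

    The SD convention matches the one used for baseline tolerance widths:
    the n−1 (sample) denominator, appropriate for small-n estimates.
    """
    if roi.slice_range[0] < 0 or roi.slice_range[1] >= volume.n_slices:
        raise ValidationError(
            f"ROI {roi.name!r} slice range {roi.slice_range} exits the volume"
        )
    mask = roi_mask(volume, roi)
    n = int(mask.sum())
    if n == 0:
        raise ValidationError(
            f"ROI {roi.name!r} contains no voxel centers (radius {roi.radius} mm "
            f"vs spacing {volume.spacing[1:]!r} mm)"
        )
    means = []
    sds = []
    for z in roi.slices:
        values = volume.voxels[z][mask].astype(np.float64)
        means.append(float(values.mean()))
        sds.append(float(values.std(ddof=ddof)) if n > ddof else 0.0)
    return RoiStats(per_slice_mean=tuple(means), per_slice_sd=tuple(sds))
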