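"""Parametric synthetic phantoms, toy lung volumes, and injectable drift.

No deposited micro-CT scans exist for the QC protocol, so every test
input is generated with known ground truth:

* **water** — a 32 mm water cylinder (grey ≈ 2000) in air (grey ≈ 449),
  with optional radial linear non-uniformity and additive Gaussian noise;
* **bar_pattern** — a 20 mm air-filled resin shell holding two 5 × 5 mm
  chips with 3.3 / 5 / 10 lp/mm bar patterns (150 / 100 / 50 µm line
  widths, ``line width = 1/(2·frequency)``);
* **low_contrast** — a 20 mm resin cylinder with nine cylindrical inserts
  (−9 / −6 / −3 % nominal contrast × 1 / 2 / 3 mm diameters);
* **lung** — bilateral ellipsoidal lung fields joined by a main-airway
  bridge, embedded in soft tissue, with a controllable parenchyma
  grey-level distribution and an exact target volume.

System blur is modeled as a single isotropic Gaussian applied before
noise; noise is additive, Gaussian, and independent per voxel (CT noise
correlation is out of scope).  All generators are pure functions of
``(spec, seed)``.

Scanner drift is injected after the fact as an additive grey-level shift
plus extra noise, emulating the failure mode in which water/air grey
levels float upward and image noise rises while spatial resolution and
low-contrast detectability stay intact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .errors import GeometryError, ValidationError
from .phantom_rois import (
    LowContrastLayout,
    default_low_contrast_layout,
    radius_for_area_fraction,
)
from .volumes_io import Volume

__all__ = [
    "PhantomSpec",
    "LungSpec",
    "DriftSpec",
    "GroundTruth",
    "BarSegment",
    "gen_phantom",
    "gen_lung",
    "inject_drift",
    "estimate_noise_sd",
    "DEFAULT_BLUR_SIGMA_MM",
]

#: Default isotropic system blur (mm); chosen so the synthetic scanner's
#: bar-pattern modulation decreases from ~50 % at 3.3 lp/mm to ~23 % at
#: 10 lp/mm, the regime of a 50 µm-voxel preclinical system.
DEFAULT_BLUR_SIGMA_MM = 0.04

_KIND_DIAMETERS = {"water": 32.0, "bar_pattern": 20.0, "low_contrast": 20.0}
_KIND_FOV = {"water": 36.0, "bar_pattern": 24.0, "low_contrast": 30.0}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, grey levels, and degradation model of one phantom scan.

    ``gradient`` adds a radial linear non-uniformity ``g·(r − r_ref)``
    (grey levels per mm) to the water interior.  ``gradient_ref_radius``
    defaults to the mean radius of the standard central QC ROI, so the
    configured ``grey_water`` is exactly what that ROI reads regardless
    of the gradient strength.
    """

    kind: str = "water"
    diameter: float | None = None
    grey_water: float = 2000.0
    grey_air: float = 449.0
    grey_background: float = 1800.0
    noise_sd: float = 124.0
    gradient: float = 0.0
    gradient_ref_radius: float | None = None
    blur_sigma: float = DEFAULT_BLUR_SIGMA_MM
    insert_contrasts: tuple[float, ...] = (-9.0, -6.0, -3.0)
    insert_diameters: tuple[float, ...] = (1.0, 2.0, 3.0)
    bar_frequencies: tuple[float, ...] = (3.3, 5.0, 10.0)
    spacing: float = 0.05
    n_slices: int | None = None
    fov: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KIND_DIAMETERS:
            raise ValidationError(f"unknown phantom kind {self.kind!r}")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.spacing <= 0:
            raise ValidationError("spacing must be > 0")
        d = self.diameter if self.diameter is not None else _KIND_DIAMETERS[self.kind]
        if d <= 0:
            raise ValidationError("diameter must be > 0")

    @property
    def phantom_diameter(self) -> float:
        return self.diameter if self.diameter is not None else _KIND_DIAMETERS[self.kind]

    @property
    def fov_mm(self) -> float:
        return self.fov if self.fov is not None else _KIND_FOV[self.kind]

    @property
    def slices(self) -> int:
        if self.n_slices is not None:
            return self.n_slices
        return 104 if self.kind == "low_contrast" else 7

    def bar_line_width(self, frequency: float) -> float:
        """Line width (mm) of a bar pattern: 1 / (2 · frequency)."""
        return 1.0 / (2.0 * frequency)


@dataclass(frozen=True)
class BarSegment:
    """Profile segment crossing one bar pattern perpendicular to the bars."""

    frequency: float
    start_xy: tuple[float, float]
    end_xy: tuple[float, float]
    offset_direction: tuple[float, float]  # unit vector parallel to the bars


@dataclass
class GroundTruth:
    """Noiseless reference volume plus region labels and layout metadata."""

    noiseless: Volume
    labels: np.ndarray
    label_names: dict[str, int]
    nominal: dict[str, float]
    layout: LowContrastLayout | None = None
    bar_segments: tuple[BarSegment, ...] = ()
    center_xy: tuple[float, float] = (0.0, 0.0)
    phantom_radius: float = 0.0

    def mask(self, name: str) -> np.ndarray:
        return self.labels == self.label_names[name]


@dataclass(frozen=True)
class DriftSpec:
    """Injectable scanner drift: additive grey shift plus extra noise.

    The extra noise has SD ``original_noise · (noise_scale − 1)`` and is
    independent of the existing noise, so the resulting total SD is
    ``original_noise · sqrt(1 + (noise_scale − 1)²)``.
    """

    grey_shift: float = 0.0
    noise_scale: float = 1.0
    allow_noise_reduction: bool = False

    def __post_init__(self) -> None:
        if self.noise_scale < 1.0 and not self.allow_noise_reduction:
            raise ValidationError(
                "noise_scale < 1 models a noise reduction; pass "
                "allow_noise_reduction=True if that is intended"
            )


# -- grid helpers ---------------------------------------------------------


def _grid(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, tuple[float, float, float], int]:
    s = spec.spacing
    n_xy = int(round(spec.fov_mm / s))
    nz = spec.slices
    # grid centered on (0, 0) in-plane
    origin = (-0.0, -(n_xy - 1) * s / 2.0, -(n_xy - 1) * s / 2.0)
    coords = origin[1] + s * np.arange(n_xy)
    x = coords[None, :]
    y = coords[:, None]
    return x, y, origin, nz


def _finalize(
    spec: PhantomSpec,
    template: np.ndarray,
    labels2d: np.ndarray,
    label_names: dict[str, int],
    nominal: dict[str, float],
    origin: tuple[float, float, float],
    nz: int,
    rng: np.random.Generator,
    **truth_kwargs,
) -> tuple[Volume, GroundTruth]:
    sigma_vox = spec.blur_sigma / spec.spacing
    blurred = ndimage.gaussian_filter(template, sigma=sigma_vox, mode="nearest")
    clean = np.broadcast_to(
        blurred.astype(np.float32), (nz,) + blurred.shape
    ).copy()
    spacing = (spec.spacing,) * 3
    noiseless = Volume(voxels=clean.copy(), spacing=spacing, origin=origin)
    if spec.noise_sd > 0:
        noisy = clean + rng.normal(
            0.0, spec.noise_sd, size=clean.shape
        ).astype(np.float32)
    else:
        noisy = clean
    volume = Volume(
        voxels=noisy,
        spacing=spacing,
        origin=origin,
        meta={"phantom_kind": spec.kind, "seed": spec.seed},
    )
    labels = np.broadcast_to(labels2d, (nz,) + labels2d.shape)
    truth = GroundTruth(
        noiseless=noiseless,
        labels=labels,
        label_names=label_names,
        nominal=nominal,
        phantom_radius=spec.phantom_diameter / 2.0,
        **truth_kwargs,
    )
    return volume, truth


def _stripe_air_coverage(
    x: np.ndarray, gaps: Sequence[tuple[float, float]], spacing: float
) -> np.ndarray:
    """Fraction of each voxel's x-extent covered by air gaps (1D, exact)."""
    coverage = np.zeros_like(x)
    half = spacing / 2.0
    for a, b in gaps:
        overlap = np.clip(np.minimum(b, x + half) - np.maximum(a, x - half), 0.0, None)
        coverage += overlap
    return np.clip(coverage / spacing, 0.0, 1.0)


# -- generators -----------------------------------------------------------


def gen_phantom(spec: PhantomSpec) -> tuple[Volume, GroundTruth]:
    """Generate one phantom scan and its ground truth.

    Deterministic given ``spec`` (which carries the seed).
    """
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "water":
        return _gen_water(spec, rng)
    if spec.kind == "bar_pattern":
        return _gen_bar_pattern(spec, rng)
    return _gen_low_contrast(spec, rng)


def _gen_water(spec: PhantomSpec, rng) -> tuple[Volume, GroundTruth]:
    x, y, origin, nz = _grid(spec)
    r = np.hypot(x, y)
    radius = spec.phantom_diameter / 2.0
    inside = r <= radius
    ref = spec.gradient_ref_radius
    if ref is None:
        # mean radius of the 10%-area central ROI: (2/3) of its radius
        ref = (2.0 / 3.0) * radius_for_area_fraction(spec.phantom_diameter, 0.1)
    template = np.full(r.shape, spec.grey_air, dtype=np.float64)
    template[inside] = spec.grey_water + spec.gradient * (r[inside] - ref)
    labels2d = inside.astype(np.uint8)
    return _finalize(
        spec,
        template,
        labels2d,
        {"outside": 0, "water": 1},
        {"water": spec.grey_water, "air": spec.grey_air},
        origin,
        nz,
        rng,
        center_xy=(0.0, 0.0),
    )


#: Bar-pattern chip layout: half-size (mm), chip centers, and the air ROI
#: center used by the protocol — all clear of one another inside the
#: 9 mm-radius air cavity.
_CHIP_HALF = 2.5
_CHIP_CENTERS = ((2.8, 2.8), (-2.8, -2.8))
BAR_AIR_ROI_XY = (-4.0, 4.0)
_SHELL_THICKNESS = 1.0
_BAR_LENGTH = 1.0  # extent of each bar along its own direction, mm
_PATTERN_ROW_OFFSETS = (1.5, 0.0, -1.5)
_N_PAIRS = {3.3: 5, 5.0: 5, 10.0: 8}


def _gen_bar_pattern(spec: PhantomSpec, rng) -> tuple[Volume, GroundTruth]:
    x, y, origin, nz = _grid(spec)
    r = np.hypot(x, y)
    radius = spec.phantom_diameter / 2.0
    inner = radius - _SHELL_THICKNESS
    template = np.full(r.shape, spec.grey_air, dtype=np.float64)
    shell = (r <= radius) & (r > inner)
    template[shell] = spec.grey_background
    labels2d = np.zeros(r.shape, dtype=np.uint8)
    labels2d[r <= inner] = 1  # interior air
    labels2d[shell] = 2

    segments: list[BarSegment] = []
    measured_chip = _CHIP_CENTERS[0]
    for cx, cy in _CHIP_CENTERS:
        chip = (np.abs(x - cx) <= _CHIP_HALF) & (np.abs(y - cy) <= _CHIP_HALF)
        template[chip] = spec.grey_background
        labels2d[chip] = 3
        for freq, row_dy in zip(spec.bar_frequencies, _PATTERN_ROW_OFFSETS):
            w = spec.bar_line_width(freq)
            n_pairs = _N_PAIRS.get(freq, max(int(round(0.8 / w)), 4))
            pattern_width = 2.0 * w * n_pairs
            x_start = cx - pattern_width / 2.0
            gaps = [
                (x_start + 2.0 * w * i, x_start + 2.0 * w * i + w)
                for i in range(n_pairs)
            ]
            row = chip & (np.abs(y - (cy + row_dy)) <= _BAR_LENGTH / 2.0)
            cov = _stripe_air_coverage(x, gaps, spec.spacing)
            cov2d = np.broadcast_to(cov, template.shape)
            template[row] = (
                spec.grey_background * (1.0 - cov2d[row])
                + spec.grey_air * cov2d[row]
            )
            if (cx, cy) == measured_chip:
                margin = 1.0
                segments.append(
                    BarSegment(
                        frequency=freq,
                        start_xy=(x_start - margin, cy + row_dy),
                        end_xy=(x_start + pattern_width + margin, cy + row_dy),
                        offset_direction=(0.0, 1.0),
                    )
                )
    return _finalize(
        spec,
        template,
        labels2d,
        {"outside": 0, "air": 1, "shell": 2, "chip": 3},
        {"air": spec.grey_air, "chip": spec.grey_background},
        origin,
        nz,
        rng,
        bar_segments=tuple(segments),
        center_xy=(0.0, 0.0),
    )


def _gen_low_contrast(spec: PhantomSpec, rng) -> tuple[Volume, GroundTruth]:
    x, y, origin, nz = _grid(spec)
    r = np.hypot(x, y)
    radius = spec.phantom_diameter / 2.0
    inside = r <= radius
    template = np.full(r.shape, spec.grey_air, dtype=np.float64)
    template[inside] = spec.grey_background
    labels2d = np.zeros(r.shape, dtype=np.uint8)
    labels2d[inside] = 1
    layout = default_low_contrast_layout(
        phantom_diameter=spec.phantom_diameter,
        contrasts=spec.insert_contrasts,
        diameters=spec.insert_diameters,
    )
    nominal = {"background": spec.grey_background, "air": spec.grey_air}
    label_names = {"outside": 0, "background": 1}
    for idx, site in enumerate(layout.inserts, start=2):
        cx, cy = site.center_xy
        if math.hypot(cx, cy) + site.diameter / 2.0 >= radius:
            raise GeometryError(
                f"insert {site.name!r} exceeds the phantom radius"
            )
        insert_mask = (x - cx) ** 2 + (y - cy) ** 2 <= (site.diameter / 2.0) ** 2
        # Insert grey chosen so the ROI contrast formula returns the
        # nominal level exactly on a noiseless scan:
        # contrast = [1 - (m_k - m_air)/(m_bg - m_air)]*100 = c
        #   <=>  m_k = m_air + (1 - c/100)*(m_bg - m_air).
        c = site.nominal_contrast_pct
        grey = spec.grey_air + (1.0 - c / 100.0) * (
            spec.grey_background - spec.grey_air
        )
        template[insert_mask] = grey
        labels2d[insert_mask] = idx
        label_names[site.name] = idx
        nominal[site.name] = grey
    return _finalize(
        spec,
        template,
        labels2d,
        label_names,
        nominal,
        origin,
        nz,
        rng,
        layout=layout,
        center_xy=(0.0, 0.0),
    )


# -- toy lungs ------------------------------------------------------------


@dataclass(frozen=True)
class LungSpec:
    """A toy bilateral mouse-lung volume with controllable aeration.

    The parenchyma grey-level distribution is Gaussian when ``skew`` is 0
    and a moment-matched shifted gamma otherwise (mean/SD/skewness all
    honored exactly in expectation).  ``volume_target_mm3`` is hit to
    within one voxel by construction.
    """

    mean: float = 850.0
    sd: float = 130.0
    skew: float = 2.3
    volume_target_mm3: float = 532.0
    spacing: float = 0.05
    tissue_grey: float = 1600.0
    tissue_noise_sd: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.volume_target_mm3 <= 0:
            raise ValidationError("volume target must be > 0")
        if self.sd <= 0 or self.spacing <= 0:
            raise ValidationError("sd and spacing must be > 0")


def _parenchyma_values(spec: LungSpec, n: int, rng) -> np.ndarray:
    if abs(spec.skew) < 1e-12:
        return rng.normal(spec.mean, spec.sd, size=n)
    k = 4.0 / spec.skew**2
    g = rng.gamma(k, 1.0, size=n)
    standardized = (g - k) / math.sqrt(k)
    if spec.skew < 0:
        standardized = -standardized
    return spec.mean + spec.sd * standardized


def gen_lung(spec: LungSpec) -> tuple[Volume, np.ndarray]:
    """Generate a toy lung volume; returns ``(volume, truth_mask)``.

    Two ellipsoidal lung fields (semi-axis ratio 1 : 1.3 : 1.7) joined by
    a 0.4 mm-radius airway bridge, trimmed to the exact voxel count
    implied by ``volume_target_mm3``, embedded in noisy soft tissue.
    Seeds change the voxel noise, never the truth-mask geometry.
    """
    s = spec.spacing
    voxel_volume = s**3
    n_target = int(round(spec.volume_target_mm3 / voxel_volume))
    if n_target < 8:
        raise GeometryError("volume target smaller than a few voxels")
    # Ellipsoids sized ~15 % above the target so trimming stays interior.
    per_lung = 1.15 * spec.volume_target_mm3 / 2.0
    scale = (per_lung / ((4.0 / 3.0) * math.pi * 1.0 * 1.3 * 1.7)) ** (1.0 / 3.0)
    a, b, c = scale, 1.3 * scale, 1.7 * scale  # x, y, z semi-axes
    gap = 0.6
    cx = a + gap  # lung centers at (±cx, 0, 0)
    pad = 4 * s + 0.2
    nx = int(round(2 * (cx + a + pad) / s))
    ny = int(round(2 * (b + pad) / s))
    nz = int(round(2 * (c + pad) / s))
    origin = (-(nz - 1) * s / 2.0, -(ny - 1) * s / 2.0, -(nx - 1) * s / 2.0)
    z = (origin[0] + s * np.arange(nz))[:, None, None]
    y = (origin[1] + s * np.arange(ny))[None, :, None]
    x = (origin[2] + s * np.arange(nx))[None, None, :]

    rho_left = ((x + cx) / a) ** 2 + (y / b) ** 2 + (z / c) ** 2
    rho_right = ((x - cx) / a) ** 2 + (y / b) ** 2 + (z / c) ** 2
    rho = np.minimum(rho_left, rho_right)
    bridge = (np.abs(x) <= cx) & (y**2 + z**2 <= 0.4**2)
    bridge = np.broadcast_to(bridge, rho.shape)

    n_bridge = int(bridge.sum())
    n_ellipsoid = n_target - n_bridge
    if n_ellipsoid <= 0:
        raise GeometryError("volume target too small for the airway bridge")
    candidates = np.where(bridge, np.inf, rho).ravel()
    order = np.argpartition(candidates, n_ellipsoid)[:n_ellipsoid]
    if not np.all(np.isfinite(candidates[order])):
        raise GeometryError(
            f"volume target {spec.volume_target_mm3} mm³ exceeds the lung grid"
        )
    mask = bridge.copy()
    mask.ravel()[order] = True

    rng = np.random.default_rng(spec.seed)
    voxels = np.empty(rho.shape, dtype=np.float32)
    n_tissue = voxels.size - n_target
    tissue = rng.normal(spec.tissue_grey, spec.tissue_noise_sd, size=n_tissue)
    voxels[~mask] = tissue.astype(np.float32)
    voxels[mask] = _parenchyma_values(spec, n_target, rng).astype(np.float32)
    volume = Volume(
        voxels=voxels,
        spacing=(s, s, s),
        origin=origin,
        meta={"kind": "lung", "seed": spec.seed,
              "volume_target_mm3": spec.volume_target_mm3},
    )
    return volume, mask


# -- drift injection ------------------------------------------------------


def estimate_noise_sd(volume: Volume) -> float:
    """Robust noise estimate from first differences along x.

    For additive iid Gaussian noise the first difference has SD σ√2; the
    median absolute deviation makes the estimate insensitive to the sparse
    structural edges crossed by the differences.
    """
    diffs = np.diff(volume.voxels, axis=2).ravel()
    mad = float(np.median(np.abs(diffs - np.median(diffs))))
    return mad / (0.67448975 * math.sqrt(2.0))


def inject_drift(
    volume: Volume,
    drift: DriftSpec,
    seed: int,
    original_noise: float | None = None,
) -> Volume:
    """Apply a scanner drift to an existing volume.

    The grey shift is added everywhere; extra Gaussian noise with SD
    ``original_noise · (noise_scale − 1)`` is superimposed (``original_noise``
    is estimated from the volume when not supplied).  Shape, spacing, and
    origin are unchanged; the identity drift returns a bit-identical grid.
    """
    if drift.grey_shift == 0.0 and drift.noise_scale == 1.0:
        return volume.with_voxels(volume.voxels.copy())
    voxels = volume.voxels.astype(np.float32) + np.float32(drift.grey_shift)
    if drift.noise_scale != 1.0:
        if original_noise is None:
            original_noise = estimate_noise_sd(volume)
        extra_sd = original_noise * abs(drift.noise_scale - 1.0)
        rng = np.random.default_rng(seed)
        voxels = voxels + rng.normal(0.0, extra_sd, size=voxels.shape).astype(
            np.float32
        )
    out = volume.with_voxels(voxels)
    out.meta["drift"] = {
        "grey_shift": drift.grey_shift,
        "noise_scale": drift.noise_scale,
    }
    return out
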