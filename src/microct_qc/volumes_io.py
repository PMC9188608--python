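"""Load, save, and represent reconstructed 3D micro-CT volumes.

A :class:`Volume` is a 3D grid of scanner grey levels with isotropic (or
per-axis) voxel spacing in millimetres.  Grey levels are kept on the
scanner's native scale throughout the toolkit — there is no conversion to
Hounsfield units, because the QC protocol anchors its baselines (water
around 2000, air around 449 on the reference scanner) directly on that
scale.

Axis convention: ``voxels[z, y, x]`` with ``z`` the longitudinal slice
axis.  ``spacing`` and ``origin`` are ordered the same way, ``(z, y, x)``,
in mm.  Voxel indexing is 0-based and physical coordinates refer to voxel
centers, so voxel ``(0, 0, 0)`` sits exactly at ``origin``.

Supported on-disk formats:

* NIfTI (``.nii`` / ``.nii.gz``) via nibabel — spacing travels in the header.
* Multipage TIFF stacks (``.tif`` / ``.tiff``) via tifffile — spacing and
  origin travel in a YAML sidecar named ``<file>.yaml``.
* Raw little-endian binary (``.raw`` / ``.bin``) with a mandatory YAML/JSON
  sidecar declaring shape, dtype, spacing — the escape hatch for scanner
  exports whose proprietary container is not parsed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import tifffile
import yaml

from .errors import ConfigurationError, ValidationError

__all__ = ["Volume", "load_volume", "save_volume", "DEFAULT_SPACING_MM"]

#: Isotropic reconstructed voxel size of the reference scanner, mm.
DEFAULT_SPACING_MM = 0.05

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_TIFF_SUFFIXES = (".tif", ".tiff")
_RAW_SUFFIXES = (".raw", ".bin")


@dataclass
class Volume:
    """A reconstructed 3D grey-level volume.

    Parameters
    ----------
    voxels
        3D array indexed ``[z, y, x]``; any integer or float dtype.
    spacing
        Voxel edge length per axis ``(z, y, x)`` in mm; all entries > 0.
    origin
        Physical coordinate (mm) of the center of voxel ``(0, 0, 0)``,
        ordered ``(z, y, x)``.
    meta
        Free-form acquisition metadata (tube voltage, current, scan date…).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (
        DEFAULT_SPACING_MM,
        DEFAULT_SPACING_MM,
        DEFAULT_SPACING_MM,
    )
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValidationError(
                f"volume grid must be 3D, got {self.voxels.ndim}D"
            )
        if self.voxels.shape[0] < 1:
            raise ValidationError("volume must contain at least one slice")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValidationError("spacing and origin must have 3 components")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be positive, got {self.spacing}")
        if np.issubdtype(self.voxels.dtype, np.floating) and not np.all(
            np.isfinite(self.voxels)
        ):
            raise ValidationError("volume contains NaN or infinite grey levels")

    # -- geometry helpers -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def voxel_volume_mm3(self) -> float:
        sz, sy, sx = self.spacing
        return sz * sy * sx

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical center coordinates (mm) of voxels along one axis."""
        n = self.voxels.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    @property
    def center_xy(self) -> tuple[float, float]:
        """Physical in-plane center ``(x, y)`` of the grid, mm."""
        y = self.axis_coords(1)
        x = self.axis_coords(2)
        return (float(x[0] + x[-1]) / 2.0, float(y[0] + y[-1]) / 2.0)

    def with_voxels(self, voxels: np.ndarray) -> "Volume":
        """A copy of this volume holding a different grid, same geometry."""
        return Volume(voxels=voxels, spacing=self.spacing, origin=self.origin,
                      meta=dict(self.meta))


# -- format plumbing ------------------------------------------------------


def _infer_format(path: Path, format_hint: str | None) -> str:
    if format_hint is not None:
        fmt = format_hint.lower()
        if fmt not in ("nifti", "tiff", "raw"):
            raise ConfigurationError(f"unsupported format {format_hint!r}")
        return fmt
    name = path.name.lower()
    if name.endswith(_NIFTI_SUFFIXES):
        return "nifti"
    if name.endswith(_TIFF_SUFFIXES):
        return "tiff"
    if name.endswith(_RAW_SUFFIXES):
        return "raw"
    raise ConfigurationError(
        f"cannot infer volume format from {path.name!r}; pass format_hint"
    )


def _sidecar_path(path: Path) -> Path | None:
    for suffix in (".yaml", ".yml", ".json"):
        candidate = Path(str(path) + suffix)
        if candidate.exists():
            return candidate
    return None


def _read_sidecar(path: Path) -> dict[str, Any]:
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _write_sidecar(path: Path, payload: Mapping[str, Any]) -> None:
    Path(str(path) + ".yaml").write_text(
        yaml.safe_dump(dict(payload), sort_keys=False)
    )


def _meta_to_geometry(
    meta: Mapping[str, Any],
) -> tuple[tuple[float, ...], tuple[float, ...]]:
    spacing = meta.get("spacing", None)
    if spacing is None:
        spacing = (DEFAULT_SPACING_MM,) * 3
    elif np.isscalar(spacing):
        spacing = (float(spacing),) * 3
    else:
        spacing = tuple(float(s) for s in spacing)
    origin = tuple(float(o) for o in meta.get("origin", (0.0, 0.0, 0.0)))
    return spacing, origin


# -- public API -----------------------------------------------------------


def load_volume(
    path: str | Path,
    format_hint: str | None = None,
    raw_meta: Mapping[str, Any] | None = None,
) -> Volume:
    """Load a reconstructed volume from disk.

    Parameters
    ----------
    path
        File to read.
    format_hint
        One of ``"nifti"``, ``"tiff"``, ``"raw"``; inferred from the file
        extension when omitted.
    raw_meta
        For raw binary import (or a TIFF without sidecar): a mapping with
        ``shape`` (z, y, x), ``dtype``, and optionally ``spacing`` (mm,
        scalar or 3-tuple) and ``origin``.  Overrides any sidecar file.

    Returns
    -------
    Volume
        Grey levels preserved bit-exactly for integer inputs.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    fmt = _infer_format(path, format_hint)

    if fmt == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise ValidationError(f"expected a 3D NIfTI, got {data.ndim}D: {path}")
        # nibabel arrays are (x, y, z); flip to the toolkit's (z, y, x).
        voxels = np.ascontiguousarray(data.transpose(2, 1, 0))
        zooms = img.header.get_zooms()[:3]
        spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
        affine = img.affine
        origin = (float(affine[2, 3]), float(affine[1, 3]), float(affine[0, 3]))
        meta: dict[str, Any] = {"source": str(path), "format": "nifti"}
    elif fmt == "tiff":
        voxels = tifffile.imread(str(path))
        if voxels.ndim == 2:
            voxels = voxels[None, :, :]
        sidecar = _sidecar_path(path)
        info: Mapping[str, Any] = raw_meta or (
            _read_sidecar(sidecar) if sidecar else {}
        )
        spacing, origin = _meta_to_geometry(info)
        meta = {"source": str(path), "format": "tiff"}
    else:  # raw
        sidecar = _sidecar_path(path)
        if raw_meta is not None:
            info = raw_meta
        elif sidecar is not None:
            info = _read_sidecar(sidecar)
        else:
            raise ConfigurationError(
                f"raw import of {path} requires a sidecar config or raw_meta "
                "declaring shape and dtype"
            )
        if "shape" not in info or "dtype" not in info:
            raise ConfigurationError(
                f"raw import of {path} requires 'shape' and 'dtype' metadata"
            )
        shape = tuple(int(n) for n in info["shape"])
        dtype = np.dtype(info["dtype"]).newbyteorder("<")
        data = np.fromfile(str(path), dtype=dtype)
        if data.size != int(np.prod(shape)):
            raise ValidationError(
                f"raw file {path} holds {data.size} voxels, "
                f"declared shape {shape} needs {int(np.prod(shape))}"
            )
        voxels = data.reshape(shape)
        spacing, origin = _meta_to_geometry(info)
        meta = {"source": str(path), "format": "raw"}

    if np.issubdtype(voxels.dtype, np.floating) and not np.all(np.isfinite(voxels)):
        raise ValidationError(f"volume {path} contains NaN/Inf grey levels")
    return Volume(voxels=voxels, spacing=tuple(spacing), origin=tuple(origin),
                  meta=meta)


def save_volume(
    volume: Volume,
    path: str | Path,
    format: str | None = None,
    dtype: str | np.dtype | None = None,
    allow_lossy: bool = False,
) -> Path:
    """Write a volume to disk in one of the supported formats.

    A requested ``dtype`` cast that cannot represent every grey level
    exactly raises :class:`ConfigurationError` unless ``allow_lossy=True``
    is passed explicitly; integer grids always round-trip bit-exactly.
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(
            f"directory does not exist: {path.parent}"
        )
    fmt = _infer_format(path, format)

    voxels = volume.voxels
    if dtype is not None:
        target = np.dtype(dtype)
        cast = voxels.astype(target)
        if not allow_lossy and not np.array_equal(
            cast.astype(voxels.dtype, copy=False), voxels
        ):
            raise ConfigurationError(
                f"cast to {target} loses grey-level information; "
                "pass allow_lossy=True to force it"
            )
        voxels = cast

    sz, sy, sx = volume.spacing
    oz, oy, ox = volume.origin
    if fmt == "nifti":
        import nibabel as nib

        affine = np.diag([sx, sy, sz, 1.0])
        affine[:3, 3] = (ox, oy, oz)
        img = nib.Nifti1Image(voxels.transpose(2, 1, 0), affine)
        img.header.set_zooms((sx, sy, sz))
        nib.save(img, str(path))
    elif fmt == "tiff":
        tifffile.imwrite(str(path), voxels)
        _write_sidecar(path, {"spacing": [sz, sy, sx], "origin": [oz, oy, ox]})
    else:  # raw
        voxels.astype(voxels.dtype.newbyteorder("<")).tofile(str(path))
        _write_sidecar(
            path,
            {
                "shape": list(voxels.shape),
                "dtype": voxels.dtype.name,
                "spacing": [sz, sy, sx],
                "origin": [oz, oy, ox],
            },
        )
    return path
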