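"""3D volume I/O and grey-level → Hounsfield-unit calibration.

Volumes are (z, y, x)-indexed numpy arrays with per-axis voxel spacing in mm
(stored in the same (dz, dy, dx) order).  The intensity unit — raw scanner
grey levels versus Hounsfield units — is tracked explicitly on the volume, so
downstream densitometry cannot be run on uncalibrated data by accident.

HU calibration is the standard two-point linear rescaling anchored at the
densities of air (−1000 HU) and water (0 HU).  The caller supplies the grey
levels measured for the two anchors; the scanner's native grey range is
never assumed.  Calibrated values are deliberately NOT clipped: voxels below
−1000 HU or above the dense-tissue band are preserved because the mean lung
attenuation must be computed on the untruncated distribution.

On disk, NIfTI (.nii/.nii.gz) and MetaImage (.mha/.mhd) are supported via
SimpleITK.  The intensity-unit tag is carried in a small JSON sidecar
(``<file>.json``) written next to the volume.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .errors import DegenerateCalibrationError, UnitError, VolumeFormatError

#: HU of pure air; the densitometric anchor of Eq. (1) and of the band scheme.
AIR_HU: float = -1000.0
#: HU of pure water, the second calibration anchor.
WATER_HU: float = 0.0

_SUPPORTED_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd")


class Unit(str, Enum):
    """Intensity unit carried by an :class:`ImageVolume`."""

    GREY = "GREY"
    HU = "HU"


@dataclass
class ImageVolume:
    """A 3D scalar grid with anisotropic voxel spacing and a unit tag.

    Parameters
    ----------
    data
        3D array indexed (z, y, x).
    spacing
        Voxel spacing (dz, dy, dx) in mm/voxel; all strictly positive.
    unit
        Intensity unit of ``data``; defaults to raw grey levels.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    unit: Unit = Unit.GREY

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeFormatError(
                f"expected 3D volume, got {self.data.ndim}D data"
            )
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3:
            raise VolumeFormatError("spacing must be a (dz, dy, dx) triple")
        if not all(math.isfinite(s) and s > 0 for s in self.spacing):
            raise VolumeFormatError(
                f"spacing components must be finite and > 0, got {self.spacing}"
            )
        self.unit = Unit(self.unit)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel, dz·dy·dx in mm³."""
        dz, dy, dx = self.spacing
        return dz * dy * dx

    def require_unit(self, unit: Unit) -> None:
        if self.unit is not unit:
            raise UnitError(
                f"operation requires a {unit.value} volume, got {self.unit.value}"
            )


@dataclass(frozen=True)
class CalibrationPair:
    """Grey levels measured for the two HU anchors (air and water)."""

    g_air: float
    g_water: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.g_air) and math.isfinite(self.g_water)):
            raise DegenerateCalibrationError("calibration anchors must be finite")
        if self.g_air == self.g_water:
            raise DegenerateCalibrationError(
                "air and water grey levels coincide; HU rescaling undefined"
            )


def grey_to_hu(vol: ImageVolume, calib: CalibrationPair) -> ImageVolume:
    """Linearly rescale a grey-level volume to Hounsfield units.

    The transform maps ``calib.g_air`` → −1000 HU and ``calib.g_water`` →
    0 HU and is exactly linear in between and beyond:

        HU(g) = −1000 + (g − g_air) · 1000 / (g_water − g_air)

    Spacing is preserved; no clipping is applied.
    """
    vol.require_unit(Unit.GREY)
    g = vol.data.astype(np.float64, copy=False)
    scale = (WATER_HU - AIR_HU) / (calib.g_water - calib.g_air)
    hu = AIR_HU + (g - calib.g_air) * scale
    return ImageVolume(hu, vol.spacing, Unit.HU)


def _sidecar_path(path: Path) -> Path:
    return Path(str(path) + ".json")


def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not name.endswith(_SUPPORTED_SUFFIXES):
        raise VolumeFormatError(
            f"unsupported volume format {path.name!r}; "
            f"supported: {', '.join(_SUPPORTED_SUFFIXES)}"
        )


def read_volume(path: str | Path, unit: Unit | str | None = None) -> ImageVolume:
    """Read a 3D volume from NIfTI or MetaImage.

    Spacing comes from the image header (converted to (dz, dy, dx) order).
    The intensity unit is taken, in order of precedence, from the ``unit``
    argument, from the JSON sidecar written by :func:`write_volume`, else it
    defaults to :attr:`Unit.GREY`.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeFormatError(f"no such file: {path}")
    _check_suffix(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # SimpleITK wraps ITK errors as RuntimeError
        raise VolumeFormatError(f"unreadable volume {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise VolumeFormatError(
            f"expected 3D volume, got {img.GetDimension()}D in {path}"
        )
    data = sitk.GetArrayFromImage(img)  # (z, y, x)
    spacing = tuple(reversed(img.GetSpacing()))  # (x,y,z) -> (z,y,x)
    if unit is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            unit = meta.get("unit", Unit.GREY)
        else:
            unit = Unit.GREY
    return ImageVolume(data, spacing, Unit(unit))


def write_volume(vol: ImageVolume, path: str | Path, dtype=None) -> None:
    """Write a volume to NIfTI or MetaImage, plus a JSON unit sidecar.

    HU volumes default to float32 on disk (HU precision without float64
    bloat); grey volumes keep their array dtype.  On failure no partial file
    is left behind.
    """
    path = Path(path)
    _check_suffix(path)
    if dtype is None:
        dtype = np.float32 if vol.unit is Unit.HU else vol.data.dtype
    data = np.ascontiguousarray(vol.data.astype(dtype, copy=False))
    img = sitk.GetImageFromArray(data)
    img.SetSpacing(tuple(reversed(vol.spacing)))  # (z,y,x) -> (x,y,z)
    try:
        sitk.WriteImage(img, str(path), useCompression=path.name.endswith(".gz"))
        _sidecar_path(path).write_text(
            json.dumps({"unit": vol.unit.value, "spacing_mm_zyx": list(vol.spacing)})
        )
    except (RuntimeError, OSError) as exc:
        for leftover in (path, _sidecar_path(path)):
            if leftover.exists():
                leftover.unlink()
        raise VolumeFormatError(f"cannot write volume to {path}: {exc}") from exc
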