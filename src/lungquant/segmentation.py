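"""Lung and airway segmentation of HU-calibrated thorax volumes.

The automatic path mirrors semi-automatic rodent-CT practice: threshold the
volume at an aeration cutoff (default −300 HU), keep the interior air
components (discarding the ambient-air component touching the volume
border), morphologically close and hole-fill the result so dense interior
lesions stay inside the parenchyma mask, and optionally subtract the
conducting-airway lumen grown from a user-placed seed.

Severely consolidated lungs defeat any threshold rule; for those a manually
drawn mask is a first-class input, merged with (or replacing) the automatic
result via :func:`merge_manual`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
from scipy import ndimage as ndi

from .errors import EmptyMaskError, NoLungFoundError, SeedNotInAirError, UnitError
from .volume_io import ImageVolume, Unit

log = logging.getLogger(__name__)


class MaskProvenance(str, Enum):
    AUTO = "AUTO"
    MANUAL = "MANUAL"
    MERGED = "MERGED"


class MergeMode(str, Enum):
    UNION = "UNION"
    REPLACE = "REPLACE"


@dataclass
class LungMask:
    """Boolean parenchyma mask aligned to its parent volume.

    ``mask`` is (z, y, x) boolean; airway-lumen voxels are False.  A mask
    returned by a successful segmentation is never empty.
    """

    mask: np.ndarray
    provenance: MaskProvenance
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise EmptyMaskError("mask must be 3D")
        self.provenance = MaskProvenance(self.provenance)
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_mm3(self) -> float:
        dz, dy, dx = self.spacing
        return self.voxel_count * dz * dy * dx


@dataclass
class SegmentationParams:
    """Tunables of the automatic segmentation.

    aerated_threshold
        HU below which a voxel counts as aerated (default −300 HU, between
        the parenchyma and soft-tissue modes of a rodent expiratory scan).
    connectivity
        Voxel neighbourhood for component labelling: 6 (faces) or 26 (full).
    closing_radius
        Radius (voxels) of the spherical closing element applied before
        hole filling; bridges small gaps so dense lesions become interior
        holes.
    min_component
        Minimum size (voxels) of an air component kept as candidate lung.
    airway_seed
        Optional (z, y, x) index inside the airway lumen; when given the
        grown airway tree is subtracted from the parenchyma mask.
    """

    aerated_threshold: float = -300.0
    connectivity: int = 26
    closing_radius: int = 2
    min_component: int = 100
    airway_seed: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")
        if self.closing_radius < 0:
            raise ValueError("closing_radius must be >= 0")
        if self.min_component < 1:
            raise ValueError("min_component must be >= 1")


def _structure(connectivity: int) -> np.ndarray:
    return ndi.generate_binary_structure(3, 3 if connectivity == 26 else 1)


def _ball(radius: int) -> np.ndarray:
    axis = np.arange(-radius, radius + 1)
    zz, yy, xx = np.meshgrid(axis, axis, axis, indexing="ij")
    return zz * zz + yy * yy + xx * xx <= radius * radius


def _border_labels(labels: np.ndarray) -> set[int]:
    faces = [labels[0], labels[-1], labels[:, 0], labels[:, -1],
             labels[:, :, 0], labels[:, :, -1]]
    out: set[int] = set()
    for face in faces:
        out.update(np.unique(face).tolist())
    out.discard(0)
    return out


def segment_airways(
    vol: ImageVolume,
    seed: tuple[int, int, int],
    aerated_threshold: float = -300.0,
    connectivity: int = 26,
    guard_min_voxels: int = 50,
) -> np.ndarray:
    """Grow the conducting-airway lumen from a seed voxel.

    Breadth-first region growing restricted to voxels with HU below
    ``aerated_threshold``.  A leak guard aborts growth when one wavefront
    generation exceeds twice the voxels accumulated so far — the signature
    of the front bursting out of a tube into open parenchyma.  The guard is
    armed only after ``guard_min_voxels`` have been collected, since the
    very first shells around a single seed always violate the ratio.
    """
    vol.require_unit(Unit.HU)
    seed = tuple(int(c) for c in seed)  # type: ignore[assignment]
    air = vol.data < aerated_threshold
    if not air[seed]:
        raise SeedNotInAirError(
            f"seed {seed} has HU {float(vol.data[seed]):.1f}, "
            f"not below threshold {aerated_threshold:.1f}"
        )
    struct = _structure(connectivity)
    grown = np.zeros(vol.shape, dtype=bool)
    grown[seed] = True
    front = grown.copy()
    total = 1
    while True:
        new_front = ndi.binary_dilation(front, structure=struct) & air & ~grown
        n_new = int(new_front.sum())
        if n_new == 0:
            break
        if total >= guard_min_voxels and n_new > 2 * total:
            log.warning(
                "airway growth aborted: wavefront of %d voxels exceeds 2x "
                "running total %d (leak guard)", n_new, total,
            )
            break
        grown |= new_front
        front = new_front
        total += n_new
    return grown


def segment_lungs(vol: ImageVolume, params: SegmentationParams | None = None) -> LungMask:
    """Automatic parenchyma segmentation of an HU volume.

    Steps: threshold at ``aerated_threshold``; label connected air
    components; discard components touching the volume border (ambient air)
    and components below ``min_component``; spherical closing then hole
    filling (per axial slice, then in 3D) so dense interior lesions are
    captured; subtract the airway tree when a seed is configured.
    """
    vol.require_unit(Unit.HU)
    params = params or SegmentationParams()
    struct = _structure(params.connectivity)

    air = vol.data < params.aerated_threshold
    labels, n = ndi.label(air, structure=struct)
    if n == 0:
        raise NoLungFoundError("no voxels below the aeration threshold")
    background = _border_labels(labels)
    counts = np.bincount(labels.ravel())
    keep = [
        lab for lab in range(1, n + 1)
        if lab not in background and counts[lab] >= params.min_component
    ]
    if not keep:
        raise NoLungFoundError(
            "no interior air component of at least "
            f"{params.min_component} voxels: no lung found"
        )
    mask = np.isin(labels, keep)

    if params.closing_radius > 0:
        r = params.closing_radius
        padded = np.pad(mask, r, mode="constant", constant_values=False)
        padded = ndi.binary_closing(padded, structure=_ball(r))
        mask = padded[r:-r, r:-r, r:-r]
    for z in range(mask.shape[0]):
        mask[z] = ndi.binary_fill_holes(mask[z])
    mask = ndi.binary_fill_holes(mask)

    if params.airway_seed is not None:
        airway = segment_airways(
            vol, params.airway_seed,
            aerated_threshold=params.aerated_threshold,
            connectivity=params.connectivity,
        )
        mask &= ~airway
        # subtraction can strand small crumbs at the airway ends
        labels, n = ndi.label(mask, structure=struct)
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < params.min_component)
        mask[np.isin(labels, small[small > 0])] = False

    if not mask.any():
        raise NoLungFoundError("mask empty after airway removal: no lung found")
    return LungMask(mask, MaskProvenance.AUTO, vol.spacing)


def merge_manual(auto: LungMask, manual: LungMask, mode: MergeMode | str) -> LungMask:
    """Combine an automatic mask with a manually drawn one.

    UNION takes the voxelwise OR (provenance MERGED); REPLACE discards the
    automatic mask entirely (provenance MANUAL).  The result must be
    non-empty.
    """
    mode = MergeMode(mode)
    if auto.mask.shape != manual.mask.shape:
        raise EmptyMaskError(
            f"mask shape mismatch: {auto.mask.shape} vs {manual.mask.shape}"
        )
    if mode is MergeMode.UNION:
        merged = auto.mask | manual.mask
        provenance = MaskProvenance.MERGED
    else:
        merged = manual.mask.copy()
        provenance = MaskProvenance.MANUAL
    if not merged.any():
        raise EmptyMaskError("merged mask is empty")
    log.info("manual mask merged (%s): %d -> %d voxels",
             mode.value, auto.voxel_count, int(merged.sum()))
    return LungMask(merged, provenance, auto.spacing)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) between two boolean grids."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        raise EmptyMaskError("Dice undefined for two empty masks")
    return 2.0 * float(np.logical_and(a, b).sum()) / float(denom)
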